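#!/usr/bin/env python
"""Download the eight avian uncoupling-protein CDS from NCBI (network required).

Fetches the CDS FASTA of the eight transcripts via NCBI efetch
(``rettype=fasta_cds_na``), writes ``data/avucp/avucp_cds.fasta`` and a
matching ``sample_sheet.tsv``, and prints per-record lengths.  Analyses and
tests never call the network themselves; run this once to enable the
dataset-dependent end-to-end tests.

Usage:
    python scripts/fetch_avucp.py [--out data/avucp]
"""

from __future__ import annotations

import argparse
import re
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

SPECIES_OF_ACCESSION = {
    "NM_204107.2": "Chicken",
    "XM_005025525.4": "Mallard",
    "XM_032677900.1": "Manakin",
    "XM_021285112.1": "Pigeon",
    "XM_039697035.1": "Sparrow",
    "XM_040089804.1": "Swallow",
    "NM_001303164.1": "Turkey",
    "XM_038133918.1": "Wagtail",
}


def fetch_cds(accession: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "fasta_cds_na", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        return resp.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("data/avucp"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = []
    for accession, species in sorted(SPECIES_OF_ACCESSION.items(), key=lambda kv: kv[1]):
        text = fetch_cds(accession).strip()
        if not text.startswith(">"):
            raise SystemExit(f"unexpected efetch response for {accession}")
        header, *lines = text.splitlines()
        seq = "".join(l.strip() for l in lines if not l.startswith(">"))
        records.append((accession, species, seq))
        print(f"{species:<10} {accession:<16} {len(seq)} nt")
        time.sleep(0.4)  # NCBI rate limit

    fasta = args.out / "avucp_cds.fasta"
    with open(fasta, "w") as fh:
        for accession, species, seq in records:
            fh.write(f">{accession} {species}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    sheet = args.out / "sample_sheet.tsv"
    with open(sheet, "w") as fh:
        fh.write("id\tspecies\n")
        for accession, species, _ in records:
            fh.write(f"{accession}\t{species}\n")
    print(f"wrote {fasta} and {sheet}")


if __name__ == "__main__":
    main()
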