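"""Sequence containers, FASTA I/O, translation and CDS validation.

The in-memory model is intentionally small: a :class:`CodingSequence` is a
nucleotide CDS (stored over ``{A,C,G,T}``; ``U`` is normalized to ``T`` on
input), a :class:`ProteinSequence` is a string over the 20 standard amino
acid letters, and a :class:`SequenceSet` is an ordered, id-unique collection
of one kind or the other.  FASTA parsing is delegated to Biopython; the
genetic code is the standard table (NCBI id 1) wrapped in
:class:`GeneticCode`.

All coordinates in reports are 1-based and inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Data import CodonTable

DNA_ALPHABET = frozenset("ACGT")
# IUPAC nucleotide ambiguity codes (accepted on read, flagged by validation)
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid/stop mapping (``*`` marks stop codons)."""

    table: dict[str, str]
    name: str = "standard"

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise SequenceError(f"genetic code must map 64 codons, got {len(self.table)}")
        if sum(aa == "*" for aa in self.table.values()) != 3:
            raise SequenceError("genetic code must have exactly 3 stop codons")

    @classmethod
    def standard(cls) -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[1]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = "*"
        return cls(table=table)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == "*")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa != "*"))

    def synonymous_family(self, amino_acid: str) -> tuple[str, ...]:
        """All sense codons encoding ``amino_acid`` (its degeneracy is the length)."""
        return tuple(sorted(c for c, aa in self.table.items() if aa == amino_acid))

    def __getitem__(self, codon: str) -> str:
        return self.table[codon]


STANDARD_CODE = GeneticCode.standard()


def _normalize_nt(residues: str) -> str:
    return residues.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class CodingSequence:
    """A nucleotide CDS with identifier and species tag.

    ``frame_checked`` records that the sequence passed strict validation
    (frame, no internal stop, unambiguous alphabet).
    """

    id: str
    residues: str
    species: str = ""
    frame_checked: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalize_nt(self.residues))
        bad = set(self.residues) - DNA_ALPHABET - AMBIGUITY_CODES
        if bad:
            raise SequenceError(f"{self.id}: non-nucleotide characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def codons(self) -> list[str]:
        if len(self.residues) % 3:
            raise SequenceError(f"{self.id}: length {len(self)} not divisible by 3")
        return [self.residues[i : i + 3] for i in range(0, len(self.residues), 3)]


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.strip().upper())
        if not self.residues:
            raise SequenceError(f"{self.id}: empty protein sequence")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise SequenceError(f"{self.id}: non-standard amino acids {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """Ordered, id-unique collection of sequences of one kind."""

    records: list[CodingSequence] | list[ProteinSequence]
    kind: Literal["cds", "protein"]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate sequence ids: {dupes}")
        want = CodingSequence if self.kind == "cds" else ProteinSequence
        for r in self.records:
            if not isinstance(r, want):
                raise SequenceError(f"{r.id}: expected {self.kind} record")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __getitem__(self, key: int | str):
        if isinstance(key, int):
            return self.records[key]
        for r in self.records:
            if r.id == key:
                return r
        raise KeyError(key)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass(frozen=True)
class ValidationReport:
    """Report-only result of :func:`validate_cds`; never mutates the input."""

    id: str
    frame_ok: bool
    internal_stop_codons: tuple[int, ...]  # 1-based codon indices
    ambiguous_positions: tuple[int, ...]  # 1-based nucleotide positions
    has_terminal_stop: bool

    @property
    def is_clean(self) -> bool:
        return self.frame_ok and not self.internal_stop_codons

    @property
    def is_strictly_clean(self) -> bool:
        return self.is_clean and not self.ambiguous_positions


def validate_cds(cds: CodingSequence, code: GeneticCode = STANDARD_CODE) -> ValidationReport:
    """Check reading frame, internal stops and alphabet of a CDS."""
    frame_ok = len(cds) % 3 == 0 and len(cds) > 0
    ambiguous = tuple(
        i + 1 for i, base in enumerate(cds.residues) if base not in DNA_ALPHABET
    )
    internal: list[int] = []
    terminal = False
    if frame_ok:
        codons = [cds.residues[i : i + 3] for i in range(0, len(cds), 3)]
        for idx, codon in enumerate(codons, start=1):
            if codon in code.stop_codons:
                if idx == len(codons):
                    terminal = True
                else:
                    internal.append(idx)
    return ValidationReport(
        id=cds.id,
        frame_ok=frame_ok,
        internal_stop_codons=tuple(internal),
        ambiguous_positions=ambiguous,
        has_terminal_stop=terminal,
    )


def translate(
    cds: CodingSequence,
    code: GeneticCode = STANDARD_CODE,
    drop_terminal_stop: bool = True,
) -> ProteinSequence:
    """Translate a frame-valid CDS; internal stops are an error.

    Raises :class:`SequenceError` naming the 1-based codon index of the first
    internal stop, or if any codon contains ambiguity codes.
    """
    codons = cds.codons()
    residues: list[str] = []
    for idx, codon in enumerate(codons, start=1):
        if set(codon) - DNA_ALPHABET:
            raise SequenceError(f"{cds.id}: ambiguous codon {codon} at codon {idx}")
        aa = code[codon]
        if aa == "*":
            if idx == len(codons):
                if drop_terminal_stop:
                    break
                raise SequenceError(
                    f"{cds.id}: terminal stop codon retained but proteins cannot "
                    "contain '*'; use drop_terminal_stop=True"
                )
            raise SequenceError(f"{cds.id}: internal stop codon {codon} at codon {idx}")
        residues.append(aa)
    return ProteinSequence(id=cds.id, residues="".join(residues), species=cds.species)


def translate_set(
    seqs: SequenceSet, code: GeneticCode = STANDARD_CODE, drop_terminal_stop: bool = True
) -> SequenceSet:
    """Translate every CDS of a set, preserving order and metadata."""
    if seqs.kind != "cds":
        raise SequenceError("translate_set expects a CDS set")
    prots = [translate(c, code=code, drop_terminal_stop=drop_terminal_stop) for c in seqs]
    return SequenceSet(records=prots, kind="protein", provenance=seqs.provenance)


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>species`` sheet mapping record ids to species labels."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() == "id":
                continue
            if len(row) < 2:
                raise SequenceError(f"sample sheet row needs id and species: {row!r}")
            mapping[row[0].strip()] = row[1].strip()
    return mapping


def read_fasta(
    path: str | Path,
    kind: Literal["cds", "protein"] = "cds",
    sample_sheet: str | Path | None = None,
) -> SequenceSet:
    """Read a multi-record FASTA into a :class:`SequenceSet`.

    The id is the header token before the first whitespace; the species label
    defaults to the remainder of the header and may be overridden by a
    sample-sheet TSV (columns ``id``, ``species``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    species_of = read_sample_sheet(sample_sheet) if sample_sheet else {}
    records: list = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            species = species_of.get(rec.id, rec.description[len(rec.id) :].strip())
            try:
                if kind == "cds":
                    records.append(
                        CodingSequence(id=rec.id, residues=str(rec.seq), species=species)
                    )
                else:
                    records.append(
                        ProteinSequence(id=rec.id, residues=str(rec.seq), species=species)
                    )
            except SequenceError as exc:
                raise SequenceError(f"{path}: {exc}") from exc
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return SequenceSet(records=records, kind=kind, provenance=str(path))


def write_fasta(seqs: SequenceSet | Iterable, path: str | Path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA (``>id species`` headers)."""
    with open(path, "w") as fh:
        for rec in seqs:
            header = f">{rec.id}" + (f" {rec.species}" if rec.species else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
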