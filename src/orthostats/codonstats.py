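"""Nucleotide composition, codon usage, RSCU, CAI and expected CAI.

Relative synonymous codon usage of codon *j* for amino acid *i* is

    RSCU_ij = n_i * x_ij / sum_j x_ij

with ``x_ij`` the observed count and ``n_i`` the degeneracy of the family;
RSCU > 1 marks a preferred codon, an unobserved codon has RSCU 0, and a
codon of an amino acid absent from the sequence is reported as 0 by
convention (the ratio is 0/0 there).

The codon adaptation index follows Sharp & Li: the geometric mean over the
CDS of each codon's relative adaptiveness ``w_ij = f_ij / max_j f_ij``
computed from a reference usage table, excluding Met, Trp and stops.  The
expected CAI is the CAI distribution of random coding sequences drawn from
a first-order Markov nucleotide model fitted to the query's dinucleotide
composition, the significance baseline used with 500 replicates.

Codons are stored as DNA internally and rendered with U in report grids.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import (
    DNA_ALPHABET,
    STANDARD_CODE,
    CodingSequence,
    GeneticCode,
    SequenceError,
    SequenceSet,
)

BASES = "ACGT"


def rna(codon: str) -> str:
    """Render a DNA codon with U, as codon-usage reports conventionally do."""
    return codon.replace("T", "U")


def dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionProfile:
    """Base percentages overall and at each codon position, plus GC columns.

    ``base_pct[base][k]`` holds the percentage of ``base`` at codon position
    ``k`` (1, 2, 3) or overall (``k = 0``).  ``gc[k]`` likewise; all values
    are kept at full precision and rounded only in report grids.
    """

    base_pct: dict[str, dict[int, float]]
    gc: dict[int, float]
    length: int

    def __getattr__(self, name: str) -> float:
        # convenience accessors: .gc0/.gc1/.gc2/.gc3 and e.g. .c3, .g1
        m = re.fullmatch(r"gc([0-3])", name)
        if m:
            return self.gc[int(m.group(1))]
        m = re.fullmatch(r"([acgt])([0-3])", name)
        if m:
            return self.base_pct[m.group(1).upper()][int(m.group(2))]
        raise AttributeError(name)


def composition(cds: CodingSequence) -> CompositionProfile:
    """Per-base percentages overall and at codon positions 1-3."""
    seq = cds.residues
    if not seq:
        raise SequenceError(f"{cds.id}: empty sequence")
    if len(seq) % 3:
        raise SequenceError(f"{cds.id}: length {len(seq)} not divisible by 3")
    positions = {0: seq, 1: seq[0::3], 2: seq[1::3], 3: seq[2::3]}
    base_pct: dict[str, dict[int, float]] = {b: {} for b in BASES}
    gc: dict[int, float] = {}
    for k, sub in positions.items():
        n = len(sub)
        for b in BASES:
            base_pct[b][k] = 100.0 * sub.count(b) / n
        gc[k] = base_pct["G"][k] + base_pct["C"][k]
    return CompositionProfile(base_pct=base_pct, gc=gc, length=len(seq))


def composition_grid(seqs: SequenceSet, decimals: int = 1) -> pd.DataFrame:
    """Species-by-column composition grid (C, G, C-1..G-3, GC, GC-1..GC-3)."""
    rows = {}
    for cds in seqs:
        p = composition(cds)
        rows[cds.species or cds.id] = {
            "C": p.base_pct["C"][0],
            "G": p.base_pct["G"][0],
            "C-1": p.base_pct["C"][1],
            "G-1": p.base_pct["G"][1],
            "C-2": p.base_pct["C"][2],
            "G-2": p.base_pct["G"][2],
            "C-3": p.base_pct["C"][3],
            "G-3": p.base_pct["G"][3],
            "GC": p.gc[0],
            "GC-1": p.gc[1],
            "GC-2": p.gc[2],
            "GC-3": p.gc[3],
        }
    return pd.DataFrame.from_dict(rows, orient="index").round(decimals)


# ---------------------------------------------------------------------------
# Codon usage and RSCU
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonUsageTable:
    """Observed codon counts of one CDS (stops tracked separately)."""

    counts: dict[str, int]  # sense codons only, all 61 keys present
    stop_counts: dict[str, int]
    skipped_ambiguous: int
    code: GeneticCode = STANDARD_CODE

    @property
    def total_sense(self) -> int:
        return sum(self.counts.values())

    def family_total(self, amino_acid: str) -> int:
        return sum(self.counts[c] for c in self.code.synonymous_family(amino_acid))


def codon_usage(cds: CodingSequence, code: GeneticCode = STANDARD_CODE) -> CodonUsageTable:
    """Count every codon of a frame-valid CDS once; ambiguous codons skipped."""
    counts = {c: 0 for c in code.sense_codons}
    stops = {c: 0 for c in code.stop_codons}
    skipped = 0
    for codon in cds.codons():
        if set(codon) - DNA_ALPHABET:
            skipped += 1
        elif codon in stops:
            stops[codon] += 1
        else:
            counts[codon] += 1
    return CodonUsageTable(counts=counts, stop_counts=stops, skipped_ambiguous=skipped, code=code)


@dataclass(frozen=True)
class RscuTable:
    values: dict[str, float]  # sense codon -> RSCU
    counts: dict[str, int]
    code: GeneticCode = STANDARD_CODE

    @property
    def preferred(self) -> tuple[str, ...]:
        """Sense codons with RSCU strictly greater than 1."""
        return tuple(sorted(c for c, v in self.values.items() if v > 1.0))

    @property
    def unused(self) -> tuple[str, ...]:
        """Sense codons never observed (RSCU reported 0)."""
        return tuple(sorted(c for c in self.values if self.counts[c] == 0))


def rscu(table: CodonUsageTable) -> RscuTable:
    code = table.code
    values: dict[str, float] = {}
    for aa in sorted(set(code.table.values()) - {"*"}):
        family = code.synonymous_family(aa)
        total = sum(table.counts[c] for c in family)
        for c in family:
            values[c] = len(family) * table.counts[c] / total if total else 0.0
    return RscuTable(values=values, counts=dict(table.counts), code=code)


@dataclass(frozen=True)
class CodonBiasSummary:
    n_preferred: int
    n_unused: int
    preferred_set: tuple[str, ...]
    third_base_of_preferred: dict[str, int]  # rendered bases A/C/G/U


def codon_bias_summary(rscu_table: RscuTable) -> CodonBiasSummary:
    preferred = rscu_table.preferred
    tally = {b: 0 for b in "ACGU"}
    for codon in preferred:
        tally[rna(codon)[-1]] += 1
    return CodonBiasSummary(
        n_preferred=len(preferred),
        n_unused=len(rscu_table.unused),
        preferred_set=tuple(rna(c) for c in preferred),
        third_base_of_preferred=tally,
    )


def codon_usage_grid(seqs: SequenceSet, code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
    """Codon-by-species grid of CU counts and 1-decimal RSCU values.

    Rows are codons rendered with U and annotated with the encoded amino
    acid, e.g. ``CUG(L)``; columns interleave ``<species> CU`` and
    ``<species> RSCU``.
    """
    data: dict[str, dict[str, float]] = {}
    for cds in seqs:
        label = cds.species or cds.id
        table = codon_usage(cds, code=code)
        values = rscu(table)
        for codon in code.sense_codons:
            row = data.setdefault(f"{rna(codon)}({code[codon]})", {})
            row[f"{label} CU"] = table.counts[codon]
            row[f"{label} RSCU"] = round(values.values[codon], 1)
    return pd.DataFrame.from_dict(data, orient="index")


# ---------------------------------------------------------------------------
# Reference codon usage tables and CAI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceCodonTable:
    """Reference usage frequencies (any non-negative scale) for 61 sense codons."""

    frequencies: dict[str, float]
    source: str = ""
    code: GeneticCode = STANDARD_CODE

    def __post_init__(self) -> None:
        missing = set(self.code.sense_codons) - set(self.frequencies)
        if missing:
            raise SequenceError(f"reference table missing codons: {sorted(missing)[:5]}...")
        if any(v < 0 for v in self.frequencies.values()):
            raise SequenceError("reference frequencies must be non-negative")

    @classmethod
    def uniform(cls, code: GeneticCode = STANDARD_CODE) -> "ReferenceCodonTable":
        return cls({c: 1.0 for c in code.sense_codons}, source="uniform", code=code)

    @classmethod
    def from_counts(cls, table: CodonUsageTable, source: str = "query") -> "ReferenceCodonTable":
        return cls({c: float(n) for c, n in table.counts.items()}, source=source, code=table.code)

    @classmethod
    def read(cls, path: str | Path, code: GeneticCode = STANDARD_CODE) -> "ReferenceCodonTable":
        """Read a Kazusa-style codon usage table or a two-column TSV.

        The Kazusa text layout is runs of ``UUU 17.6( 714298)`` fields; the
        TSV fallback is ``codon<TAB>frequency`` with optional ``#`` comments.
        """
        text = Path(path).read_text()
        freqs: dict[str, float] = {}
        kazusa = re.findall(r"([AUGCT]{3})\s+([\d.]+)\s*\(\s*[\d.]+\s*\)", text)
        if kazusa:
            for codon, freq in kazusa:
                freqs[dna(codon)] = float(freq)
        else:
            for line in text.splitlines():
                line = line.split("#")[0].strip()
                if not line:
                    continue
                parts = line.replace(",", "\t").split()
                if len(parts) < 2 or not re.fullmatch(r"[AUGCTaugct]{3}", parts[0]):
                    continue
                freqs[dna(parts[0])] = float(parts[1])
        for stop in code.stop_codons:
            freqs.pop(stop, None)
        return cls(freqs, source=str(path), code=code)

    def relative_adaptiveness(self, floor: float = 0.5) -> dict[str, float]:
        """w_ij = f_ij / max over the synonymous family, zero freqs floored.

        A reference frequency of exactly zero is replaced by ``floor``
        (0.5 occurrences-equivalent on the table's own scale) so log w stays
        finite; a warning is emitted when the floor is applied.
        """
        floored = dict(self.frequencies)
        zeros = [c for c, v in floored.items() if v == 0.0]
        if zeros:
            warnings.warn(
                f"reference table {self.source!r}: {len(zeros)} zero-frequency "
                f"codons floored at {floor}",
                stacklevel=2,
            )
            for c in zeros:
                floored[c] = floor
        w: dict[str, float] = {}
        for aa in sorted(set(self.code.table.values()) - {"*"}):
            family = self.code.synonymous_family(aa)
            fmax = max(floored[c] for c in family)
            for c in family:
                w[c] = floored[c] / fmax
        return w


#: codons excluded from CAI (no synonymous choice) plus stops
_CAI_EXCLUDED_AA = {"M", "W", "*"}


def cai(cds: CodingSequence, ref: ReferenceCodonTable) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Met, Trp and stop codons carry no synonymous information and are
    excluded; ambiguous codons are skipped.  Invariant to codon order.
    """
    w = ref.relative_adaptiveness()
    code = ref.code
    log_sum = 0.0
    n = 0
    for codon in cds.codons():
        if set(codon) - DNA_ALPHABET:
            continue
        if code[codon] in _CAI_EXCLUDED_AA:
            continue
        log_sum += math.log(w[codon])
        n += 1
    if n == 0:
        raise SequenceError(f"{cds.id}: no CAI-informative codons")
    return math.exp(log_sum / n)


@dataclass(frozen=True)
class MarkovModel:
    """First-order nucleotide chain (initial distribution + 4x4 transitions)."""

    initial: np.ndarray  # shape (4,), order ACGT
    transition: np.ndarray  # shape (4, 4), rows sum to 1

    def __post_init__(self) -> None:
        if self.initial.shape != (4,) or self.transition.shape != (4, 4):
            raise SequenceError("Markov model needs 4 initial and 4x4 transition probabilities")
        if (self.initial < 0).any() or (self.transition < 0).any():
            raise SequenceError("Markov probabilities must be non-negative")
        if not math.isclose(self.initial.sum(), 1.0, abs_tol=1e-9):
            raise SequenceError("initial probabilities must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise SequenceError("transition rows must sum to 1")

    @classmethod
    def fit(cls, cds: CodingSequence, pseudocount: float = 1.0) -> "MarkovModel":
        """Fit to the query's mononucleotide and dinucleotide composition."""
        idx = {b: i for i, b in enumerate(BASES)}
        seq = [idx[b] for b in cds.residues if b in idx]
        init = np.bincount(seq, minlength=4).astype(float)
        init /= init.sum()
        trans = np.full((4, 4), pseudocount)
        for a, b in zip(seq[:-1], seq[1:]):
            trans[a, b] += 1
        trans /= trans.sum(axis=1, keepdims=True)
        return cls(initial=init, transition=trans)

    def sample(self, n_nt: int, rng: np.random.Generator) -> str:
        states = np.empty(n_nt, dtype=np.int64)
        states[0] = rng.choice(4, p=self.initial)
        cum = np.cumsum(self.transition, axis=1)
        u = rng.random(n_nt)
        for i in range(1, n_nt):
            states[i] = np.searchsorted(cum[states[i - 1]], u[i])
        return "".join(BASES[s] for s in states)


@dataclass(frozen=True)
class CaiResult:
    cai: float
    expected_cai: float  # mean over replicates
    expected_sd: float
    expected_q95: float
    n_reps: int
    seed: int
    reference: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.cai <= 1.0:
            raise SequenceError(f"CAI {self.cai} outside [0, 1]")


def expected_cai(
    cds: CodingSequence,
    ref: ReferenceCodonTable,
    n_reps: int = 500,
    seed: int = 0,
    length_codons: int | None = None,
    model: MarkovModel | None = None,
) -> CaiResult:
    """Monte-Carlo expected CAI under a sequence-composition null.

    Draws ``n_reps`` random sequences of the query's length from a
    first-order Markov nucleotide model fitted to the query (or supplied),
    scores each with :func:`cai` and summarizes the null distribution.
    Reproducible under a fixed seed.
    """
    if n_reps < 1:
        raise SequenceError("n_reps must be >= 1")
    model = model or MarkovModel.fit(cds)
    n_codons = length_codons or len(cds) // 3
    rng = np.random.default_rng(seed)
    sims = np.empty(n_reps)
    for r in range(n_reps):
        random_cds = CodingSequence(id=f"sim{r}", residues=model.sample(3 * n_codons, rng))
        sims[r] = cai(random_cds, ref)
    return CaiResult(
        cai=cai(cds, ref),
        expected_cai=float(sims.mean()),
        expected_sd=float(sims.std(ddof=1)) if n_reps > 1 else 0.0,
        expected_q95=float(np.quantile(sims, 0.95)),
        n_reps=n_reps,
        seed=seed,
        reference=ref.source,
    )
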