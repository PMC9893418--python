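"""Site classification, per-column Shannon entropy and logo matrices.

Works on an equal-length residue matrix (nucleotide or protein).  A column
is *conserved* when a single state occupies it, *parsimony-informative*
when at least two states each occur at least twice, and a *singleton*
otherwise (variable but not informative).  Column entropy is
``H = -sum_s p_s log p_s`` over observed state frequencies, in nats by
default; over 8 sequences the attainable maximum with state multiplicities
(2,2,2,1,1) is 1.56 nats.  Positions are 1-based in every output.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import SequenceError, SequenceSet

CONSERVED = "conserved"
SINGLETON = "singleton"
PARSIMONY_INFORMATIVE = "parsimony_informative"

#: characters treated as gap/missing when ``strict`` handling is requested
GAP_CHARS = frozenset("-.NX?")


@dataclass(frozen=True)
class Alignment:
    """Equal-length rows over a shared alphabet; >= 2 rows required."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    kind: str = "protein"

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SequenceError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise SequenceError(
                f"rows have unequal lengths {sorted(lengths)}; supply a proper "
                "alignment (no aligner is built in)"
            )
        if len(self.ids) != len(self.rows):
            raise SequenceError("ids/rows length mismatch")

    @classmethod
    def from_sequence_set(cls, seqs: SequenceSet) -> "Alignment":
        return cls(
            ids=tuple(seqs.ids),
            rows=tuple(r.residues for r in seqs),
            kind=seqs.kind,
        )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, i: int) -> str:
        """Column by 0-based index."""
        return "".join(row[i] for row in self.rows)


@dataclass(frozen=True)
class SiteClassification:
    labels: tuple[str, ...]
    excluded_columns: tuple[int, ...]  # 1-based, gap/ambiguity columns (strict mode)

    @property
    def n_conserved(self) -> int:
        return sum(l == CONSERVED for l in self.labels)

    @property
    def n_parsimony_informative(self) -> int:
        return sum(l == PARSIMONY_INFORMATIVE for l in self.labels)

    @property
    def n_singleton(self) -> int:
        return sum(l == SINGLETON for l in self.labels)

    @property
    def n_variable(self) -> int:
        return self.n_parsimony_informative + self.n_singleton

    def counts(self) -> dict[str, int]:
        return {
            "conserved": self.n_conserved,
            "variable": self.n_variable,
            "parsimony_informative": self.n_parsimony_informative,
            "singleton": self.n_singleton,
        }


def _classify_column(column: str) -> str:
    counts = Counter(column)
    if len(counts) == 1:
        return CONSERVED
    if sum(1 for n in counts.values() if n >= 2) >= 2:
        return PARSIMONY_INFORMATIVE
    return SINGLETON


def classify_sites(aln: Alignment, strict: bool = False) -> SiteClassification:
    """Label each column conserved / singleton / parsimony-informative.

    In strict mode columns containing gap or ambiguity characters are
    excluded from the labels and reported as 1-based indices.
    """
    labels: list[str] = []
    excluded: list[int] = []
    for i in range(aln.n_cols):
        col = aln.column(i)
        if strict and set(col) & GAP_CHARS:
            excluded.append(i + 1)
            continue
        labels.append(_classify_column(col))
    return SiteClassification(labels=tuple(labels), excluded_columns=tuple(excluded))


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntropyProfile:
    entropies: tuple[float, ...]
    log_base: float  # e for nats, 2 for bits

    def __len__(self) -> int:
        return len(self.entropies)


def shannon_entropy(counts, log_base: float = math.e) -> float:
    """Entropy of a state-count multiset, e.g. (2,2,2,1,1) over 8 -> 1.5596."""
    counts = sorted(counts)  # fixed summation order: row order cannot perturb H
    total = sum(counts)
    h = 0.0
    for n in counts:
        if n:
            p = n / total
            h -= p * math.log(p)
    return h / math.log(log_base)


def column_entropy(aln: Alignment, log_base: float = math.e, strict: bool = False) -> EntropyProfile:
    """Per-column Shannon entropy; gap-containing columns get NaN in strict mode."""
    entropies = []
    for i in range(aln.n_cols):
        col = aln.column(i)
        if strict and set(col) & GAP_CHARS:
            entropies.append(float("nan"))
            continue
        entropies.append(shannon_entropy(Counter(col).values(), log_base=log_base))
    return EntropyProfile(entropies=tuple(entropies), log_base=log_base)


@dataclass(frozen=True)
class EntropySummary:
    mean: float
    n_zero: int
    max_entropy: float
    top_positions: tuple[tuple[int, float], ...]  # (1-based position, H), H desc then index
    zero_runs: tuple[tuple[int, int], ...]  # 1-based inclusive spans, len > threshold
    zero_run_min_len: int


def entropy_summary(
    profile: EntropyProfile, zero_run_min_len: int = 10, n_top: int = 7
) -> EntropySummary:
    """Mean/zero-count/max, top positions, and long fully-conserved runs.

    Zero runs strictly longer than ``zero_run_min_len`` are reported as
    1-based inclusive spans ("more than 10 residues" is the default rule).
    """
    h = np.asarray(profile.entropies, dtype=float)
    valid = h[~np.isnan(h)]
    order = sorted(
        ((i + 1, float(v)) for i, v in enumerate(h) if not math.isnan(v)),
        key=lambda t: (-t[1], t[0]),
    )
    runs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(h):
        if v == 0.0:
            if start is None:
                start = i
        else:
            if start is not None and i - start > zero_run_min_len:
                runs.append((start + 1, i))
            start = None
    if start is not None and len(h) - start > zero_run_min_len:
        runs.append((start + 1, len(h)))
    return EntropySummary(
        mean=float(valid.mean()),
        n_zero=int((valid == 0.0).sum()),
        max_entropy=float(valid.max()),
        top_positions=tuple(order[:n_top]),
        zero_runs=tuple(runs),
        zero_run_min_len=zero_run_min_len,
    )


# ---------------------------------------------------------------------------
# Logo matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogoMatrix:
    """Per-column information (bits) and per-letter heights (freq x info)."""

    information: tuple[float, ...]
    heights: tuple[dict[str, float], ...]


def logo_matrix(aln: Alignment, alphabet_size: int = 20) -> LogoMatrix:
    """Information-content logo: info = log2(|alphabet|) - H(column, bits).

    No small-sample correction is applied; a fully conserved protein column
    carries log2(20) = 4.32 bits in a single letter.
    """
    info: list[float] = []
    heights: list[dict[str, float]] = []
    max_bits = math.log2(alphabet_size)
    for i in range(aln.n_cols):
        col = aln.column(i)
        counts = Counter(col)
        h_bits = shannon_entropy(counts.values(), log_base=2)
        ic = max(max_bits - h_bits, 0.0)
        info.append(ic)
        heights.append({letter: (n / len(col)) * ic for letter, n in sorted(counts.items())})
    return LogoMatrix(information=tuple(info), heights=tuple(heights))


def site_report(aln: Alignment, log_base: float = math.e) -> pd.DataFrame:
    """Per-position TSV-ready table: state counts, entropy and class label."""
    classes = classify_sites(aln)
    profile = column_entropy(aln, log_base=log_base)
    rows = []
    for i in range(aln.n_cols):
        counts = Counter(aln.column(i))
        rows.append(
            {
                "position": i + 1,
                "states": "".join(sorted(counts)),
                "counts": ",".join(str(counts[s]) for s in sorted(counts)),
                "entropy": profile.entropies[i],
                "class": classes.labels[i],
            }
        )
    return pd.DataFrame(rows)
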