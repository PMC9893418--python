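"""Kyte-Doolittle hydropathy profiles and membrane-topology assembly.

A hydropathy profile is the sliding unweighted mean of per-residue
Kyte-Doolittle values over an odd window (default 19, the classic choice
for transmembrane helices).  Candidate transmembrane segments are maximal
runs of window centers above a threshold (default 1.6); runs shorter than
``min_len`` are dropped and surviving runs closer than ``min_gap`` are
merged.  The loops between transmembrane segments are then labeled by
alternation starting from the configured side at the N-terminus
(extracellular by default, matching mitochondrial carrier topology where
an even transmembrane count puts both termini on the same side: six
segments yield four extracellular and three cytoplasmic regions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protstats import KYTE_DOOLITTLE
from .seqio import ProteinSequence, SequenceError

TRANSMEMBRANE = "transmembrane"
EXTRACELLULAR = "extracellular"
CYTOPLASMIC = "cytoplasmic"


@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed mean hydropathy; ``positions`` are 1-based window centers."""

    values: tuple[float, ...]
    positions: tuple[int, ...]
    window: int
    length: int  # protein length

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "hydropathy": self.values})


def kd_profile(p: ProteinSequence, window: int = 19) -> HydropathyProfile:
    """Sliding unweighted mean of Kyte-Doolittle values (window odd, <= L)."""
    if window % 2 == 0:
        raise SequenceError(f"window must be odd, got {window}")
    if window > len(p):
        raise SequenceError(f"window {window} exceeds protein length {len(p)}")
    raw = np.array([KYTE_DOOLITTLE[aa] for aa in p.residues])
    means = np.convolve(raw, np.full(window, 1.0 / window), mode="valid")
    half = window // 2
    positions = tuple(range(half + 1, len(p) - half + 1))
    return HydropathyProfile(
        values=tuple(float(v) for v in means),
        positions=positions,
        window=window,
        length=len(p),
    )


@dataclass(frozen=True)
class Segment:
    start: int  # 1-based inclusive residue positions
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SequenceError(f"segment start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


def call_tm_segments(
    profile: HydropathyProfile,
    threshold: float = 1.6,
    min_len: int = 15,
    min_gap: int = 5,
) -> list[Segment]:
    """Maximal above-threshold runs -> drop short runs -> merge close runs."""
    runs: list[list[int]] = []
    for pos, value in zip(profile.positions, profile.values):
        if value > threshold:
            if runs and runs[-1][1] == pos - 1:
                runs[-1][1] = pos
            else:
                runs.append([pos, pos])
    kept = [r for r in runs if r[1] - r[0] + 1 >= min_len]
    merged: list[list[int]] = []
    for r in kept:
        if merged and r[0] - merged[-1][1] < min_gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [Segment(start=s, end=e, label=TRANSMEMBRANE) for s, e in merged]


@dataclass(frozen=True)
class TopologyModel:
    """Ordered segments tiling 1..L; loop labels alternate around the TMs."""

    segments: tuple[Segment, ...]
    length: int

    def __post_init__(self) -> None:
        expect = 1
        for seg in self.segments:
            if seg.start != expect:
                raise SequenceError(f"segments do not tile: gap/overlap at {seg.start}")
            expect = seg.end + 1
        if expect != self.length + 1:
            raise SequenceError("segments do not cover the full sequence")

    def count(self, label: str) -> int:
        return sum(s.label == label for s in self.segments)

    def counts(self) -> dict[str, int]:
        return {
            "transmembrane": self.count(TRANSMEMBRANE),
            "extracellular": self.count(EXTRACELLULAR),
            "cytoplasmic": self.count(CYTOPLASMIC),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"start": s.start, "end": s.end, "label": s.label} for s in self.segments]
        )


def assemble_topology(
    segments: list[Segment], length: int, n_terminal: str = EXTRACELLULAR
) -> TopologyModel:
    """Label inter-TM loops by alternation from the N-terminal side.

    With six transmembrane segments and an extracellular N-terminus this
    yields four extracellular and three cytoplasmic regions.
    """
    if n_terminal not in (EXTRACELLULAR, CYTOPLASMIC):
        raise SequenceError(f"invalid n_terminal side {n_terminal!r}")
    ordered = sorted(segments, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise SequenceError(f"overlapping segments at {b.start}")
    if ordered and ordered[-1].end > length:
        raise SequenceError("segment extends past sequence end")
    other = {EXTRACELLULAR: CYTOPLASMIC, CYTOPLASMIC: EXTRACELLULAR}
    out: list[Segment] = []
    side = n_terminal
    cursor = 1
    for tm in ordered:
        if tm.start > cursor:
            out.append(Segment(start=cursor, end=tm.start - 1, label=side))
        out.append(tm)
        side = other[side]
        cursor = tm.end + 1
    if cursor <= length:
        out.append(Segment(start=cursor, end=length, label=side))
    return TopologyModel(segments=tuple(out), length=length)


def predict_topology(
    p: ProteinSequence,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
    min_gap: int = 5,
    n_terminal: str = EXTRACELLULAR,
) -> TopologyModel:
    """Profile -> segment calling -> alternating topology, in one call."""
    profile = kd_profile(p, window=window)
    tms = call_tm_segments(profile, threshold=threshold, min_len=min_len, min_gap=min_gap)
    return assemble_topology(tms, length=len(p), n_terminal=n_terminal)
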