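"""Physico-chemical protein indices: MW, pI, aliphatic index, instability
index, GRAVY, charge/hydropathy fractions, sulfur count, extinction.

These are the classic ProtParam-style descriptors.  Molecular weight uses
average (not monoisotopic) residue masses.  The isoelectric point solves
net charge = 0 by bisection over Henderson-Hasselbalch terms for the
termini and the ionizable side chains (D, E, C, Y, H, K, R); the default
pKa set is the Bjellqvist/Expasy one, with EMBOSS selectable.  The
instability index is Guruprasad's dipeptide-weight statistic
(10/L * sum of consecutive-dipeptide weights; < 40 is conventionally
"stable"), and the aliphatic index is
X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu) in mole percent.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import DIWV  # Guruprasad dipeptide weights

from .seqio import ProteinSequence, SequenceError, SequenceSet

WATER_MASS = 18.0153

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: pKa sets: (positive groups, negative groups); 'nterm'/'cterm' are termini
PKA_SETS = {
    # Bjellqvist values as popularized by the Expasy tools
    "expasy": (
        {"nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
        {"cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    ),
    "emboss": (
        {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5},
        {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    ),
}

#: Bjellqvist residue-specific terminal pKas (used by the expasy set)
NTERM_PKA = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
CTERM_PKA = {"D": 4.55, "E": 4.75}

NEGATIVE_RESIDUES = frozenset("DE")
POSITIVE_RESIDUES = frozenset("KRH")
HYDROPHOBIC_RESIDUES = frozenset("ACFILMVW")
HYDROPHILIC_RESIDUES = frozenset("DEGHKNQRSTY")


def aa_composition(p: ProteinSequence) -> "AaComposition":
    counts = Counter(p.residues)
    return AaComposition(
        counts={aa: counts.get(aa, 0) for aa in sorted(KYTE_DOOLITTLE)},
        length=len(p),
    )


@dataclass(frozen=True)
class AaComposition:
    counts: dict[str, int]
    length: int

    @property
    def mole_percent(self) -> dict[str, float]:
        return {aa: 100.0 * n / self.length for aa, n in self.counts.items()}


def molecular_weight(p: ProteinSequence) -> float:
    """Average-mass molecular weight in Daltons (sum of residues + water)."""
    residue_mass = sum(protein_weights[aa] - WATER_MASS for aa in p.residues)
    return residue_mass + WATER_MASS


def _net_charge(counts: Counter, ph: float, positive: dict, negative: dict) -> float:
    charge = 0.0
    for group, pka in positive.items():
        n = 1 if group == "nterm" else counts.get(group, 0)
        charge += n / (1.0 + 10 ** (ph - pka))
    for group, pka in negative.items():
        n = 1 if group == "cterm" else counts.get(group, 0)
        charge -= n / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(p: ProteinSequence, pka_set: str = "expasy", tol: float = 1e-3) -> float:
    """pH at which the Henderson-Hasselbalch net charge crosses zero.

    The charge is strictly decreasing in pH, so bisection over [0, 14]
    converges; non-convergence within 100 iterations raises (guarded,
    cannot occur for a monotone curve).
    """
    if pka_set not in PKA_SETS:
        raise SequenceError(f"unknown pKa set {pka_set!r}; choose from {sorted(PKA_SETS)}")
    positive, negative = _terminal_adjusted_pkas(p, pka_set)
    counts = Counter(p.residues)
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if hi - lo < tol:
            return mid
        if _net_charge(counts, mid, positive, negative) > 0:
            lo = mid
        else:
            hi = mid
    raise SequenceError("isoelectric point bisection failed to converge")


def _terminal_adjusted_pkas(p: ProteinSequence, pka_set: str) -> tuple[dict, dict]:
    positive, negative = (d.copy() for d in PKA_SETS[pka_set])
    if pka_set == "expasy":  # Bjellqvist terminal pKas depend on the residue
        positive["nterm"] = NTERM_PKA.get(p.residues[0], positive["nterm"])
        negative["cterm"] = CTERM_PKA.get(p.residues[-1], negative["cterm"])
    return positive, negative


def net_charge_at(p: ProteinSequence, ph: float, pka_set: str = "expasy") -> float:
    positive, negative = _terminal_adjusted_pkas(p, pka_set)
    return _net_charge(Counter(p.residues), ph, positive, negative)


def instability_index(p: ProteinSequence) -> float:
    """Guruprasad dipeptide-weight instability index, (10/L) * sum of DIWV."""
    if len(p) < 2:
        raise SequenceError("instability index needs at least 2 residues")
    total = sum(DIWV[a][b] for a, b in zip(p.residues[:-1], p.residues[1:]))
    return 10.0 * total / len(p)


def aliphatic_index(p: ProteinSequence) -> float:
    x = aa_composition(p).mole_percent
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def gravy(p: ProteinSequence) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value per residue)."""
    return sum(KYTE_DOOLITTLE[aa] for aa in p.residues) / len(p)


def sulfur_count(p: ProteinSequence) -> int:
    """Number of sulfur atoms: one per Cys plus one per Met."""
    return p.residues.count("C") + p.residues.count("M")


def charge_and_hydropathy_fractions(
    p: ProteinSequence,
    negative: frozenset[str] = NEGATIVE_RESIDUES,
    positive: frozenset[str] = POSITIVE_RESIDUES,
    hydrophobic: frozenset[str] = HYDROPHOBIC_RESIDUES,
    hydrophilic: frozenset[str] = HYDROPHILIC_RESIDUES,
) -> dict[str, float]:
    """Residue-set fractions; the hydropathy split is configurable because
    published tools disagree on the partition."""
    if set(negative) & set(positive):
        raise SequenceError("negative and positive residue sets overlap")
    n = len(p)
    in_set = lambda s: sum(1 for aa in p.residues if aa in s) / n
    return {
        "negative": in_set(negative),
        "positive": in_set(positive),
        "hydrophobic": in_set(hydrophobic),
        "hydrophilic": in_set(hydrophilic),
    }


def extinction_coefficient(p: ProteinSequence) -> dict[str, float]:
    """Molar extinction at 280 nm: 5500/Trp + 1490/Tyr (+125 per cystine)."""
    n_w = p.residues.count("W")
    n_y = p.residues.count("Y")
    n_c = p.residues.count("C")
    reduced = 5500.0 * n_w + 1490.0 * n_y
    return {"reduced": reduced, "cystines": reduced + 125.0 * (n_c // 2)}


@dataclass(frozen=True)
class PhysChemProfile:
    """The per-protein physico-chemical parameter bundle."""

    id: str
    species: str
    mw_kda: float
    isoelectric_point: float
    aliphatic_index: float
    sulfur_atoms: int
    hydrophobic_fraction: float
    hydrophilic_fraction: float
    neg_charged_fraction: float
    pos_charged_fraction: float
    instability_index: float
    gravy: float
    extinction_reduced: float
    extinction_cystines: float

    @property
    def stability_label(self) -> str:
        return "stable" if self.instability_index < 40.0 else "unstable"


def physchem_profile(p: ProteinSequence, pka_set: str = "expasy", **fraction_sets) -> PhysChemProfile:
    fr = charge_and_hydropathy_fractions(p, **fraction_sets)
    ext = extinction_coefficient(p)
    return PhysChemProfile(
        id=p.id,
        species=p.species,
        mw_kda=molecular_weight(p) / 1000.0,
        isoelectric_point=isoelectric_point(p, pka_set=pka_set),
        aliphatic_index=aliphatic_index(p),
        sulfur_atoms=sulfur_count(p),
        hydrophobic_fraction=fr["hydrophobic"],
        hydrophilic_fraction=fr["hydrophilic"],
        neg_charged_fraction=fr["negative"],
        pos_charged_fraction=fr["positive"],
        instability_index=instability_index(p),
        gravy=gravy(p),
        extinction_reduced=ext["reduced"],
        extinction_cystines=ext["cystines"],
    )


def physchem_grid(prots: SequenceSet, pka_set: str = "expasy") -> pd.DataFrame:
    """Species-by-parameter grid in the conventional column order."""
    rows = {}
    for p in prots:
        prof = physchem_profile(p, pka_set=pka_set)
        rows[p.species or p.id] = {
            "MW (kDa)": round(prof.mw_kda, 2),
            "IP": round(prof.isoelectric_point, 2),
            "AI": round(prof.aliphatic_index, 2),
            "S": prof.sulfur_atoms,
            "H-phobic": round(prof.hydrophobic_fraction, 2),
            "H-philic": round(prof.hydrophilic_fraction, 2),
            "-R": round(prof.neg_charged_fraction, 3),
            "+R": round(prof.pos_charged_fraction, 3),
            "II": round(prof.instability_index, 2),
            "GRAVY": round(prof.gravy, 3),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
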