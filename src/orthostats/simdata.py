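"""Synthetic ortholog-family generator with known truth.

Produces equal-length, ungapped, frame-valid CDS families related by a
random tree, so every analysis stage can be exercised against a known
topology, divergence level and codon bias without any external data.  The
default configuration emulates the shape of a small avian ortholog family:
8 taxa, 308 codons (307 sense codons plus a fixed terminal stop, i.e. a
924-nt CDS translating to a 307-residue protein), strong third-position
G+C bias (GC3 target 0.88) and a divergence level leaving roughly three
quarters of sites untouched.

Evolution is simulated at the nucleotide level along the tree: per branch
of length *t* each site is hit with probability ``1 - exp(-t)``; proposed
changes are transition/transversion weighted by ``kappa``; proposals that
create a stop codon are rejected and non-synonymous proposals are accepted
with probability ``omega_like``.  This is deliberately not a full codon
rate-matrix model — it is a generator whose statistical structure
(conserved/variable site mix, GC3, tree signal) the pipeline consumes and
which is easy to verify.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .phylo import PhyloTree
from .seqio import STANDARD_CODE, CodingSequence, GeneticCode, SequenceError, SequenceSet

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; ``length_codons`` counts the terminal stop."""

    seed: int
    n_taxa: int = 8
    length_codons: int = 308
    gc3_target: float = 0.88
    branch_scale: float = 0.05
    kappa: float = 2.0
    omega_like: float = 0.2

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise SequenceError("n_taxa must be >= 3")
        if self.length_codons < 2:
            raise SequenceError("length_codons must be >= 2 (sense + stop)")
        if not 0.0 <= self.gc3_target <= 1.0:
            raise SequenceError("gc3_target must be in [0, 1]")
        if self.branch_scale < 0:
            raise SequenceError("branch_scale must be >= 0")
        if self.kappa < 0:
            raise SequenceError("kappa must be >= 0")
        if not 0.0 <= self.omega_like <= 1.0:
            raise SequenceError("omega_like must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulated family."""

    tree: PhyloTree
    per_site_substitutions: np.ndarray  # accepted changes per sense-region site
    realized_root_gc3: float
    config: SimConfig


def sample_tree(
    n_taxa: int, branch_scale: float, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PhyloTree:
    """Random Yule topology with i.i.d. exponential branch lengths.

    Tips are named ``taxon_01`` .. ``taxon_NN``; reproducible under a fixed
    seed.
    """
    if n_taxa < 3:
        raise SequenceError("n_taxa must be >= 3")
    rng = rng if rng is not None else np.random.default_rng(seed)
    root = TreeNode(children=[TreeNode(), TreeNode()])
    tips = list(root.children)
    while len(tips) < n_taxa:
        victim = tips.pop(int(rng.integers(len(tips))))
        victim.extend([TreeNode(), TreeNode()])
        tips.extend(victim.children)
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"taxon_{i:02d}"
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(branch_scale)) if branch_scale > 0 else 0.0
    return PhyloTree(root=root)


def _sense_codons_by_gc3(code: GeneticCode) -> tuple[tuple[str, ...], tuple[str, ...]]:
    gc = tuple(c for c in code.sense_codons if c[2] in "GC")
    at = tuple(c for c in code.sense_codons if c[2] in "AT")
    return gc, at


def _propose(base: str, kappa: float, rng: np.random.Generator) -> str:
    """Transition with weight kappa, each transversion with weight 1."""
    ti = TRANSITION[base]
    tv = [b for b in BASES if b != base and b != ti]
    weights = np.array([kappa, 1.0, 1.0])
    probs = weights / weights.sum()
    return [ti, tv[0], tv[1]][rng.choice(3, p=probs)]


def _evolve_branch(
    seq: list[str], t: float, cfg: SimConfig, code: GeneticCode,
    rng: np.random.Generator, subs: np.ndarray,
) -> list[str]:
    out = list(seq)
    if t <= 0:
        return out
    p_hit = 1.0 - np.exp(-t)
    hits = np.nonzero(rng.random(len(out)) < p_hit)[0]
    for site in hits:
        old = out[site]
        new = _propose(old, cfg.kappa, rng)
        ci = (site // 3) * 3
        codon = out[ci : ci + 3]
        codon[site % 3] = new
        mutated = "".join(codon)
        if code[mutated] == "*":
            continue  # stop-creating proposals rejected
        original = "".join(out[ci : ci + 3])
        if code[mutated] != code[original] and rng.random() >= cfg.omega_like:
            continue  # non-synonymous proposal not accepted
        out[site] = new
        subs[site] += 1
    return out


#: fixed terminal stop appended to every simulated CDS (not evolved)
TERMINAL_STOP = "TGA"


def simulate_family(
    cfg: SimConfig, code: GeneticCode = STANDARD_CODE, tree: PhyloTree | None = None
) -> tuple[SequenceSet, SimTruth]:
    """Simulate one CDS family along a sampled (or supplied) tree.

    Returns the leaf CDS set (equal length, stop-free sense region plus a
    fixed terminal stop) and the :class:`SimTruth` with the generating tree,
    accepted-substitution counts per sense-region site and realized root
    GC3.  Pass ``tree`` to evolve along a fixed topology with fixed branch
    lengths (e.g. for recovery experiments); otherwise a Yule tree is
    sampled from the configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    if tree is None:
        tree = sample_tree(cfg.n_taxa, cfg.branch_scale, rng=rng)
    elif len(tree.leaf_names) < 3:
        raise SequenceError("supplied tree needs at least 3 leaves")
    n_sense = cfg.length_codons - 1
    gc_codons, at_codons = _sense_codons_by_gc3(code)
    root_codons = [
        gc_codons[rng.integers(len(gc_codons))]
        if rng.random() < cfg.gc3_target
        else at_codons[rng.integers(len(at_codons))]
        for _ in range(n_sense)
    ]
    root_seq = list("".join(root_codons))
    realized_gc3 = sum(c[2] in "GC" for c in root_codons) / n_sense
    subs = np.zeros(3 * n_sense, dtype=int)

    leaf_seqs: dict[str, str] = {}

    def descend(node: TreeNode, seq: list[str]) -> None:
        for child in node.children:
            child_seq = _evolve_branch(seq, child.length or 0.0, cfg, code, rng, subs)
            if child.is_tip():
                leaf_seqs[child.name] = "".join(child_seq)
            else:
                descend(child, child_seq)

    descend(tree.root, root_seq)
    records = [
        CodingSequence(
            id=name, residues=leaf_seqs[name] + TERMINAL_STOP, species=name,
            frame_checked=True,
        )
        for name in sorted(leaf_seqs)
    ]
    seqs = SequenceSet(records=records, kind="cds", provenance=f"simulated seed={cfg.seed}")
    truth = SimTruth(
        tree=tree, per_site_substitutions=subs,
        realized_root_gc3=realized_gc3, config=cfg,
    )
    return seqs, truth


#: residues drawn for transmembrane stretches / polar loops of the synthetic
#: membrane protein (strongly hydrophobic vs strongly hydrophilic)
_TM_RESIDUES = "ILVFA"
_LOOP_RESIDUES = "DEKRSTNQG"


def make_membrane_protein(
    n_tm: int = 6,
    tm_len: int = 30,
    loop_len: int = 25,
    seed: int = 0,
) -> "ProteinSequence":
    """Synthetic polytopic membrane protein with known helix layout.

    Alternates hydrophilic loops with ``n_tm`` strongly hydrophobic
    stretches; both termini are loops.  The default helix length (30) is
    wide enough that a 19-window Kyte-Doolittle caller with a 15-center
    minimum run finds exactly ``n_tm`` segments.  Used to exercise the
    topology stage, which random-composition simulated proteins cannot.
    """
    from .seqio import ProteinSequence

    rng = np.random.default_rng(seed)
    parts = []
    for i in range(n_tm):
        parts.append("".join(rng.choice(list(_LOOP_RESIDUES), size=loop_len)))
        parts.append("".join(rng.choice(list(_TM_RESIDUES), size=tm_len)))
    parts.append("".join(rng.choice(list(_LOOP_RESIDUES), size=loop_len)))
    return ProteinSequence(
        id=f"synthetic_carrier_{n_tm}tm", residues="".join(parts),
        species="synthetic",
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(out_dir: str | Path, seed: int) -> dict:
    """Write a deterministic fixture battery and a checksum manifest.

    Contents: two toy alignments (one per-column class of each kind, one
    all-identical), one default-configuration family with its true tree and
    per-site substitution counts, and ``manifest.json`` recording the
    configuration, seed and sha256 of every file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed)
    seqs, truth = simulate_family(cfg)

    files: dict[str, Path] = {}

    fam = out / "family_cds.fasta"
    with open(fam, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id} {rec.species}\n{rec.residues}\n")
    files["family_cds.fasta"] = fam

    nwk = out / "true_tree.nwk"
    with open(nwk, "w") as fh:
        fh.write(truth.tree.newick() + "\n")
    files["true_tree.nwk"] = nwk

    tsv = out / "per_site_substitutions.tsv"
    with open(tsv, "w") as fh:
        fh.write(f"# config={asdict(cfg)}\n")
        fh.write("site\tsubstitutions\n")
        for i, n in enumerate(truth.per_site_substitutions, start=1):
            fh.write(f"{i}\t{n}\n")
    files["per_site_substitutions.tsv"] = tsv

    toy = out / "toy_sites.fasta"
    # columns: conserved, singleton, parsimony-informative
    toy.write_text(">r1\nAAA\n>r2\nAAA\n>r3\nAAB\n>r4\nABB\n")
    files["toy_sites.fasta"] = toy

    ident = out / "toy_identical.fasta"
    ident.write_text(">r1\nMKV\n>r2\nMKV\n>r3\nMKV\n")
    files["toy_identical.fasta"] = ident

    manifest = {
        "seed": seed,
        "config": asdict(cfg),
        "realized_root_gc3": truth.realized_root_gc3,
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
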