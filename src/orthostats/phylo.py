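"""Jukes-Cantor protein distances, neighbor joining, bootstrap, Newick.

The distance between two equal-length proteins is the multiple-hit
corrected ``d = -(19/20) ln(1 - 20 p / 19)`` from the observed mismatch
proportion ``p``; the correction saturates at ``p >= 19/20``, where a large
sentinel distance is recorded with a warning rather than NaN.

Neighbor joining is the standard Saitou-Nei agglomeration on the Q
criterion, exact on additive matrices.  Ties in the Q minimization are
broken on the lexicographically smallest taxon pair (each cluster is
identified by its smallest leaf label), and negative branch-length
estimates are clamped to zero with the deficit moved to the sibling edge,
so output is fully deterministic.  Trees are scikit-bio ``TreeNode``
objects; bootstrap supports (percent of column-resampled replicates
containing each internal bipartition) are stored as internal node names,
the convention Newick viewers expect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .alignstats import Alignment
from .seqio import ProteinSequence, SequenceError

#: distance recorded for fully saturated pairs (p >= 19/20)
SATURATION_SENTINEL = 10.0


def p_distance(a: ProteinSequence | str, b: ProteinSequence | str) -> float:
    """Mismatch proportion between equal-length sequences."""
    ra = a.residues if isinstance(a, ProteinSequence) else a
    rb = b.residues if isinstance(b, ProteinSequence) else b
    if len(ra) != len(rb):
        raise SequenceError(f"length mismatch: {len(ra)} vs {len(rb)}")
    if not ra:
        raise SequenceError("empty sequences")
    return sum(x != y for x, y in zip(ra, rb)) / len(ra)


def jc_protein_distance(p: float) -> float:
    """Jukes-Cantor 20-state correction, d = -(19/20) ln(1 - 20p/19).

    Returns :data:`SATURATION_SENTINEL` (with a warning) when p >= 19/20.
    """
    if p < 0:
        raise SequenceError(f"proportion {p} < 0")
    if p >= 19.0 / 20.0:
        warnings.warn(f"p-distance {p:.3f} at or beyond saturation; recording sentinel")
        return SATURATION_SENTINEL
    return -(19.0 / 20.0) * math.log(1.0 - 20.0 * p / 19.0)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise SequenceError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise SequenceError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise SequenceError("distance matrix diagonal must be zero")
        if (m < 0).any():
            raise SequenceError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])

    def to_tsv(self, path: str | Path) -> None:
        """PHYLIP-like square format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.matrix):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def protein_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise Jukes-Cantor protein distances over an alignment."""
    n = aln.n_rows
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = jc_protein_distance(p_distance(aln.rows[i], aln.rows[j]))
    return DistanceMatrix(labels=tuple(aln.ids), matrix=m)


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root node) with optional supports."""

    root: TreeNode

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(sorted(t.name for t in self.root.tips()))

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the leaf side not
        containing the lexicographically smallest taxon."""
        all_leaves = set(self.leaf_names)
        anchor = min(all_leaves)
        parts = set()
        for node in self.root.non_tips(include_self=False):
            side = {t.name for t in node.tips()}
            if len(side) < 2 or len(all_leaves) - len(side) < 2:
                continue
            if anchor in side:
                side = all_leaves - side
            parts.add(frozenset(side))
        return frozenset(parts)

    def rf_distance(self, other: "PhyloTree") -> int:
        """Unrooted Robinson-Foulds distance (symmetric bipartition difference)."""
        if set(self.leaf_names) != set(other.leaf_names):
            raise SequenceError("trees have different leaf sets")
        return len(self.bipartitions() ^ other.bipartitions())

    def newick(self) -> str:
        buf = StringIO()
        self.root.write(buf)
        return buf.getvalue().strip()


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Requires >= 3 taxa; the result is unrooted with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise SequenceError("neighbor joining needs at least 3 taxa")
    # active clusters: id -> (tie-break label = smallest leaf, TreeNode)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=label) for i, label in enumerate(dm.labels)
    }
    tiebreak: dict[int, str] = {i: label for i, label in enumerate(dm.labels)}
    d = {(i, j): float(dm.matrix[i, j]) for i in range(n) for j in range(n) if i != j}
    active = list(range(n))
    next_id = n

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(i, j)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active) for i in active}
        best = None
        best_key = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((tiebreak[i], tiebreak[j])))
                key = (q, pair_key)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best
        dij = dist(i, j)
        limb_i = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        limb_j = dij - limb_i
        # clamp negative estimates, moving the deficit to the sibling edge
        if limb_i < 0:
            limb_j += limb_i
            limb_i = 0.0
        if limb_j < 0:
            limb_i += limb_j
            limb_j = 0.0
        limb_i, limb_j = max(limb_i, 0.0), max(limb_j, 0.0)
        child_i, child_j = nodes.pop(i), nodes.pop(j)
        child_i.length, child_j.length = limb_i, limb_j
        parent = TreeNode(children=[child_i, child_j])
        nodes[next_id] = parent
        tiebreak[next_id] = min(tiebreak[i], tiebreak[j])
        for k in active:
            if k in (i, j):
                continue
            duk = (dist(i, k) + dist(j, k) - dij) / 2.0
            d[(next_id, k)] = d[(k, next_id)] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = sorted(active, key=lambda a: tiebreak[a])
    li = (dist(i, j) + dist(i, k) - dist(j, k)) / 2.0
    lj = (dist(i, j) + dist(j, k) - dist(i, k)) / 2.0
    lk = (dist(i, k) + dist(j, k) - dist(i, j)) / 2.0
    children = []
    for a, length in ((i, li), (j, lj), (k, lk)):
        node = nodes.pop(a)
        node.length = max(length, 0.0)
        children.append(node)
    return PhyloTree(root=TreeNode(children=children))


def bootstrap_support(
    aln: Alignment, n_reps: int = 100, seed: int = 0
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Builds the tree from the full alignment, then resamples columns with
    replacement ``n_reps`` times, rebuilds NJ per replicate and labels each
    internal node with the percentage of replicates containing its
    bipartition.  Seed-reproducible.
    """
    if n_reps < 1:
        raise SequenceError("n_reps must be >= 1")
    main = neighbor_joining(protein_distance_matrix(aln))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in main.bipartitions()}
    cols = np.arange(aln.n_cols)
    for _ in range(n_reps):
        pick = rng.choice(cols, size=aln.n_cols, replace=True)
        rows = tuple("".join(row[c] for c in pick) for row in aln.rows)
        rep = neighbor_joining(
            protein_distance_matrix(Alignment(ids=aln.ids, rows=rows, kind=aln.kind))
        )
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_leaves = set(main.leaf_names)
    anchor = min(all_leaves)
    for node in main.root.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = all_leaves - side
        bp = frozenset(side)
        if bp in counts:
            node.name = str(round(100.0 * counts[bp] / n_reps))
    return main


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree(root=TreeNode.read(str(path)))
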