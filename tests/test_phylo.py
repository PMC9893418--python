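import math

import numpy as np
import pytest

from orthostats import (
    Alignment,
    SequenceError,
    bootstrap_support,
    jc_protein_distance,
    neighbor_joining,
    p_distance,
    protein_distance_matrix,
    read_newick,
    sample_tree,
    write_newick,
)
from orthostats.phylo import SATURATION_SENTINEL, DistanceMatrix, PhyloTree


def test_p_distance_cases():
    assert p_distance("AAAA", "AAAA") == 0.0
    assert p_distance("AAAA", "AAAB") == 0.25
    assert p_distance("AAAA", "AAAB") == p_distance("AAAB", "AAAA")
    with pytest.raises(SequenceError):
        p_distance("AA", "AAA")


def test_jc_distance_closed_form():
    assert jc_protein_distance(0.0) == 0.0
    assert jc_protein_distance(0.05) == pytest.approx(
        -(19 / 20) * math.log(1 - 20 * 0.05 / 19), abs=1e-12
    )
    assert jc_protein_distance(0.05) == pytest.approx(0.05136, abs=1e-5)


def test_jc_distance_inflates_p():
    for p in np.linspace(0.01, 0.9, 30):
        assert jc_protein_distance(p) >= p


def test_jc_saturation_sentinel_with_warning():
    with pytest.warns(UserWarning, match="saturation"):
        assert jc_protein_distance(0.96) == SATURATION_SENTINEL


def test_distance_matrix_validation():
    with pytest.raises(SequenceError, match="symmetric"):
        DistanceMatrix(labels=("a", "b"), matrix=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(SequenceError, match="diagonal"):
        DistanceMatrix(labels=("a", "b"), matrix=np.array([[1.0, 1.0], [1.0, 0.0]]))


def _path_length_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Independent oracle: pairwise tip-to-tip path lengths via scikit-bio."""
    dm = tree.root.tip_tip_distances()
    labels = tuple(dm.ids)
    return DistanceMatrix(labels=labels, matrix=np.asarray(dm.data))


def test_nj_three_taxa_closed_form():
    dm = DistanceMatrix(
        labels=("a", "b", "c"),
        matrix=np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
    )
    tree = neighbor_joining(dm)
    lengths = {t.name: t.length for t in tree.root.tips()}
    assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0), "c": pytest.approx(3.0)}


def test_nj_exact_on_hand_built_four_taxon_tree():
    # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
    dm = DistanceMatrix(
        labels=("a", "b", "c", "d"),
        matrix=np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 0.0 + 7.0, 0.0],
            ]
        ),
    )
    tree = neighbor_joining(dm)
    # topology: a-b vs c-d split
    assert frozenset({"c", "d"}) in tree.bipartitions() or frozenset({"a", "b"}) in tree.bipartitions()
    # branch lengths reproduce the generating additive matrix exactly
    oracle = _path_length_matrix(tree)
    for x in "abcd":
        for y in "abcd":
            if x != y:
                assert oracle[(x, y)] == pytest.approx(dm[(x, y)], abs=1e-9)


@pytest.mark.parametrize("n_taxa,seed", [(5, 1), (7, 2), (10, 3), (10, 4), (8, 5)])
def test_nj_recovers_random_additive_matrices(n_taxa, seed):
    """NJ is exact on additive matrices: topology and path lengths recovered."""
    true = sample_tree(n_taxa, branch_scale=1.0, seed=seed)
    dm = _path_length_matrix(true)
    inferred = neighbor_joining(dm)
    assert inferred.rf_distance(true) == 0
    back = _path_length_matrix(inferred)
    for i, x in enumerate(dm.labels):
        for y in dm.labels[i + 1 :]:
            assert back[(x, y)] == pytest.approx(dm[(x, y)], rel=1e-9, abs=1e-9)


def test_nj_requires_three_taxa():
    with pytest.raises(SequenceError):
        neighbor_joining(DistanceMatrix(labels=("a", "b"), matrix=np.zeros((2, 2))))


def test_nj_deterministic_under_ties():
    dm = DistanceMatrix(labels=("d", "c", "b", "a"), matrix=np.ones((4, 4)) - np.eye(4))
    t1 = neighbor_joining(dm)
    t2 = neighbor_joining(dm)
    assert t1.newick() == t2.newick()


def test_protein_distance_matrix(protein_alignment):
    dm = protein_distance_matrix(protein_alignment)
    assert dm.labels == protein_alignment.ids
    assert (np.diag(dm.matrix) == 0).all()
    assert (dm.matrix >= 0).all()


def test_bootstrap_single_replicate_supports_extreme(protein_alignment):
    tree = bootstrap_support(protein_alignment, n_reps=1, seed=0)
    supports = [int(n.name) for n in tree.root.non_tips() if n.name is not None]
    assert supports and all(s in (0, 100) for s in supports)


def test_bootstrap_identical_sequences_degenerate_ok():
    aln = Alignment(ids=("a", "b", "c", "d"), rows=("MKVL",) * 4)
    tree = bootstrap_support(aln, n_reps=3, seed=1)
    assert set(tree.leaf_names) == {"a", "b", "c", "d"}
    for tip in tree.root.tips():
        assert tip.length == pytest.approx(0.0)


def test_bootstrap_reproducible(protein_alignment):
    a = bootstrap_support(protein_alignment, n_reps=10, seed=7).newick()
    b = bootstrap_support(protein_alignment, n_reps=10, seed=7).newick()
    assert a == b


def test_bootstrap_long_internal_branch_high_support():
    """A simulated family with long internal branches gives the true
    bipartitions >= 95% support at 100 replicates."""
    from skbio import TreeNode

    from orthostats import Alignment as Aln
    from orthostats import SimConfig, simulate_family, translate_set
    from orthostats.phylo import PhyloTree as PT

    nwk = "((a:0.04,b:0.04):0.3,(c:0.04,d:0.04):0.3,(e:0.04,f:0.04):0.3);"
    truth = PT(root=TreeNode.read([nwk]))
    seqs, _ = simulate_family(SimConfig(seed=6, length_codons=500), tree=truth)
    aln = Aln.from_sequence_set(translate_set(seqs))
    tree = bootstrap_support(aln, n_reps=100, seed=11)
    assert tree.rf_distance(truth) == 0
    anchor = min(tree.leaf_names)
    all_leaves = set(tree.leaf_names)
    for node in tree.root.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = all_leaves - side
        if side in ({"c", "d"}, {"e", "f"}, {"a", "b"}):
            assert int(node.name) >= 95, side


def test_newick_round_trip_with_supports(tmp_path, protein_alignment):
    tree = bootstrap_support(protein_alignment, n_reps=5, seed=2)
    path = tmp_path / "tree.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert back.rf_distance(tree) == 0
    assert {n.name for n in back.root.non_tips() if n.name} == {
        n.name for n in tree.root.non_tips() if n.name
    }


def test_newick_canonical_three_leaf():
    dm = DistanceMatrix(
        labels=("b", "a", "c"),
        matrix=np.array([[0.0, 3.0, 5.0], [3.0, 0.0, 4.0], [5.0, 4.0, 0.0]]),
    )
    nwk = neighbor_joining(dm).newick()
    assert nwk == "(a:1.0,b:2.0,c:3.0);"
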