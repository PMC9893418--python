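import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orthostats import (
    CodingSequence,
    MarkovModel,
    ReferenceCodonTable,
    SequenceError,
    STANDARD_CODE,
    cai,
    codon_bias_summary,
    codon_usage,
    composition,
    expected_cai,
    rscu,
)
from orthostats.codonstats import composition_grid, codon_usage_grid, rna

SENSE = STANDARD_CODE.sense_codons
codon_lists = st.lists(st.sampled_from(SENSE), min_size=2, max_size=80)


def _cds(codons):
    return CodingSequence(id="x", residues="".join(codons))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_composition_all_gc():
    p = composition(_cds(["GGG", "CCC"]))
    assert p.gc0 == 100.0 and p.gc3 == 100.0


def test_composition_hand_tally():
    # ATG CAT: pos1 = A,C; pos2 = T,A; pos3 = G,T
    p = composition(_cds(["ATG", "CAT"]))
    assert p.base_pct["A"][1] == 50.0 and p.base_pct["C"][1] == 50.0
    assert p.base_pct["T"][2] == 50.0 and p.base_pct["A"][2] == 50.0
    assert p.base_pct["G"][3] == 50.0 and p.base_pct["T"][3] == 50.0
    assert p.gc0 == pytest.approx(100 * 2 / 6)
    assert p.gc1 == 50.0 and p.gc2 == 0.0 and p.gc3 == 50.0


def test_composition_position_percentages_sum_to_100(family_cds):
    for cds in family_cds:
        p = composition(cds)
        for k in range(4):
            assert sum(p.base_pct[b][k] for b in "ACGT") == pytest.approx(100.0)
            assert p.gc[k] == pytest.approx(p.base_pct["G"][k] + p.base_pct["C"][k])


@given(codons=codon_lists)
@settings(max_examples=30, deadline=None)
def test_composition_invariant_under_codon_shuffle(codons):
    rng = np.random.default_rng(0)
    shuffled = list(codons)
    rng.shuffle(shuffled)
    a, b = composition(_cds(codons)), composition(_cds(shuffled))
    assert a.gc == b.gc
    assert a.base_pct == b.base_pct


def test_composition_empty_errors():
    with pytest.raises(SequenceError):
        composition(CodingSequence(id="x", residues=""))


# ---------------------------------------------------------------------------
# codon usage and RSCU
# ---------------------------------------------------------------------------

def test_codon_usage_counts_each_codon_once():
    table = codon_usage(_cds(["ATG", "ATG"]))
    assert table.counts["ATG"] == 2
    assert table.total_sense == 2


@given(codons=codon_lists, add_stop=st.booleans())
@settings(max_examples=30, deadline=None)
def test_codon_usage_conservation(codons, add_stop):
    residues = "".join(codons) + ("TGA" if add_stop else "")
    table = codon_usage(CodingSequence(id="x", residues=residues))
    assert table.total_sense + sum(table.stop_counts.values()) == len(residues) // 3
    assert table.total_sense == len(codons)


def test_rscu_leucine_hand_example():
    # Leu counts {CTG: 4, CTA: 2}: n=6, total=6 -> RSCU 4.0 and 2.0
    values = rscu(codon_usage(_cds(["CTG"] * 4 + ["CTA"] * 2))).values
    assert values["CTG"] == pytest.approx(4.0)
    assert values["CTA"] == pytest.approx(2.0)
    assert values["CTC"] == 0.0


def test_rscu_uniform_usage_is_one():
    table = codon_usage(_cds(list(SENSE)))  # every sense codon exactly once
    values = rscu(table).values
    assert all(v == pytest.approx(1.0) for v in values.values())


@given(codons=codon_lists)
@settings(max_examples=50, deadline=None)
def test_rscu_family_sum_equals_degeneracy(codons):
    """Sum of RSCU over each present amino acid's codons == its degeneracy;
    Met/Trp RSCU == 1 when present; absent families report 0."""
    table = codon_usage(_cds(codons))
    values = rscu(table).values
    for aa in set(STANDARD_CODE.table.values()) - {"*"}:
        family = STANDARD_CODE.synonymous_family(aa)
        total = sum(values[c] for c in family)
        if table.family_total(aa):
            assert total == pytest.approx(len(family), abs=1e-9)
        else:
            assert total == 0.0
    if table.counts["ATG"]:
        assert values["ATG"] == pytest.approx(1.0)
    if table.counts["TGG"]:
        assert values["TGG"] == pytest.approx(1.0)


def test_codon_bias_summary_uniform_has_no_preferred():
    summary = codon_bias_summary(rscu(codon_usage(_cds(list(SENSE)))))
    assert summary.n_preferred == 0
    assert summary.n_unused == 0


def test_codon_bias_summary_counts_and_third_base():
    # CTG used 4x, CTA 2x -> CTG preferred; 59 sense codons unused
    summary = codon_bias_summary(rscu(codon_usage(_cds(["CTG"] * 4 + ["CTA"] * 2))))
    assert summary.n_preferred == 2  # CTG (4.0) and CTA (2.0) both > 1
    assert summary.n_unused == 59
    assert summary.third_base_of_preferred["G"] == 1
    assert summary.third_base_of_preferred["A"] == 1
    assert set(summary.preferred_set) == {"CUG", "CUA"}


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------

def _max_codon_cds(ref: ReferenceCodonTable) -> CodingSequence:
    """CDS built only from each amino acid's reference-maximal codon."""
    codons = []
    for aa in sorted(set(STANDARD_CODE.table.values()) - {"*"}):
        family = STANDARD_CODE.synonymous_family(aa)
        codons.append(max(family, key=lambda c: (ref.frequencies[c], c)))
    return _cds(codons)


def test_cai_is_one_for_maximal_codons(family_cds):
    ref = ReferenceCodonTable.from_counts(codon_usage(family_cds[0]))
    assert cai(_max_codon_cds(ref), ref) == pytest.approx(1.0)


informative_codon_lists = codon_lists.filter(
    lambda cs: any(c not in ("ATG", "TGG") for c in cs)
)


@given(codons=informative_codon_lists)
@settings(max_examples=30, deadline=None)
def test_cai_uniform_reference_is_one(codons):
    assert cai(_cds(codons), ReferenceCodonTable.uniform()) == pytest.approx(1.0)


@given(codons=informative_codon_lists)
@settings(max_examples=20, deadline=None)
def test_cai_invariant_to_codon_order(codons):
    freqs = {c: (i % 7) + 1.0 for i, c in enumerate(SENSE)}
    ref = ReferenceCodonTable(freqs)
    rng = np.random.default_rng(1)
    shuffled = list(codons)
    rng.shuffle(shuffled)
    assert cai(_cds(codons), ref) == pytest.approx(cai(_cds(shuffled), ref))


def test_cai_zero_frequency_floored_with_warning():
    freqs = {c: 1.0 for c in SENSE}
    freqs["CTG"] = 0.0
    ref = ReferenceCodonTable(freqs)
    with pytest.warns(UserWarning, match="floored"):
        value = cai(_cds(["CTG", "AAA"]), ref)
    assert 0.0 < value < 1.0


def test_reference_table_requires_all_sense_codons():
    with pytest.raises(SequenceError, match="missing"):
        ReferenceCodonTable({"ATG": 1.0})


def test_reference_table_readers_agree(tmp_path):
    rng = np.random.default_rng(3)
    freqs = {c: round(float(rng.uniform(1, 40)), 1) for c in SENSE}
    kazusa = tmp_path / "ref_kazusa.txt"
    fields = [f"{rna(c)} {freqs.get(c, 0.5)}( {int(freqs.get(c, 1) * 100)})"
              for c in list(SENSE) + ["TAA", "TAG", "TGA"]]
    kazusa.write_text("\n".join("  ".join(fields[i : i + 4]) for i in range(0, 64, 4)))
    tsv = tmp_path / "ref.tsv"
    tsv.write_text("# codon\tfreq\n" + "\n".join(f"{c}\t{freqs[c]}" for c in SENSE))
    a = ReferenceCodonTable.read(kazusa)
    b = ReferenceCodonTable.read(tsv)
    assert a.frequencies == b.frequencies
    assert set(a.frequencies) == set(SENSE)  # stops excluded


# ---------------------------------------------------------------------------
# expected CAI (Markov null)
# ---------------------------------------------------------------------------

def test_expected_cai_reproducible(family_cds):
    cds = family_cds[0]
    ref = ReferenceCodonTable.from_counts(codon_usage(cds))
    a = expected_cai(cds, ref, n_reps=5, seed=42)
    b = expected_cai(cds, ref, n_reps=5, seed=42)
    assert a == b
    assert 0.0 <= a.expected_cai <= 1.0


def test_expected_cai_uniform_reference_is_exactly_one(family_cds):
    cds = family_cds[0]
    res = expected_cai(cds, ReferenceCodonTable.uniform(), n_reps=3, seed=0)
    assert res.expected_cai == pytest.approx(1.0)
    assert res.expected_sd == pytest.approx(0.0)


def test_expected_cai_monte_carlo_stability(family_cds):
    """Null mean is stable across seeds at a few hundred replicates."""
    cds = family_cds[0]
    ref = ReferenceCodonTable.from_counts(codon_usage(cds))
    means = [expected_cai(cds, ref, n_reps=200, seed=s).expected_cai for s in (1, 2)]
    assert abs(means[0] - means[1]) < 0.03


def test_markov_model_validation():
    with pytest.raises(SequenceError):
        MarkovModel(initial=np.array([0.5, 0.5, 0.5, 0.5]), transition=np.eye(4))
    with pytest.raises(SequenceError):
        MarkovModel(initial=np.array([0.25] * 4), transition=np.ones((4, 4)))


def test_report_grids_shapes(family_cds):
    grid = composition_grid(family_cds)
    assert grid.shape == (len(family_cds), 12)
    assert list(grid.columns)[:2] == ["C", "G"] and list(grid.columns)[-1] == "GC-3"
    cu = codon_usage_grid(family_cds)
    assert cu.shape == (61, 2 * len(family_cds))
    assert "CUG(L)" in cu.index
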