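"""Pair classification, frequency matrices, null model, group comparison."""

import numpy as np
import pandas as pd
import pytest

from conftest import record_from
from mirduplex.duplex_map import GAP, PositionPair, align_record
from mirduplex.io_formats import NucleotideComposition
from mirduplex.pair_stats import (IntegrityError, PairFrequencyMatrix,
                                  classify_pair, compare_groups,
                                  conservation_count,
                                  count_mismatch_positions,
                                  expected_pair_frequencies,
                                  overall_composition, paired_unpaired_shares,
                                  site_composition)
from mirduplex.synthetic_data import SyntheticSpec, generate_records


def _pp(nt5, nt3, paired, coord=1):
    return PositionPair(coord=coord, nt5=nt5, nt3=nt3, paired=paired,
                        src5=None if nt5 == GAP else 10,
                        src3=None if nt3 == GAP else 40)


@pytest.mark.parametrize("nt5, nt3, paired, kind, symmetric", [
    ("G", "C", True, "WC", "G-C"),
    ("U", "A", True, "WC", "A-U"),
    ("U", "G", True, "WOBBLE", "G-U"),
    ("C", "C", False, "MISMATCH", "C-C"),
    ("U", "C", False, "MISMATCH", "C-U"),
    ("A", "C", False, "MISMATCH", "A-C"),
    ("G", GAP, False, "BULGE", "bulge"),
    (GAP, "A", False, "BULGE", "bulge"),
])
def test_classify_pair(nt5, nt3, paired, kind, symmetric):
    pc = classify_pair(_pp(nt5, nt3, paired))
    assert (pc.kind, pc.identity_symmetric) == (kind, symmetric)


def test_paired_noncanonical_is_an_integrity_error():
    with pytest.raises(IntegrityError, match="rec9"):
        classify_pair(_pp("A", "A", True), record_id="rec9")


def _alignments_from_spec(spec):
    records, truths = generate_records(spec)
    return [align_record(r) for r in records], truths


@pytest.fixture(scope="module")
def survey_alignments():
    spec = SyntheticSpec(n_records=150, seed=5)
    records, truths = generate_records(spec)
    return [align_record(r) for r in records], truths


def test_all_wc_alignment_pools_to_100_percent():
    spec = SyntheticSpec(
        n_records=1, seed=3,
        class_probs={c: {"G-C": 1.0} for c in
                     SyntheticSpec().coordinates()})
    alns, _ = _alignments_from_spec(spec)
    m = overall_composition(alns, mode="kind")
    assert m.value("WC", "all") == 100.0


def test_overall_recovers_planted_wobble_share():
    probs = {"G-C": 0.55, "A-U": 0.35, "G-U": 0.10}
    spec = SyntheticSpec(
        n_records=80, seed=17,
        class_probs={c: probs for c in SyntheticSpec().coordinates()})
    alns, _ = _alignments_from_spec(spec)
    m = overall_composition(alns, mode="kind")
    n = m.counts["all"].sum()
    se = 100 * np.sqrt(0.10 * 0.90 / n)
    assert abs(m.value("WOBBLE", "all") - 10.0) < 3 * se


def test_column_normalization_everywhere(survey_alignments):
    alns, _ = survey_alignments
    for mode in ("kind", "symmetric", "ordered"):
        m = site_composition(alns, [-1, 1, 2, 3, 21, 22, 23, 24], mode=mode)
        assert ((m.percentages.sum(axis=0) - 100.0).abs() < 0.01).all()
    overall = overall_composition(alns, mode="kind")
    assert abs(overall.percentages["all"].sum() - 100.0) < 0.01


def test_site_composition_single_record_is_degenerate():
    spec = SyntheticSpec(
        n_records=1, seed=2,
        class_probs={c: {"G-C": 1.0} for c in SyntheticSpec().coordinates()})
    alns, _ = _alignments_from_spec(spec)
    m = site_composition(alns, [1, 2, 3])
    assert (m.percentages.max(axis=0) == 100.0).all()
    assert (m.n_per_position == 1).all()


def test_symmetric_mode_invariant_under_arm_swap(survey_alignments):
    """Swapping every record's arms (nt5 <-> nt3) leaves symmetric-mode
    matrices unchanged."""
    import dataclasses
    alns, _ = survey_alignments
    swapped = []
    for aln in alns:
        rows = [dataclasses.replace(r, nt5=r.nt3, nt3=r.nt5,
                                    src5=r.src3, src3=r.src5)
                for r in aln.rows]
        swapped.append(dataclasses.replace(aln, rows=rows))
    coords = [-1, 1, 2, 3, 21]
    a = site_composition(alns, coords, mode="symmetric")
    b = site_composition(swapped, coords, mode="symmetric")
    assert a.counts.equals(b.counts)


def test_count_mismatch_positions_planted():
    # five planted mismatches per precursor at fixed coordinates
    base = {c: {"G-C": 1.0} for c in SyntheticSpec().coordinates()}
    for c in (2, 5, 8, 11, 14):
        base[c] = {"U-U": 1.0}
    spec = SyntheticSpec(n_records=20, seed=23, class_probs=base)
    alns, _ = _alignments_from_spec(spec)
    assert count_mismatch_positions(alns) == (100, 20)


def test_count_mismatch_positions_perfectly_paired_is_zero():
    spec = SyntheticSpec(
        n_records=5, seed=1,
        class_probs={c: {"A-U": 1.0} for c in SyntheticSpec().coordinates()})
    alns, _ = _alignments_from_spec(spec)
    assert count_mismatch_positions(alns) == (0, 0)


def test_conservation_count_planted_identity():
    base = {c: {"G-C": 1.0} for c in SyntheticSpec().coordinates()}
    base[9] = {"C-C": 1.0}
    spec = SyntheticSpec(n_records=12, seed=4, class_probs=base)
    alns, _ = _alignments_from_spec(spec)
    assert conservation_count(alns, 9, "C-C") == (12, 12)
    assert conservation_count(alns, 9, "U-U") == (0, 12)
    assert conservation_count([], 9, "C-C") == (0, 0)


class TestNullModel:
    def test_uniform_composition_gives_625_per_ordered_pair(self):
        null = expected_pair_frequencies({nt: 0.25 for nt in "ACGU"})
        assert np.allclose(null.expected_ordered.values, 6.25)
        assert null.expected_ordered.sum() == pytest.approx(100.0)
        assert null.expected_symmetric.sum() == pytest.approx(100.0)

    def test_cc_share_is_squared_frequency(self):
        null = expected_pair_frequencies(
            {"A": 0.3, "C": 0.3, "G": 0.2, "U": 0.2})
        assert null.expected_ordered["C-C"] == pytest.approx(9.0)

    def test_observed_equal_expected_gives_zero_everything(self):
        p = {nt: 0.25 for nt in "ACGU"}
        # counts exactly proportional to the uniform expectation
        from mirduplex.pair_stats import ORDERED_CLASSES
        counts = pd.DataFrame({1: [16] * 16}, index=list(ORDERED_CLASSES))
        obs = PairFrequencyMatrix(counts=counts,
                                  n_per_position=pd.Series({1: 256}),
                                  mode="ordered")
        null = expected_pair_frequencies(p, observed=obs)
        assert np.allclose(null.enrichment.values, 0.0)
        assert null.chisquare["statistic"].iloc[0] == pytest.approx(0.0)
        assert null.chisquare["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_zero_expected_nonzero_observed_is_inf_sentinel(self):
        from mirduplex.pair_stats import SYMMETRIC_CLASSES
        counts = pd.DataFrame(
            {1: [10] * len(SYMMETRIC_CLASSES)}, index=list(SYMMETRIC_CLASSES))
        obs = PairFrequencyMatrix(
            counts=counts,
            n_per_position=pd.Series({1: counts[1].sum()}), mode="symmetric")
        p = {"A": 0.5, "U": 0.5, "C": 0.0, "G": 0.0}
        with pytest.warns(UserWarning, match="zero expectation"):
            null = expected_pair_frequencies(p, observed=obs)
        assert null.enrichment.loc["G-C", 1] == np.inf

    def test_rejects_unnormalized_composition(self):
        with pytest.raises(ValueError, match="sum to 1"):
            expected_pair_frequencies({"A": 0.5, "C": 0.5, "G": 0.5, "U": 0.5})


class TestCompareGroups:
    def test_matrix_vs_itself_is_all_zero(self, survey_alignments):
        alns, _ = survey_alignments
        m = site_composition(alns, [-1, 1, 2, 3], mode="symmetric")
        table = compare_groups(m, m)
        assert (table["diff_pp"] == 0).all()
        assert not table["significant"].any()

    def test_planted_difference_is_the_extreme_cell(self):
        base = dict(SyntheticSpec().class_probs)
        spec_a = SyntheticSpec(n_records=120, seed=31, class_probs={
            2: {"G-C": 0.70, "A-U": 0.30}})
        spec_b = SyntheticSpec(n_records=120, seed=32, class_probs={
            2: {"G-C": 0.50, "A-U": 0.50}})
        alns_a, _ = _alignments_from_spec(spec_a)
        alns_b, _ = _alignments_from_spec(spec_b)
        coords = [1, 2, 3]
        table = compare_groups(
            site_composition(alns_a, coords, mode="symmetric"),
            site_composition(alns_b, coords, mode="symmetric"))
        extreme = table.loc[table["diff_pp"].abs().idxmax()]
        assert extreme["position"] == 2
        assert extreme["class"] in ("G-C", "A-U")

    def test_layout_mismatch_raises(self, survey_alignments):
        alns, _ = survey_alignments
        a = site_composition(alns, [1, 2], mode="symmetric")
        b = site_composition(alns, [1, 3], mode="symmetric")
        with pytest.raises(ValueError, match="layout"):
            compare_groups(a, b)


def test_paired_unpaired_dichotomy_folds_bulges():
    base = {c: {"G-C": 1.0} for c in SyntheticSpec().coordinates()}
    base[5] = {"U-U": 1.0}
    base[8] = {"bulge5": 1.0}
    spec = SyntheticSpec(n_records=4, seed=6, class_probs=base)
    records, _ = generate_records(spec)
    alns = [align_record(r) for r in records]
    m = overall_composition(alns, mode="kind")
    shares = paired_unpaired_shares(m, fold_bulges=True)
    n_rows = m.counts["all"].sum()
    # exactly two unpaired rows per record: the mismatch and the bulge
    assert shares.loc["all", "unpaired"] == pytest.approx(100 * 2 * 4 / n_rows)
    dropped = paired_unpaired_shares(m, fold_bulges=False)
    assert dropped.loc["all", "unpaired"] < shares.loc["all", "unpaired"]


def test_empty_window_raises(survey_alignments):
    alns, _ = survey_alignments
    with pytest.raises(ValueError, match="empty window"):
        overall_composition(alns, window=[999])
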