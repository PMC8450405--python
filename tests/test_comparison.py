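"""Median fold changes, direction calls and rank tests for tumor/normal
cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gagmap import (
    ExpressionMatrix,
    classify_direction,
    compare_cohorts,
    median_fold_change,
    rank_test,
    simulate_cohorts,
)
from gagmap.comparison import DOWN, UNCHANGED, UP
from gagmap.synthetic_data import CohortSimConfig

from oracles import exact_ranksum_pvalue


class TestMedianFoldChange:
    def test_identity_at_zero_expression(self):
        _, _, fc, _ = median_fold_change([0.0, 0.0], [0.0])
        assert fc == 1.0

    def test_pseudocounted_ratio(self):
        mt, mn, fc, fc_raw = median_fold_change([5.0, 5.0, 5.0], [1.0, 1.0, 1.0])
        assert (mt, mn) == (5.0, 1.0)
        assert fc == pytest.approx(3.0)
        assert fc_raw == pytest.approx(5.0)

    def test_interpolated_medians(self):
        # medians 2 and 4 -> (2+1)/(4+1)
        _, _, fc, _ = median_fold_change([0.0, 2.0, 4.0], [4.0, 4.0, 10.0])
        assert fc == pytest.approx(0.6)

    def test_empty_arm_is_an_error(self):
        with pytest.raises(ValueError):
            median_fold_change([], [1.0])


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "fc,expected",
        [(0.5, DOWN), (0.667, UNCHANGED), (1.0, UNCHANGED),
         (1.5, UNCHANGED), (3.0, UP)],
    )
    def test_boundary_grid(self, fc, expected):
        assert classify_direction(fc) == expected

    def test_thresholds_are_strict(self):
        assert classify_direction(1.5 + 1e-9) == UP
        assert classify_direction(1.0 / 1.5) == UNCHANGED
        assert classify_direction(1.0 / 1.5 - 1e-9) == DOWN

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_antisymmetric_under_reciprocal(self, fc):
        flipped = {UP: DOWN, DOWN: UP, UNCHANGED: UNCHANGED}
        assert classify_direction(1.0 / fc) == flipped[classify_direction(fc)]

    def test_nonpositive_fc_rejected(self):
        with pytest.raises(ValueError):
            classify_direction(0.0)


class TestRankTest:
    def test_complete_separation_small_n(self):
        stat, p = rank_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert stat == 0.0
        assert p == pytest.approx(0.1)  # 2/20 rank assignments as extreme

    def test_identical_samples_near_null_center(self):
        _, p = rank_test([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
        assert p > 0.9

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (6, 6), (5, 3)])
    def test_exact_p_matches_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(5):
            a = rng.normal(0, 1, na)
            b = rng.normal(0.8, 1, nb)
            _, p = rank_test(a, b)
            assert p == pytest.approx(exact_ranksum_pvalue(a, b), abs=1e-12)

    def test_large_planted_shift_is_significant(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(2.0, 0.5, 200)
        shifted = 8.0 * rng.lognormal(2.0, 0.5, 200)
        _, p = rank_test(shifted, base)
        assert p < 1e-4

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            rank_test([1.0, 2.0], [3.0, 4.0, 5.0])

    def test_paired_variant(self):
        a = np.arange(1.0, 11.0)
        _, p_same = rank_test(a, a, paired=True)
        assert p_same == 1.0
        _, p_shift = rank_test(a + 3.0, a, paired=True)
        assert p_shift < 0.01
        with pytest.raises(ValueError):
            rank_test([1.0, 2.0, 3.0], [1.0, 2.0], paired=True)


@pytest.fixture(scope="module")
def planted(kb):
    cfg = CohortSimConfig(
        planted_fc={"CHST3": 4.0, "DSE": 0.4, "VCAN": 4.8}, seed=17
    )
    tumor, normal, truth = simulate_cohorts(cfg, kb)
    return compare_cohorts(kb, tumor, normal), truth


class TestCompareCohorts:
    def test_identical_cohorts_all_unchanged(self, kb, random_full_matrix):
        res = compare_cohorts(kb, random_full_matrix, random_full_matrix)
        assert all(r.fc == 1.0 for r in res.records)
        assert all(r.direction == UNCHANGED for r in res.records)

    def test_every_reaction_has_exactly_one_record(self, planted, kb):
        res, _ = planted
        rx_records = [r for r in res.records if r.level == "reaction"]
        assert sorted(r.target_id for r in rx_records) == sorted(kb.reaction_ids)

    def test_planted_genes_recovered(self, planted):
        res, truth = planted
        for gene, expected in truth.expected_direction.items():
            assert res.record(gene, "gene").direction == expected

    def test_non_kb_gene_passes_through_flagged(self, planted):
        res, _ = planted
        rec = res.record("VCAN", "gene")
        assert rec.in_kb is False
        assert rec.direction == UP

    def test_planted_up_gene_lifts_its_reaction(self, planted):
        res, _ = planted
        # CHST3 is the sole gene of CS/DS sulfation step 4
        assert res.record("csds_sulfation.04.galnac6s", "reaction").direction == UP

    def test_swapping_cohorts_inverts_fc(self, kb):
        cfg = CohortSimConfig(planted_fc={"CHST3": 4.0}, seed=23,
                              n_tumor=20, n_normal=20)
        tumor, normal, _ = simulate_cohorts(cfg, kb)
        fwd = compare_cohorts(kb, tumor, normal, compute_p=False)
        rev = compare_cohorts(kb, normal, tumor, compute_p=False)
        flipped = {UP: DOWN, DOWN: UP, UNCHANGED: UNCHANGED}
        for r in fwd.records:
            s = rev.record(r.target_id, r.level)
            assert r.fc * s.fc == pytest.approx(1.0, abs=1e-12)
            if r.fc != 1.0 and not (
                r.direction == UNCHANGED and s.direction == UNCHANGED
            ):
                assert s.direction == flipped[r.direction]

    def test_disjoint_gene_sets_error(self, kb):
        a = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0], "s2": [1.0], "s3": [1.0]}, index=["XYLT1"]),
            {f"s{i}": "tumor" for i in (1, 2, 3)},
        )
        b = ExpressionMatrix(
            pd.DataFrame({"t1": [1.0], "t2": [1.0], "t3": [1.0]}, index=["CHST3"]),
            {f"t{i}": "normal" for i in (1, 2, 3)},
        )
        with pytest.raises(ValueError, match="share no gene"):
            compare_cohorts(kb, a, b)

    def test_reaction_order_flag_consistent_on_clean_signal(self, kb):
        cfg = CohortSimConfig(planted_fc={"CHST3": 4.0}, seed=29,
                              n_tumor=30, n_normal=30, noise_sd=0.2)
        tumor, normal, _ = simulate_cohorts(cfg, kb)
        agg_first = compare_cohorts(kb, tumor, normal, compute_p=False)
        med_first = compare_cohorts(
            kb, tumor, normal, compute_p=False,
            reaction_order="median_then_aggregate",
        )
        rid = "csds_sulfation.04.galnac6s"
        a = agg_first.record(rid, "reaction").fc
        b = med_first.record(rid, "reaction").fc
        assert a == pytest.approx(b, rel=0.15)

    def test_bh_adds_monotone_q_values(self, kb):
        cfg = CohortSimConfig(planted_fc={"CHST3": 4.0}, seed=31,
                              n_tumor=10, n_normal=10)
        tumor, normal, _ = simulate_cohorts(cfg, kb)
        res = compare_cohorts(kb, tumor, normal, bh=True)
        assert all(r.q_value is not None for r in res.records)
        assert all(r.q_value >= r.p_value - 1e-15 for r in res.records)
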