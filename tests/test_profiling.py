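"""Row z-scores, Pearson correlation and hierarchical tissue clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gagmap import (
    ExpressionMatrix,
    hierarchical_cluster,
    pearson_matrix,
    reaction_activity,
    simulate_tissues,
    zscore_rows,
)
from gagmap.synthetic_data import TissueSimConfig

from oracles import pearson_r_formula


class TestZScore:
    def test_simple_row(self):
        z = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"]))
        assert z.values.loc["r"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_two_column_row_closed_form(self):
        # sd(0,10; ddof=1) = 10/sqrt(2) -> z = +-1/sqrt(2)
        z = zscore_rows(pd.DataFrame([[0.0, 10.0]], index=["r"]))
        assert z.values.loc["r"].tolist() == pytest.approx(
            [-0.70710678, 0.70710678]
        )

    def test_constant_row_zeroed_and_flagged(self):
        z = zscore_rows(pd.DataFrame([[5.0, 5.0, 5.0]], index=["flat"]))
        assert (z.values.loc["flat"] == 0).all()
        assert z.zero_variance_rows == ["flat"]

    def test_single_column_is_an_error(self):
        with pytest.raises(ValueError):
            zscore_rows(pd.DataFrame([[1.0]], index=["r"]))

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(0, 9, size=(20, 12)))
        z = zscore_rows(m).values.to_numpy()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(8, 6)))
        once = zscore_rows(m).values
        twice = zscore_rows(once).values
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)


class TestPearson:
    def test_self_correlation_and_negation(self):
        x = [1.0, 2.0, 3.0, 7.0]
        df = pd.DataFrame([x, [-v for v in x]], index=["g", "neg"])
        r = pearson_matrix(df).values
        assert r.at["g", "g"] == 1.0
        assert r.at["g", "neg"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 2.0, 4.0]
        df = pd.DataFrame([x, y], index=["x", "y"])
        r = pearson_matrix(df).values.at["x", "y"]
        assert r == pytest.approx(pearson_r_formula(x, y), abs=1e-12)
        # cov 4.5, variances 5 and 4.75 -> 4.5 / sqrt(23.75)
        assert r == pytest.approx(0.9233805168766388, abs=1e-9)

    def test_random_vectors_match_formula_to_1e12(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(10, 30)),
                          index=[f"g{i}" for i in range(10)])
        r = pearson_matrix(df).values
        for i in range(10):
            for j in range(i + 1, 10):
                expected = pearson_r_formula(df.iloc[i], df.iloc[j])
                assert r.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance_with_positive_scale(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(4, 15)))
        scaled = df.mul([2.0, 0.5, 7.0, 1.3], axis=0).add(
            [10.0, -3.0, 0.0, 5.0], axis=0
        )
        r1 = pearson_matrix(df).values.to_numpy()
        r2 = pearson_matrix(scaled).values.to_numpy()
        assert np.allclose(r1, r2, atol=1e-10)

    def test_constant_gene_dropped_and_flagged(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [3.0, 1.0, 2.0]],
            index=["a", "flat", "b"],
        )
        r = pearson_matrix(df)
        assert r.dropped_genes == ["flat"]
        assert list(r.values.index) == ["a", "b"]

    def test_fewer_than_two_usable_genes_is_an_error(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            pearson_matrix(df)

    def test_explicit_gene_subset(self, kb, random_full_matrix):
        subset = kb.genes[:20]
        r = pearson_matrix(random_full_matrix, genes=subset)
        assert list(r.values.index) == subset


class TestClustering:
    def test_identical_columns_merge_first(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]}
        )
        res = hierarchical_cluster(df, axis="cols")
        assert res.cut(2)["a"] == res.cut(2)["b"]
        assert res.cut(2)["a"] != res.cut(2)["c"]

    def test_two_items_single_merge(self):
        df = pd.DataFrame({"b": [1.0, 2.0], "a": [3.0, 4.0]})
        res = hierarchical_cluster(df, axis="cols")
        assert res.linkage.shape == (1, 4)
        assert sorted(res.leaf_order) == ["a", "b"]

    def test_leaf_order_is_permutation(self, kb, random_full_matrix):
        act = reaction_activity(kb, random_full_matrix)
        res = hierarchical_cluster(act.values, axis="cols")
        assert sorted(res.leaf_order) == sorted(random_full_matrix.sample_ids)

    def test_planted_archetypes_recovered_perfectly_at_low_noise(self):
        m, truth = simulate_tissues(TissueSimConfig(delta=3.0, noise_sd=0.1, seed=0))
        from gagmap import load_kb

        act = reaction_activity(load_kb(), m)
        z = zscore_rows(act.values)
        cut = hierarchical_cluster(z.values, axis="cols").cut(2)
        tissues = list(cut)
        ari = adjusted_rand_score(
            [truth.archetype_assignment[t] for t in tissues],
            [cut[t] for t in tissues],
        )
        assert ari == 1.0
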