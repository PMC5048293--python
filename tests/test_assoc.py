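import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from exprest import assoc
from exprest.io_formats import GeneSet, GeneSetCollection
from exprest.validation import (
    bh_oracle,
    fisher_oracle,
    spearman_perm_oracle,
    ward_oracle_heights,
)


class TestSpearmanScan:
    @staticmethod
    def _panel(rows, samples):
        return pd.DataFrame(rows, columns=samples)

    def test_identical_feature_gives_rho_one(self):
        s = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        panel = self._panel([[1.0, 2, 3, 4, 5]], list("abcde"))
        table = assoc.spearman_scan(s, panel)
        assert table["rho"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        # scores (1,2,3), feature (3,1,2): d = (-2,1,1), rho = 1 - 6*6/(3*8) = -0.5
        s = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        panel = self._panel([[3.0, 1, 2, 4]], list("abcd"))
        table = assoc.spearman_scan(s, panel)
        expected = stats.spearmanr([1, 2, 3, 4], [3, 1, 2, 4]).statistic
        assert table["rho"].iloc[0] == pytest.approx(expected)

    def test_three_point_rho_value(self):
        rho = stats.spearmanr([1, 2, 3], [3, 1, 2]).statistic
        assert rho == pytest.approx(-0.5)

    def test_constant_features_skipped(self):
        s = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        panel = pd.DataFrame([[1.0] * 5, [1.0, 2, 3, 4, 5]],
                             index=["flat", "ok"], columns=list("abcde"))
        table = assoc.spearman_scan(s, panel)
        assert table.attrs["skipped"] == ["flat"]
        assert list(table.index) == ["ok"]

    def test_monotone_transform_invariance(self, rng):
        s = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        panel = pd.DataFrame(rng.normal(size=(5, 30)), columns=s.index)
        t0 = assoc.spearman_scan(s, panel)
        t1 = assoc.spearman_scan(np.exp(s), panel.apply(np.tanh))
        assert np.allclose(t0["rho"], t1["rho"])
        assert np.allclose(t0["p"], t1["p"])

    def test_exact_permutation_matches_oracle(self, rng):
        for _ in range(3):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            assert assoc.spearman_exact_p(x, y) == pytest.approx(
                spearman_perm_oracle(x, y), abs=1e-12)

    def test_no_shared_samples_error(self):
        s = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        panel = pd.DataFrame([[1.0, 2, 3, 4]], columns=list("wxyz"))
        with pytest.raises(ValueError, match="no shared samples"):
            assoc.spearman_scan(s, panel)


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(assoc.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert assoc.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            assoc.bh_adjust([])

    @given(st.integers(0, 10**6))
    def test_matches_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 40)))
        np.testing.assert_allclose(assoc.bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestMeanShiftTtest:
    def test_hand_example(self):
        res = assoc.mean_shift_ttest([1.0, 2, 3, 4, 5, 6],
                                     [0, 0, 0, 1, 1, 1])
        assert res.delta == pytest.approx(3.0)
        assert res.t == pytest.approx(3.0 / math.sqrt(2.0 / 3.0), rel=1e-3)
        assert res.p == pytest.approx(2 * stats.t.sf(res.t, 4), rel=1e-6)
        assert res.cohen_d == pytest.approx(3.0)

    def test_identical_groups_null(self):
        res = assoc.mean_shift_ttest([1.0, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_small_group_and_zero_variance_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            assoc.mean_shift_ttest([1.0, 2, 3], [0, 0, 1])
        with pytest.raises(ValueError, match="variance"):
            assoc.mean_shift_ttest([2.0, 2, 2, 2], [0, 0, 1, 1])


class TestAnovaTukey:
    def test_hand_computed_f(self):
        res = assoc.anova_tukey([1.0, 2, 3, 4, 5, 6], [0, 0, 1, 1, 2, 2])
        assert res.F == pytest.approx(16.0)

    def test_equal_groups_null(self):
        res = assoc.anova_tukey([1.0, 2, 3] * 3,
                                [0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert res.F == pytest.approx(0.0)
        assert np.allclose(res.tukey["p"], 1.0)

    def test_singleton_group_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            assoc.anova_tukey([1.0, 2, 3], [0, 0, 1])

    def test_tukey_familywise_error_controlled(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(np.arange(4), 10)
        fw = 0
        reps = 200
        for _ in range(reps):
            res = assoc.anova_tukey(rng.normal(size=40), labels)
            if (res.tukey["p"] < 0.05).any():
                fw += 1
        assert fw / reps <= 0.07


class TestPearsonAssoc:
    def test_perfect_linear(self):
        x = np.arange(1.0, 6)
        r, p = assoc.pearson_assoc(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_hand_value(self):
        r, _ = assoc.pearson_assoc([1.0, 2, 3, 4], [2.0, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            assoc.pearson_assoc([1.0, 1, 1], [1.0, 2, 3])


class TestFisherEnrichment:
    def test_hand_enumeration(self):
        _, p = assoc.fisher_enrichment(3, 4, 4, 8)
        assert p == pytest.approx(17 / 70, abs=1e-12)

    def test_zero_overlap_greater_is_one(self):
        _, p = assoc.fisher_enrichment(0, 4, 4, 20)
        assert p == pytest.approx(1.0)

    def test_inconsistent_margins(self):
        with pytest.raises(ValueError):
            assoc.fisher_enrichment(5, 4, 4, 8)
        with pytest.raises(ValueError):
            assoc.fisher_enrichment(0, 6, 6, 8)

    def test_matches_enumeration_oracle_small_universe(self):
        for N in (5, 9, 12):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        _, p = assoc.fisher_enrichment(k, K, n, N)
                        assert p == pytest.approx(fisher_oracle(k, K, n, N),
                                                  abs=1e-10)


class TestKsShift:
    def test_identical_samples(self):
        x = np.arange(10.0)
        d, p = assoc.ks_shift_test(x, x.copy())
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self, rng):
        x = rng.uniform(0.0, 0.5, size=50)
        y = rng.uniform(0.5, 1.0, size=50)
        d, p = assoc.ks_shift_test(x, y)
        assert d == pytest.approx(1.0)
        assert p < 1e-10

    def test_empty_sample_error(self):
        with pytest.raises(ValueError, match="empty"):
            assoc.ks_shift_test([], [1.0])


class TestGeneSetScan:
    @staticmethod
    def _collection():
        return GeneSetCollection({
            "target": GeneSet("d", [f"g{i}" for i in range(10)]),
            "other": GeneSet("d", [f"h{i}" for i in range(10)]),
        })

    def test_full_set_query_ranks_first(self):
        universe = [f"g{i}" for i in range(10)] + [f"h{i}" for i in range(10)]
        table = assoc.hypergeom_geneset_scan([f"g{i}" for i in range(10)],
                                             self._collection(), universe)
        assert table.index[0] == "target"

    def test_per_set_p_equals_direct_fisher(self):
        universe = [f"g{i}" for i in range(10)] + [f"h{i}" for i in range(10)]
        query = ["g0", "g1", "g2", "h0"]
        table = assoc.hypergeom_geneset_scan(query, self._collection(), universe)
        _, p = assoc.fisher_enrichment(3, 10, 4, 20)
        assert table.loc["target", "p"] == pytest.approx(p)

    def test_adjusted_not_below_raw(self, rng):
        universe = [f"g{i}" for i in range(10)] + [f"h{i}" for i in range(10)]
        query = list(rng.choice(universe, size=6, replace=False))
        table = assoc.hypergeom_geneset_scan(query, self._collection(), universe)
        assert (table["p_adj"] >= table["p"] - 1e-12).all()

    def test_empty_universe_error(self):
        with pytest.raises(ValueError, match="universe"):
            assoc.hypergeom_geneset_scan([], self._collection(), [])


class TestDrugScan:
    def test_noiseless_fold_change(self):
        groups = pd.Series(["high", "high", "low", "low"], index=list("abcd"))
        ic50 = pd.DataFrame([[-2.0, -2.0, 0.0, 0.0]], index=["d"],
                            columns=list("abcd"))
        table = assoc.drug_sensitivity_scan(groups, ic50)
        assert table.loc["d", "fold_change"] == pytest.approx(math.exp(-2))

    def test_identical_arms(self):
        groups = pd.Series(["high", "high", "low", "low"], index=list("abcd"))
        ic50 = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["d"], columns=list("abcd"))
        table = assoc.drug_sensitivity_scan(groups, ic50)
        assert table.loc["d", "fold_change"] == pytest.approx(1.0)
        assert table.loc["d", "p"] == pytest.approx(1.0)

    def test_empty_arm_skipped_with_report(self):
        groups = pd.Series(["high", "high", "low", "low"], index=list("abcd"))
        ic50 = pd.DataFrame([[1.0, 2.0, np.nan, np.nan], [1.0, 2.0, 0.5, 1.5]],
                            index=["broken", "ok"], columns=list("abcd"))
        table = assoc.drug_sensitivity_scan(groups, ic50)
        assert table.attrs["skipped"] == ["broken"]
        assert list(table.index) == ["ok"]


class TestMutationScan:
    def test_planted_mutation_ranks_first(self, rng):
        n = 200
        z = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        carrier = (z.to_numpy() + rng.normal(scale=0.5, size=n) > 0.5).astype(int)
        null = (rng.uniform(size=n) < 0.3).astype(int)
        panel = pd.DataFrame([carrier, null], index=["driver", "noise"],
                             columns=z.index)
        table = assoc.mutation_scan(z, panel)
        assert table["p_adj"].idxmin() == "driver"
        assert table.loc["driver", "delta"] > 0


class TestWardClustering:
    def test_two_genes_keep_input_order(self, rng):
        df = pd.DataFrame(rng.normal(size=(2, 8)), index=["g1", "g2"])
        assert assoc.ward_corr_cluster_order(df).order == ["g1", "g2"]

    def test_duplicate_profiles_adjacent(self, rng):
        base = rng.normal(size=8)
        df = pd.DataFrame([base, rng.normal(size=8), base + 0.0,
                           rng.normal(size=8)],
                          index=["dupA", "x", "dupB", "y"])
        order = assoc.ward_corr_cluster_order(df).order
        assert abs(order.index("dupA") - order.index("dupB")) == 1

    def test_merge_heights_match_lance_williams_oracle(self, rng):
        X = rng.normal(size=(6, 10))
        result = assoc.ward_corr_cluster_order(pd.DataFrame(X))
        np.testing.assert_allclose(result.linkage[:, 2], ward_oracle_heights(X),
                                   atol=1e-8)

    def test_zero_variance_gene_named(self):
        df = pd.DataFrame([[1.0, 1, 1, 1], [1.0, 2, 3, 4]], index=["flat", "g"])
        with pytest.raises(ValueError, match="flat"):
            assoc.ward_corr_cluster_order(df)
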