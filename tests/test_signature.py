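import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exprest.io_formats import ExpressionMatrix
from exprest.signature import (
    CorrelationProfile,
    SignatureDefinition,
    compute_rest_score,
    derive_signature,
    dichotomize_by_median,
    pearson_profile,
)
from exprest.synthetic import SimulationConfig, generate_cohort


def _profile(mapping, cohort="A", seed="seed"):
    return CorrelationProfile(cohort=cohort, seed_gene=seed,
                              r=pd.Series(mapping), n=50)


class TestPearsonProfile:
    def test_seed_self_correlation_is_one(self, small_expr):
        prof = pearson_profile(small_expr, "REST")
        assert prof.r["REST"] == 1.0

    def test_linear_and_antilinear_genes(self, small_expr):
        prof = pearson_profile(small_expr, "REST")
        assert prof.r["POSG"] == pytest.approx(1.0)
        assert prof.r["NEGG"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[1.0, 2, 3, 4], [2.0, 1, 4, 3]], index=["seed", "g"],
            columns=list("abcd")))
        prof = pearson_profile(expr, "seed")
        assert prof.r["g"] == pytest.approx(0.6)

    def test_zero_variance_gene_excluded_and_reported(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[1.0, 2, 3], [5.0, 5, 5]], index=["seed", "flat"],
            columns=list("abc")))
        prof = pearson_profile(expr, "seed")
        assert "flat" not in prof.r.index
        assert prof.dropped == ["flat"]

    def test_seed_errors(self, small_expr):
        with pytest.raises(ValueError, match="absent"):
            pearson_profile(small_expr, "NOPE")
        flat = ExpressionMatrix(pd.DataFrame(
            [[1.0, 1, 1], [1.0, 2, 3]], index=["seed", "g"], columns=list("abc")))
        with pytest.raises(ValueError, match="zero variance"):
            pearson_profile(flat, "seed")


def _brute_filter(ra, rb, cutoff):
    """Independent re-statement of the membership rule."""
    keep_pos, keep_neg = [], []
    for g in ra:
        if g == "seed" or g not in rb:
            continue
        a, b = ra[g], rb[g]
        if np.sign(a) == np.sign(b) and min(abs(a), abs(b)) >= cutoff and a != 0:
            (keep_pos if a > 0 else keep_neg).append(g)
    return keep_pos, keep_neg


class TestDeriveSignature:
    CASE_A = {"A": 0.9, "B": 0.5, "C": -0.2, "D": -0.6, "seed": 1.0}
    CASE_B = {"A": 0.8, "B": -0.4, "C": -0.25, "D": -0.35, "seed": 1.0}

    def test_rule_application_matches_brute_filter(self):
        signature = derive_signature(_profile(self.CASE_A), _profile(self.CASE_B),
                                     cutoff=0.3)
        pos, neg = _brute_filter(self.CASE_A, self.CASE_B, 0.3)
        assert signature.rest_type == ["seed"] + pos
        assert signature.restless_type == neg
        assert signature.rest_type == ["seed", "A"]   # B sign-flips, C below cutoff
        assert signature.restless_type == ["D"]       # (-0.6, -0.35) joins G_L

    def test_cutoff_zero_keeps_all_sign_consistent(self):
        ra = {"A": 0.9, "B": 0.5, "C": 0.1, "seed": 1.0}
        rb = {"A": 0.8, "B": 0.4, "C": 0.2, "seed": 1.0}
        signature = derive_signature(_profile(ra), _profile(rb), cutoff=0.0)
        assert set(signature.rest_type) == {"seed", "A", "B", "C"}

    def test_exclude_seed_flag(self):
        signature = derive_signature(_profile(self.CASE_A), _profile(self.CASE_B),
                                     cutoff=0.3, include_seed=False)
        assert "seed" not in signature.rest_type

    def test_no_shared_genes_error(self):
        with pytest.raises(ValueError, match="no genes beyond the seed|share no genes"):
            derive_signature(_profile({"seed": 1.0, "X": 0.5}),
                             _profile({"seed": 1.0, "Y": 0.5}), cutoff=0.3)

    def test_empty_signature_error(self):
        ra = {"A": 0.1, "seed": 1.0}
        rb = {"A": 0.1, "seed": 1.0}
        with pytest.raises(ValueError, match="empty signature"):
            derive_signature(_profile(ra), _profile(rb), cutoff=0.5,
                             include_seed=False)

    @given(st.integers(0, 10**6))
    def test_random_profiles_match_brute_filter(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        ra = dict(zip(genes, rng.uniform(-1, 1, 30)), seed=1.0)
        rb = dict(zip(genes, rng.uniform(-1, 1, 30)), seed=1.0)
        pos, neg = _brute_filter(ra, rb, 0.3)
        if not pos and not neg:
            return
        signature = derive_signature(_profile(ra), _profile(rb), cutoff=0.3,
                                     include_seed=False)
        assert set(signature.rest_type) == set(pos)
        assert set(signature.restless_type) == set(neg)


class TestRestScore:
    def test_worked_three_gene_example(self):
        expr = ExpressionMatrix(pd.DataFrame({"s1": [2.0, 4.0, 1.0]},
                                             index=["a", "b", "c"]))
        signature = SignatureDefinition(None, ["a", "b"], ["c"])
        scores = compute_rest_score(expr, signature, standardize="none")
        assert scores.scores["s1"] == pytest.approx(2.0)

    def test_per_sample_shift_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 4)),
                          index=list("abcdef"), columns=list("wxyz"))
        signature = SignatureDefinition(None, ["a", "b", "c"], ["d", "e"])
        s0 = compute_rest_score(ExpressionMatrix(df), signature, "none").scores
        shifted = df + rng.normal(size=(1, 4))  # per-sample additive offsets
        s1 = compute_rest_score(ExpressionMatrix(shifted), signature, "none").scores
        assert np.allclose(s0, s1)

    def test_positive_scaling_scales_score(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 4)),
                          index=list("abcde"), columns=list("wxyz"))
        signature = SignatureDefinition(None, ["a", "b"], ["c", "d"])
        s0 = compute_rest_score(ExpressionMatrix(df), signature, "none").scores
        s3 = compute_rest_score(ExpressionMatrix(3.0 * df), signature, "none").scores
        assert np.allclose(3.0 * s0, s3)

    def test_zscore_invariant_to_gene_affine_transforms(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 6)), index=list("abcde"),
                          columns=[f"s{i}" for i in range(6)])
        signature = SignatureDefinition(None, ["a", "b"], ["c", "d"])
        s0 = compute_rest_score(ExpressionMatrix(df), signature, "zscore").scores
        scale = rng.uniform(0.5, 3.0, size=(5, 1))
        shift = rng.normal(size=(5, 1))
        s1 = compute_rest_score(ExpressionMatrix(df * scale + shift),
                                signature, "zscore").scores
        assert np.allclose(s0, s1)

    def test_swapping_sets_negates_score(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"),
                          columns=list("wxyz"))
        fwd = SignatureDefinition(None, ["a", "b"], ["c", "d"])
        rev = SignatureDefinition(None, ["c", "d"], ["a", "b"])
        s_f = compute_rest_score(ExpressionMatrix(df), fwd, "none").scores
        s_r = compute_rest_score(ExpressionMatrix(df), rev, "none").scores
        assert np.allclose(s_f, -s_r)

    def test_empty_restless_set_scores_over_rest_only(self):
        expr = ExpressionMatrix(pd.DataFrame({"s1": [2.0, 4.0]}, index=["a", "b"]))
        signature = SignatureDefinition(None, ["a", "b"], [])
        assert compute_rest_score(expr, signature, "none").scores["s1"] == 3.0

    def test_missing_genes_warn_below_coverage(self):
        expr = ExpressionMatrix(pd.DataFrame({"s1": [2.0], "s2": [3.0]}, index=["a"]))
        signature = SignatureDefinition(None, ["a", "b", "c"], [])
        with pytest.warns(UserWarning, match="coverage"):
            scores = compute_rest_score(expr, signature, "none")
        assert scores.coverage["REST"] == pytest.approx(1 / 3)

    def test_no_signature_gene_error(self):
        expr = ExpressionMatrix(pd.DataFrame({"s1": [2.0]}, index=["a"]))
        signature = SignatureDefinition(None, ["x"], ["y"])
        with pytest.raises(ValueError, match="no signature gene"):
            compute_rest_score(expr, signature, "none")

    def test_score_tracks_latent_factor(self):
        cfg = SimulationConfig(beta=1.0, sigma=1.0, n_pos=20, n_neg=20, n_null=50)
        expr, truth = generate_cohort(cfg, seed=21, n_samples=500)
        signature = SignatureDefinition(
            cfg.seed_gene, [cfg.seed_gene] + truth.planted_pos, truth.planted_neg)
        scores = compute_rest_score(expr, signature, "none")
        r = np.corrcoef(scores.scores, truth.z)[0, 1]
        assert r > 0.9

    def test_member_correlation_signs_match_sets(self):
        cfg = SimulationConfig(n_pos=10, n_neg=10, n_null=50)
        expr, truth = generate_cohort(cfg, seed=33, n_samples=300)
        signature = SignatureDefinition(
            cfg.seed_gene, [cfg.seed_gene] + truth.planted_pos, truth.planted_neg)
        scores = compute_rest_score(expr, signature, "none").scores
        for g in signature.rest_type:
            assert np.corrcoef(expr.gene(g), scores)[0, 1] > 0
        for g in signature.restless_type:
            assert np.corrcoef(expr.gene(g), scores)[0, 1] < 0


class TestMedianSplit:
    def _scores(self, vals):
        from exprest.signature import RestScoreVector

        return RestScoreVector(pd.Series(vals, index=[f"s{i}" for i in range(len(vals))]))

    def test_even_count_balanced(self):
        split = dichotomize_by_median(self._scores([1.0, 2.0, 3.0, 4.0]))
        assert list(split.groups) == ["low", "low", "high", "high"]

    def test_tie_at_median_goes_low(self):
        split = dichotomize_by_median(self._scores([1.0, 2.0, 3.0]))
        assert list(split.groups) == ["low", "low", "high"]

    def test_degenerate_split_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            dichotomize_by_median(self._scores([2.0, 2.0, 2.0]))

    @given(st.integers(0, 10**6))
    def test_even_distinct_scores_split_in_half(self, seed):
        rng = np.random.default_rng(seed)
        n = 2 * int(rng.integers(2, 30))
        vals = rng.permutation(np.arange(n, dtype=float))
        split = dichotomize_by_median(self._scores(list(vals)))
        counts = split.groups.value_counts()
        assert counts["low"] == counts["high"] == n // 2
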