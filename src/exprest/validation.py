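"""Benchmark battery: recovery, calibration and oracle checks.

Every function here recomputes a property of the package from scratch on
synthetic data — planted-signal recovery, type-I calibration of the
test statistics, agreement with brute-force oracles, BUM parameter
recovery, Cox effect recovery, drug-screen power, and end-to-end
determinism.  The brute-force oracles (step-up BH by definition,
hypergeometric tails by exact enumeration, the naive Lance-Williams
Ward recurrence, direct-permutation Spearman) are deliberately
independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, signature as sig, survival_analysis as surv, synthetic
from .io_formats import SurvivalTable
from .pipeline import RunConfig, run_pipeline

# ---------------------------------------------------------------------------
# 1. signature recovery
# ---------------------------------------------------------------------------

def signature_recovery(seed: int, n_seeds: int = 20) -> tuple[float, float]:
    """Mean sensitivity and false-discovery proportion of derive_signature.

    Paired cohorts (400 tumors / 50 cell lines), 30 + 10 planted genes
    at r* = 0.5 among 500 nulls, cutoff 0.3, averaged over ``n_seeds``
    independent replicates.
    """
    cfg = synthetic.SimulationConfig()  # defaults ARE these conditions
    sens, fdp = [], []
    for i in range(n_seeds):
        expr_a, truth = synthetic.generate_cohort(cfg, seed=seed + 2 * i,
                                                  n_samples=cfg.n_tumor)
        expr_b, _ = synthetic.generate_cohort(cfg, seed=seed + 2 * i + 1,
                                              n_samples=cfg.n_cellline)
        prof_a = sig.pearson_profile(expr_a, cfg.seed_gene, cohort="A")
        prof_b = sig.pearson_profile(expr_b, cfg.seed_gene, cohort="B")
        signature = sig.derive_signature(prof_a, prof_b, cutoff=0.3)
        found = set(signature.genes) - {cfg.seed_gene}
        planted = set(truth.planted_pos) | set(truth.planted_neg)
        tp = len(found & planted)
        fp = len(found - planted)
        sens.append(tp / len(planted))
        fdp.append(fp / max(len(found), 1))
    return float(np.mean(sens)), float(np.mean(fdp))


def score_fidelity(seed: int) -> float:
    """Pearson r between the derived-signature score and the latent factor."""
    cfg = synthetic.SimulationConfig()
    expr_a, truth = synthetic.generate_cohort(cfg, seed=seed, n_samples=cfg.n_tumor)
    expr_b, _ = synthetic.generate_cohort(cfg, seed=seed + 1, n_samples=cfg.n_cellline)
    signature = sig.derive_signature(
        sig.pearson_profile(expr_a, cfg.seed_gene),
        sig.pearson_profile(expr_b, cfg.seed_gene),
        cutoff=0.3,
    )
    scores = sig.compute_rest_score(expr_a, signature, standardize="none")
    r, _ = assoc.pearson_assoc(scores.scores.to_numpy(), truth.z.to_numpy())
    return float(r)


def worked_example_score() -> float:
    """The 3-gene worked example: G_R genes at (2, 4), G_L gene at 1 -> S = 2."""
    from .io_formats import ExpressionMatrix

    expr = ExpressionMatrix(pd.DataFrame({"s1": [2.0, 4.0, 1.0]},
                                         index=["gA", "gB", "gC"]))
    signature = sig.SignatureDefinition(seed_gene=None, rest_type=["gA", "gB"],
                                        restless_type=["gC"])
    scores = sig.compute_rest_score(expr, signature, standardize="none")
    return float(scores.scores.iloc[0])


# ---------------------------------------------------------------------------
# 3. type-I calibration (rejection rate at alpha = 0.05 under the null)
# ---------------------------------------------------------------------------

def calibration_ttest(seed: int, reps: int = 1000, n: int = 20) -> float:
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n)
    hits = 0
    for _ in range(reps):
        x = rng.normal(size=2 * n)
        if assoc.mean_shift_ttest(x, labels).p < 0.05:
            hits += 1
    return hits / reps


def calibration_anova(seed: int, reps: int = 1000, n: int = 10, k: int = 4) -> float:
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), n)
    hits = 0
    for _ in range(reps):
        x = rng.normal(size=k * n)
        if assoc.anova_tukey(x, labels, with_tukey=False).p < 0.05:
            hits += 1
    return hits / reps


def calibration_logrank(seed: int, reps: int = 1000, n_per_arm: int = 100) -> float:
    """Median split of z with gamma = 0: the groups carry no hazard signal."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(reps):
        z = pd.Series(rng.normal(size=2 * n_per_arm),
                      index=[f"s{j}" for j in range(2 * n_per_arm)])
        table = synthetic.generate_survival(z, gamma=0.0, h0=0.001, censor_frac=0.3,
                                            seed=int(rng.integers(2**31)))
        groups = pd.Series(np.where(z <= z.median(), "low", "high"), index=z.index)
        _, p = surv.logrank(table, groups)
        if p < 0.05:
            hits += 1
    return hits / reps


def calibration_spearman(seed: int, n: int = 50, n_features: int = 1000) -> float:
    """One scan of independent Gaussian features doubles as n_features nulls."""
    rng = np.random.default_rng(seed)
    scores = pd.Series(rng.normal(size=n), index=[f"s{j}" for j in range(n)])
    panel = pd.DataFrame(rng.normal(size=(n_features, n)), columns=scores.index)
    table = assoc.spearman_scan(scores, panel)
    return float((table["p"] < 0.05).mean())


def calibration_ks(seed: int, reps: int = 1000, n: int = 100) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        x = rng.uniform(size=n)
        y = rng.uniform(size=n)
        _, p = assoc.ks_shift_test(x, y)
        if p < 0.05:
            hits += 1
    return hits / reps


def spearman_null_uniformity(seed: int, n: int = 50, n_features: int = 500) -> float:
    """KS p-value of the null Spearman p-values against U(0,1)."""
    rng = np.random.default_rng(seed)
    scores = pd.Series(rng.normal(size=n), index=[f"s{j}" for j in range(n)])
    panel = pd.DataFrame(rng.normal(size=(n_features, n)), columns=scores.index)
    table = assoc.spearman_scan(scores, panel)
    return float(stats.kstest(table["p"], "uniform").pvalue)


# ---------------------------------------------------------------------------
# 4. brute-force oracles
# ---------------------------------------------------------------------------

def bh_oracle(pvalues) -> np.ndarray:
    """BH by definition: adj_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def oracle_bh_max_diff(seed: int, n_vectors: int = 100) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        p = rng.uniform(size=m)
        worst = max(worst, float(np.max(np.abs(assoc.bh_adjust(p) - bh_oracle(p)))))
    return worst


def fisher_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X hypergeometric, by exact rational enumeration."""
    total = Fraction(0)
    for x in range(max(0, K + n - N), min(K, n) + 1):
        if x >= k:
            total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return float(total)


def oracle_fisher_max_diff(max_N: int = 12) -> float:
    worst = 0.0
    for N in range(2, max_N + 1):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    _, p = assoc.fisher_enrichment(k, K, n, N, alternative="greater")
                    worst = max(worst, abs(p - fisher_oracle(k, K, n, N)))
    return worst


def ward_oracle_heights(X: np.ndarray) -> list[float]:
    """Naive Lance-Williams Ward recurrence on d = 1 - Pearson distances."""
    n = X.shape[0]
    corr = np.corrcoef(X)
    # scipy's ward treats the input as squared-euclidean-like via d^2 internally
    d2 = {(i, j): (1.0 - corr[i, j]) ** 2 for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), best = min(
            (((a, b), d2[(min(a, b), max(a, b))])
             for a, b in itertools.combinations(sorted(active), 2)),
            key=lambda t: t[1],
        )
        heights.append(math.sqrt(best))
        si, sj = size[i], size[j]
        for k in sorted(active - {i, j}):
            sk = size[k]
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            new = ((si + sk) * dik + (sj + sk) * djk - sk * best) / (si + sj + sk)
            d2[(min(k, next_id), max(k, next_id))] = new
        size[next_id] = si + sj
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return heights


def oracle_ward_max_diff(seed: int, n_genes: int = 6, n_samples: int = 12) -> float:
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_genes, n_samples))
    result = assoc.ward_corr_cluster_order(pd.DataFrame(X))
    ours = result.linkage[:, 2]
    oracle = ward_oracle_heights(X)
    return float(np.max(np.abs(ours - np.array(oracle))))


def spearman_perm_oracle(x, y) -> float:
    """Two-sided permutation p by direct re-ranking of every permutation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = stats.rankdata(x)
    obs = abs(stats.pearsonr(rx, stats.rankdata(y)).statistic)
    count = total = 0
    for perm in itertools.permutations(y):
        rho = stats.pearsonr(rx, stats.rankdata(perm)).statistic
        if abs(rho) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def oracle_spearman_exact_max_diff(seed: int, n_vectors: int = 5, n: int = 7) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        worst = max(worst, abs(assoc.spearman_exact_p(x, y) - spearman_perm_oracle(x, y)))
    return worst


def logrank_hand_chi2() -> float:
    """Group A deaths at (1, 2), B at (3, 4), no censoring: chi2 = 49/17."""
    table = SurvivalTable(pd.DataFrame(
        {"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1]},
        index=["a1", "a2", "b1", "b2"]))
    groups = pd.Series(["A", "A", "B", "B"], index=table.sample_ids)
    chi2, _ = surv.logrank(table, groups)
    return float(chi2)


# ---------------------------------------------------------------------------
# 5. BUM recovery
# ---------------------------------------------------------------------------

def sample_bum_pvalues(rng, n: int, lam: float, a: float) -> np.ndarray:
    """Draw from lam * U(0,1) + (1 - lam) * Beta(a, 1)."""
    is_null = rng.uniform(size=n) < lam
    p = np.where(is_null, rng.uniform(size=n), rng.uniform(size=n) ** (1.0 / a))
    return np.clip(p, 1e-300, 1.0)


def bum_recovery_max_error(seed: int, n: int = 10_000) -> float:
    """Worst |pi0_upper - truth| over the (lam, a) grid {0.5, 0.8} x {0.1, 0.3}."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for lam in (0.5, 0.8):
        for a in (0.1, 0.3):
            p = sample_bum_pvalues(rng, n, lam, a)
            fit = assoc.fit_bum(p)
            truth = lam + (1 - lam) * a
            worst = max(worst, abs(fit.pi0_upper - truth))
    return worst


def bum_plugin_example() -> float:
    """FDR(0.01) for lam = 0.5, a = 0.5: 0.75 * 0.01 / 0.055 = 3/22."""
    fit = assoc.BumFit(lam=0.5, a=0.5, loglik=0.0, n=100)
    return assoc.bum_fdr_at(fit, 0.01)


def bum_realized_fdr(seed: int, reps: int = 10, n: int = 10_000,
                     lam: float = 0.6, a: float = 0.1,
                     fdr_target: float = 0.1) -> float:
    """Average realized FDR (null fraction among calls) at the plug-in threshold."""
    rng = np.random.default_rng(seed)
    realized = []
    for _ in range(reps):
        is_null = rng.uniform(size=n) < lam
        p = np.where(is_null, rng.uniform(size=n), rng.uniform(size=n) ** (1.0 / a))
        p = np.clip(p, 1e-300, 1.0)
        fit = assoc.fit_bum(p)
        _, mask, count = assoc.bum_significant(fit, p, fdr_target)
        realized.append(float(is_null[mask].sum() / max(count, 1)))
    return float(np.mean(realized))


# ---------------------------------------------------------------------------
# 6. Cox recovery
# ---------------------------------------------------------------------------

def cox_binary_recovery(seed: int, reps: int = 200, n: int = 1000,
                        true_hr: float = 2.0) -> tuple[float, float]:
    """(mean HR estimate, CI coverage) for a planted binary hazard ratio."""
    rng = np.random.default_rng(seed)
    gamma = math.log(true_hr)
    hrs, covered = [], 0
    for i in range(reps):
        x = (rng.uniform(size=n) < 0.5).astype(float)
        z = pd.Series(x, index=[f"s{j}" for j in range(n)])
        table = synthetic.generate_survival(z, gamma=gamma, h0=0.001,
                                            censor_frac=0.2,
                                            seed=int(rng.integers(2**31)))
        res = surv.cox_hr(table, z, type="continuous")
        hrs.append(res.hr)
        if res.ci_low <= true_hr <= res.ci_high:
            covered += 1
    return float(np.mean(hrs)), covered / reps


def cox_continuous_recovery(seed: int, reps: int = 100, n: int = 400,
                            true_hr: float = 1.35) -> float:
    """Mean HR-per-unit estimate for a planted continuous effect."""
    rng = np.random.default_rng(seed)
    gamma = math.log(true_hr)
    hrs = []
    for i in range(reps):
        z = pd.Series(rng.normal(size=n), index=[f"s{j}" for j in range(n)])
        table = synthetic.generate_survival(z, gamma=gamma, h0=0.001,
                                            censor_frac=0.2,
                                            seed=int(rng.integers(2**31)))
        hrs.append(surv.cox_hr(table, z, type="continuous").hr)
    return float(np.mean(hrs))


# ---------------------------------------------------------------------------
# 7. drug screen
# ---------------------------------------------------------------------------

def drug_screen_power(seed: int, reps: int = 100, n_per_arm: int = 20,
                      n_null: int = 30, delta: float = -2.0,
                      sigma: float = 0.5) -> float:
    """Fraction of replicates in which the planted drug has the smallest BH q."""
    rng = np.random.default_rng(seed)
    cells = [f"c{j}" for j in range(2 * n_per_arm)]
    groups = pd.Series(["high"] * n_per_arm + ["low"] * n_per_arm, index=cells)
    effects = pd.Series([delta] + [0.0] * n_null,
                        index=["PLANTED"] + [f"N{j}" for j in range(n_null)])
    hits = 0
    for _ in range(reps):
        ic50 = synthetic.generate_drug_response(groups, effects, sigma,
                                                seed=int(rng.integers(2**31)))
        table = assoc.drug_sensitivity_scan(groups, ic50)
        best = table["p_adj"].idxmin()
        if best == "PLANTED" and table.loc["PLANTED", "p_adj"] == table["p_adj"].min():
            hits += 1
    return hits / reps


def drug_fold_example() -> float:
    """Noiseless fold change: high arm at -2, low arm at 0 -> exp(-2)."""
    groups = pd.Series(["high", "high", "low", "low"],
                       index=["c1", "c2", "c3", "c4"])
    ic50 = pd.DataFrame({"c1": [-2.0], "c2": [-2.0], "c3": [0.0], "c4": [0.0]},
                        index=["drug"])
    table = assoc.drug_sensitivity_scan(groups, ic50)
    return float(table.loc["drug", "fold_change"])


# ---------------------------------------------------------------------------
# 8. end-to-end
# ---------------------------------------------------------------------------

def end_to_end(seed: int, workdir) -> tuple[bool, float]:
    """Run the packaged synthetic study twice; return (byte-identical, log-rank p)."""
    workdir = Path(workdir)
    manifests = []
    for tag in ("run1", "run2"):
        cfg = RunConfig(outdir=str(workdir / tag), seed=seed, simulate={})
        manifests.append(run_pipeline(cfg))
    h1 = {k: v["sha256"] for k, v in manifests[0]["outputs"].items()}
    h2 = {k: v["sha256"] for k, v in manifests[1]["outputs"].items()}
    identical = h1 == h2
    import json

    with open(workdir / "run1" / "survival.json", "rt", encoding="utf-8") as fh:
        p = float(json.load(fh)["logrank"]["p"])
    return identical, p
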