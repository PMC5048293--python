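"""Feature-level association statistics for an activity score.

Covers the full battery tying a per-sample score to molecular features:
Spearman scans against expression panels, beta-uniform-mixture (BUM)
FDR estimation, Benjamini-Hochberg adjustment, two-group t statistics
for binary features (mutations), one-way ANOVA with Tukey HSD for
subtypes, Pearson association, hypergeometric / Fisher gene-set
enrichment, Kolmogorov-Smirnov shift tests, drug-sensitivity fold
changes, and Ward clustering on 1 - Pearson distance.

The BUM machinery models a p-value distribution as the mixture

    f(p) = lam + (1 - lam) * a * p^(a-1),   lam in [0,1], a in (0,1]

whose uniform component plus the flat part of the beta component bound
the null proportion from above, pi0_upper = lam + (1 - lam) * a.  The
plug-in FDR at threshold tau is pi0_upper * tau / F(tau) with
F(tau) = lam * tau + (1 - lam) * tau^a.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.optimize import minimize
from scipy.spatial.distance import squareform
from scipy.special import expit, logit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BumFit",
    "spearman_scan",
    "spearman_exact_p",
    "fit_bum",
    "bum_fdr_at",
    "bum_significant",
    "bh_adjust",
    "mean_shift_ttest",
    "anova_tukey",
    "pearson_assoc",
    "fisher_enrichment",
    "ks_shift_test",
    "hypergeom_geneset_scan",
    "drug_sensitivity_scan",
    "mutation_scan",
    "ward_corr_cluster_order",
]


def _as_series(scores) -> pd.Series:
    """Accept a RestScoreVector, Series, or array of per-sample values."""
    if hasattr(scores, "scores"):
        return scores.scores
    return pd.Series(scores)


# ---------------------------------------------------------------------------
# Spearman scan
# ---------------------------------------------------------------------------

def spearman_exact_p(x, y, alternative: str = "two-sided") -> float:
    """Exact permutation p for Spearman's rho (n <= 10, midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p restricted to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0:
        raise ValueError("constant input")
    obs = float(rxc @ ryc) / denom
    # rho under permutation is a linear function of rxc . perm(ryc)
    count = 0
    total = 0
    chunk = []
    tol = 1e-12

    def flush(chunk):
        nonlocal count, total
        P = np.array(chunk)
        rho = (P @ rxc) / denom
        if alternative == "two-sided":
            count += int(np.sum(np.abs(rho) >= abs(obs) - tol))
        elif alternative == "greater":
            count += int(np.sum(rho >= obs - tol))
        elif alternative == "less":
            count += int(np.sum(rho <= obs + tol))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        total += len(chunk)

    for perm in itertools.permutations(ryc):
        chunk.append(perm)
        if len(chunk) >= 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return count / total


def _spearman_t_p(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return np.clip(p, 0.0, 1.0)


def spearman_scan(scores, feature_matrix: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of every feature (rows) against the score, with p and BH q.

    Midranks handle ties.  Two-sided p comes from the t approximation for
    n > 10 and from exact permutation for n <= 10.  Features with fewer
    than two distinct values are skipped and listed in ``.attrs['skipped']``.
    """
    s = _as_series(scores)
    shared = feature_matrix.columns.intersection(s.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between scores and features")
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples for a Spearman scan")
    X = feature_matrix.loc[:, shared].to_numpy(dtype=float)
    sv = s.loc[shared].to_numpy(dtype=float)
    n = len(shared)

    distinct = np.array([len(np.unique(row)) for row in X])
    keep = distinct >= 2
    skipped = list(feature_matrix.index[~keep])
    X = X[keep]

    ranks = np.apply_along_axis(stats.rankdata, 1, X) if len(X) else X
    rs = stats.rankdata(sv)
    rsc = rs - rs.mean()
    Rc = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.einsum("ij,ij->i", Rc, Rc) * float(rsc @ rsc))
    rho = (Rc @ rsc) / denom
    rho = np.clip(rho, -1.0, 1.0)

    if n > 10:
        p = _spearman_t_p(rho, n)
    else:
        p = np.array([spearman_exact_p(row, sv) for row in X])

    table = pd.DataFrame(
        {"rho": rho, "p": p, "p_adj": bh_adjust(p) if len(p) else p},
        index=feature_matrix.index[keep],
    )
    table.attrs["skipped"] = skipped
    table.attrs["n"] = n
    return table


# ---------------------------------------------------------------------------
# BUM model
# ---------------------------------------------------------------------------

@dataclass
class BumFit:
    """Maximum-likelihood fit of the beta-uniform mixture to p-values."""

    lam: float
    a: float
    loglik: float
    n: int
    boundary: bool = False

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0 and 0.0 < self.a <= 1.0):
            raise ValueError("BUM parameters out of range")

    @property
    def pi0_upper(self) -> float:
        return self.lam + (1.0 - self.lam) * self.a

    def density(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.lam + (1.0 - self.lam) * self.a * p ** (self.a - 1.0)

    def cdf(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.lam * p + (1.0 - self.lam) * p**self.a


_BUM_STARTS = [(0.5, 0.5), (0.9, 0.1), (0.1, 0.1), (0.5, 0.9), (0.8, 0.3)]


def fit_bum(pvalues) -> BumFit:
    """Fit f(p) = lam + (1-lam) a p^(a-1) by maximum likelihood.

    Box constraints are enforced through a logit reparameterization and
    the optimizer is restarted from five interior points; the best
    solution wins.  Fits pinned against a parameter boundary (notably
    a -> 1, where the density collapses to the uniform and lam is not
    identifiable) are flagged ``boundary=True``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) < 50:
        raise ValueError("need >= 50 p-values to fit the mixture")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    logp = np.log(p)

    def nll(theta):
        lam = expit(theta[0])
        a = expit(theta[1])
        dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
        return -np.sum(np.log(np.maximum(dens, 1e-300)))

    best = None
    for lam0, a0 in _BUM_STARTS:
        res = minimize(nll, x0=[logit(lam0), logit(a0)], method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    lam = float(expit(best.x[0]))
    a = float(expit(best.x[1]))
    eps = 1e-3
    boundary = lam < eps or lam > 1 - eps or a < eps or a > 1 - eps
    return BumFit(lam=lam, a=min(a, 1.0), loglik=-float(best.fun), n=len(p), boundary=boundary)


def bum_fdr_at(fit: BumFit, tau: float) -> float:
    """Plug-in FDR(tau) = pi0_upper * tau / F(tau)."""
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    return fit.pi0_upper * tau / float(fit.cdf(tau))


def bum_significant(fit: BumFit, pvalues, fdr_target: float):
    """Largest threshold tau with FDR(tau) <= fdr_target; mask = p <= tau.

    Returns ``(tau, mask, count)``.  FDR(tau) is increasing in tau, so
    tau is found by root bracketing; when even the smallest threshold
    exceeds the target (e.g. a near-uniform fit), nothing is called.
    """
    p = np.asarray(pvalues, dtype=float)
    if not 0 < fdr_target <= 1:
        raise ValueError("fdr_target must be in (0, 1]")
    if fdr_target == 1 or bum_fdr_at(fit, 1.0) <= fdr_target:
        tau = 1.0
    elif fit.a >= 1.0 - 1e-9:
        # density is uniform: FDR(tau) = pi0_upper for all tau
        tau = 0.0
    else:
        from scipy.optimize import brentq

        lo = 1e-300
        if bum_fdr_at(fit, lo) > fdr_target:
            tau = 0.0
        else:
            tau = brentq(lambda t: bum_fdr_at(fit, t) - fdr_target, lo, 1.0,
                         xtol=1e-300, rtol=1e-12)
    mask = p <= tau + 1e-15
    return tau, mask, int(mask.sum())


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class TTestResult(NamedTuple):
    delta: float     # mean(group 1) - mean(group 0)
    t: float
    p: float
    cohen_d: float


def mean_shift_ttest(scores, binary_labels) -> TTestResult:
    """Pooled-variance two-sided Student t test between two groups of scores."""
    s = _as_series(scores).to_numpy(dtype=float)
    g = np.asarray(binary_labels)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("binary_labels must have exactly 2 levels")
    x0 = s[g == levels[0]]
    x1 = s[g == levels[1]]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each group needs >= 2 samples")
    n0, n1 = len(x0), len(x1)
    pooled_var = ((n0 - 1) * x0.var(ddof=1) + (n1 - 1) * x1.var(ddof=1)) / (n0 + n1 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(x1, x0, equal_var=True)
    delta = float(x1.mean() - x0.mean())
    return TTestResult(delta=delta, t=float(t), p=float(p), cohen_d=delta / math.sqrt(pooled_var))


class AnovaResult(NamedTuple):
    F: float
    p: float
    tukey: pd.DataFrame | None


def anova_tukey(scores, group_labels, with_tukey: bool = True) -> AnovaResult:
    """One-way ANOVA F test plus all-pairs Tukey HSD p-values.

    Tukey p-values come from the studentized range distribution and are
    reported for every pair regardless of the omnibus outcome.
    """
    s = _as_series(scores).to_numpy(dtype=float)
    g = np.asarray(group_labels)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [s[g == lev] for lev in levels]
    for lev, x in zip(levels, samples):
        if len(x) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")
    F, p = stats.f_oneway(*samples)
    if np.isnan(F):  # zero between- and within-group variance
        F, p = 0.0, 1.0
    tukey = None
    if with_tukey:
        res = stats.tukey_hsd(*samples)
        rows = []
        for i, j in itertools.combinations(range(len(levels)), 2):
            rows.append({
                "group1": levels[i], "group2": levels[j],
                "diff": float(np.mean(samples[j]) - np.mean(samples[i])),
                "p": float(res.pvalue[i, j]),
            })
        tukey = pd.DataFrame(rows)
    return AnovaResult(F=float(F), p=float(p), tukey=tukey)


def pearson_assoc(x, y):
    """Pearson r with two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fisher_enrichment(k: int, K: int, n: int, N: int, alternative: str = "greater"):
    """Exact hypergeometric test of an overlap of size k.

    k = |query ∩ set|, K = set size, n = query size, N = universe size.
    Returns (odds_ratio, p); default alternative 'greater' tests
    over-representation.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError("inconsistent margins: k must satisfy 0 <= k <= min(K, n)")
    if K > N or n > N or N < K + n - k:
        raise ValueError("inconsistent margins: universe too small")
    table = [[k, K - k], [n - k, N - K - (n - k)]]
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p)


def ks_shift_test(pvals_targets, pvals_nontargets, alternative: str = "smaller"):
    """Two-sample Kolmogorov-Smirnov test for a distributional shift.

    Default alternative 'smaller' tests whether the target sample is
    stochastically smaller than the non-target sample.  The exact null
    distribution is used when m*n <= 10^4, otherwise the asymptotic one.
    """
    x = np.asarray(pvals_targets, dtype=float)
    y = np.asarray(pvals_nontargets, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    alt = {"smaller": "greater", "larger": "less", "two-sided": "two-sided"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    method = "exact" if len(x) * len(y) <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, alternative=alt, method=method)
    return float(res.statistic), float(res.pvalue)


def hypergeom_geneset_scan(query_genes, collection, universe) -> pd.DataFrame:
    """Over-representation of the query in each gene set, BH-adjusted.

    Each set is intersected with the universe before testing; sets with
    an empty intersection are dropped.  Rows are sorted by p ascending.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, gs in collection:
        members = set(gs.genes) & universe
        if not members:
            continue
        k = len(query & members)
        odds, p = fisher_enrichment(k, len(members), len(query), len(universe))
        rows.append({"set": name, "overlap": k, "set_size": len(members),
                     "odds": odds, "p": p})
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    table = pd.DataFrame(rows).set_index("set")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values(["p", "p_adj"], kind="mergesort")


def drug_sensitivity_scan(group_labels, log_ic50_table: pd.DataFrame) -> pd.DataFrame:
    """Per-drug high-vs-low comparison of log-IC50 values.

    For each drug: delta = mean log-IC50(high) - mean log-IC50(low),
    fold change = exp(delta) (geometric-mean ratio; < 1 means the
    high-activity group is more sensitive), pooled t-test p, BH across
    drugs.  Drugs with fewer than 2 usable cell lines in either arm are
    skipped and listed in ``.attrs['skipped']``.
    """
    g = pd.Series(group_labels)
    shared = log_ic50_table.columns.intersection(g.index)
    if len(shared) == 0:
        raise ValueError("no shared cell lines between groups and IC50 table")
    g = g.loc[shared]
    high_ids = g.index[g == "high"]
    low_ids = g.index[g == "low"]
    rows, skipped = [], []
    for drug, row in log_ic50_table.loc[:, shared].iterrows():
        hi = row.loc[high_ids].dropna().to_numpy(dtype=float)
        lo = row.loc[low_ids].dropna().to_numpy(dtype=float)
        if len(hi) < 2 or len(lo) < 2:
            skipped.append(drug)
            continue
        delta = float(hi.mean() - lo.mean())
        if hi.var(ddof=1) == 0 and lo.var(ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(hi, lo, equal_var=True)
        rows.append({"drug": drug, "delta": delta, "fold_change": math.exp(delta),
                     "t": float(t), "p": float(p)})
    if not rows:
        raise ValueError("no drug with >= 2 cell lines per arm")
    table = pd.DataFrame(rows).set_index("drug")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table.attrs["skipped"] = skipped
    return table


def mutation_scan(scores, binary_features: pd.DataFrame) -> pd.DataFrame:
    """Score shift between carriers (1) and non-carriers (0) of each feature.

    Per feature: delta = mean score(carriers) - mean score(wildtype),
    pooled t-test p, Cohen's d, BH across features.  Features with fewer
    than 2 samples in either group are skipped (``.attrs['skipped']``).
    """
    s = _as_series(scores)
    shared = binary_features.columns.intersection(s.index)
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples")
    sv = s.loc[shared]
    rows, skipped = [], []
    for feat, row in binary_features.loc[:, shared].iterrows():
        carrier = row.astype(int) == 1
        if carrier.sum() < 2 or (~carrier).sum() < 2:
            skipped.append(feat)
            continue
        try:
            res = mean_shift_ttest(sv, carrier.to_numpy())
        except ValueError:
            skipped.append(feat)
            continue
        rows.append({"feature": feat, "delta": res.delta, "t": res.t,
                     "p": res.p, "cohen_d": res.cohen_d,
                     "n_mut": int(carrier.sum()), "n_wt": int((~carrier).sum())})
    if not rows:
        raise ValueError("no testable mutation feature")
    table = pd.DataFrame(rows).set_index("feature")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table.attrs["skipped"] = skipped
    return table


class ClusterResult(NamedTuple):
    order: list          # leaf order (gene identifiers)
    linkage: np.ndarray  # scipy linkage matrix (merge heights in column 2)


def ward_corr_cluster_order(expr) -> ClusterResult:
    """Ward-linkage clustering of genes under d = 1 - Pearson correlation.

    Accepts an ExpressionMatrix or a genes x samples DataFrame.  The
    Lance-Williams Ward recurrence is applied to the correlation
    distances; leaf order is deterministic with ties broken by input
    order.
    """
    values = expr.values if hasattr(expr, "values") and not isinstance(expr, pd.DataFrame) else expr
    if isinstance(values, pd.DataFrame):
        names = list(values.index)
        X = values.to_numpy(dtype=float)
    else:
        X = np.asarray(values, dtype=float)
        names = list(range(X.shape[0]))
    if X.shape[0] < 2:
        raise ValueError("need >= 2 genes to cluster")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = names[int(np.argmin(sd))]
        raise ValueError(f"zero-variance gene {bad!r}")
    corr = np.corrcoef(X)
    d = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="ward")
    order = [names[i] for i in leaves_list(Z)]
    return ClusterResult(order=order, linkage=Z)
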