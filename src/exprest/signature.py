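"""Seed-guided signature derivation and REST-activity scoring.

The signature is built by correlating every gene against a single seed
gene (REST) in two independent cohorts, keeping genes whose correlation
is sign-consistent across cohorts and at least ``cutoff`` in absolute
value in both.  Positively correlated members form the REST-type set
G_R, negatively correlated members the RESTless-type set G_L.  The
per-sample score is

    S_i = mean_{g in G_R} e_gi  -  mean_{g in G_L} e_gi

so a large S_i indicates enhanced REST activity.  Median dichotomization
of S yields the low/high groups used in survival analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = [
    "CorrelationProfile",
    "SignatureDefinition",
    "RestScoreVector",
    "pearson_profile",
    "derive_signature",
    "compute_rest_score",
    "dichotomize_by_median",
]


@dataclass
class CorrelationProfile:
    """Per-gene Pearson correlation with the seed gene in one cohort."""

    cohort: str
    seed_gene: str
    r: pd.Series            # gene -> Pearson r with the seed gene
    n: int                  # samples used
    dropped: list[str] = field(default_factory=list)  # zero-variance genes excluded

    def __post_init__(self):
        vals = self.r.to_numpy(dtype=float)
        if np.any(np.abs(vals) > 1 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")
        self.r = self.r.clip(-1.0, 1.0)


@dataclass
class SignatureDefinition:
    """Two disjoint gene sets with their derivation correlations.

    ``rest_type`` (G_R) holds positively correlated genes, ``restless_type``
    (G_L) negatively correlated ones.  ``correlations`` carries the
    per-cohort r of each member (columns r_cohortA, r_cohortB) when the
    signature was derived rather than supplied.
    """

    seed_gene: str | None
    rest_type: list[str]
    restless_type: list[str]
    cutoff: float | None = None
    correlations: pd.DataFrame | None = None

    def __post_init__(self):
        overlap = set(self.rest_type) & set(self.restless_type)
        if overlap:
            raise ValueError(
                f"gene(s) in both REST and RESTless sets: {sorted(overlap)[:5]}"
            )
        if len(set(self.rest_type)) != len(self.rest_type):
            raise ValueError("duplicate gene in REST-type set")
        if len(set(self.restless_type)) != len(self.restless_type):
            raise ValueError("duplicate gene in RESTless-type set")

    @property
    def genes(self) -> list[str]:
        return list(self.rest_type) + list(self.restless_type)

    def __len__(self) -> int:
        return len(self.rest_type) + len(self.restless_type)


@dataclass
class RestScoreVector:
    """Per-sample score S_i, optionally with median-split group labels."""

    scores: pd.Series
    groups: pd.Series | None = None  # 'low' / 'high'
    coverage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("non-finite score")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def pearson_profile(expr: ExpressionMatrix, seed_gene: str, cohort: str = "") -> CorrelationProfile:
    """Pearson correlation of every gene with the seed gene across samples.

    Genes with zero variance are excluded and listed in ``dropped``.  The
    seed gene itself maps to exactly 1.
    """
    if seed_gene not in expr.values.index:
        raise ValueError(f"seed gene {seed_gene!r} absent from matrix")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to compute correlations")
    X = expr.values.to_numpy(dtype=float)
    seed = expr.values.loc[seed_gene].to_numpy(dtype=float)
    seed_c = seed - seed.mean()
    seed_ss = float(seed_c @ seed_c)
    if seed_ss == 0.0:
        raise ValueError(f"seed gene {seed_gene!r} has zero variance")

    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    keep = ss > 0.0
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    r = np.full(X.shape[0], np.nan)
    r[keep] = (Xc[keep] @ seed_c) / np.sqrt(ss[keep] * seed_ss)
    series = pd.Series(r[keep], index=np.asarray(expr.gene_ids)[keep]).clip(-1.0, 1.0)
    series.loc[seed_gene] = 1.0
    return CorrelationProfile(
        cohort=cohort, seed_gene=seed_gene, r=series, n=expr.shape[1], dropped=dropped
    )


def derive_signature(
    profile_a: CorrelationProfile,
    profile_b: CorrelationProfile,
    cutoff: float = 0.3,
    include_seed: bool = True,
    rule: str = "both",
) -> SignatureDefinition:
    """Select sign-consistent, strongly correlated genes from two cohorts.

    A gene is a member iff sign(r_A) == sign(r_B) and the correlation
    magnitude clears ``cutoff`` under ``rule``:

    - ``both`` (default): min(|r_A|, |r_B|) >= cutoff
    - ``either``: max(|r_A|, |r_B|) >= cutoff
    - ``mean``: (|r_A| + |r_B|) / 2 >= cutoff

    Positive members go to G_R, negative to G_L.  The seed gene is kept
    in G_R unless ``include_seed=False``.
    """
    if profile_a.seed_gene != profile_b.seed_gene:
        raise ValueError("profiles were computed against different seed genes")
    seed = profile_a.seed_gene
    shared = profile_a.r.index.intersection(profile_b.r.index)
    if len(shared.drop(seed, errors="ignore")) == 0:
        raise ValueError("cohorts share no genes beyond the seed")

    ra = profile_a.r.loc[shared]
    rb = profile_b.r.loc[shared]
    sign_ok = np.sign(ra) == np.sign(rb)
    if rule == "both":
        mag_ok = np.minimum(ra.abs(), rb.abs()) >= cutoff
    elif rule == "either":
        mag_ok = np.maximum(ra.abs(), rb.abs()) >= cutoff
    elif rule == "mean":
        mag_ok = (ra.abs() + rb.abs()) / 2 >= cutoff
    else:
        raise ValueError(f"unknown cutoff rule {rule!r}")
    member = sign_ok & mag_ok & (ra != 0)

    rest = [g for g in shared[member & (ra > 0)] if g != seed]
    restless = list(shared[member & (ra < 0)])
    if include_seed:
        rest = [seed] + rest
    if not rest and not restless:
        raise ValueError("empty signature: no gene passes the cutoff in both cohorts")

    members = rest + restless
    corr = pd.DataFrame(
        {"r_cohortA": ra.reindex(members), "r_cohortB": rb.reindex(members)}
    )
    return SignatureDefinition(
        seed_gene=seed, rest_type=rest, restless_type=restless,
        cutoff=cutoff, correlations=corr,
    )


def compute_rest_score(
    expr: ExpressionMatrix,
    signature: SignatureDefinition,
    standardize: str = "none",
) -> RestScoreVector:
    """Mean expression over G_R minus mean expression over G_L, per sample.

    Signature genes absent from the matrix are skipped; the per-set
    coverage fraction is reported and a warning is issued below 80%.
    With ``standardize='zscore'`` each gene is z-scored across the scored
    samples first, which makes scores comparable across platforms; the
    default ``'none'`` reproduces the literal mean-difference formula.
    An empty (or fully missing) G_L contributes zero.
    """
    if standardize not in ("none", "zscore"):
        raise ValueError(f"unknown standardize mode {standardize!r}")
    present_r = [g for g in signature.rest_type if g in expr.values.index]
    present_l = [g for g in signature.restless_type if g in expr.values.index]
    if not present_r and not present_l:
        raise ValueError("no signature gene present in expression matrix")

    coverage = {}
    if signature.rest_type:
        coverage["REST"] = len(present_r) / len(signature.rest_type)
    if signature.restless_type:
        coverage["RESTless"] = len(present_l) / len(signature.restless_type)
    for name, frac in coverage.items():
        if frac < 0.8:
            warnings.warn(
                f"{name}-type coverage {frac:.0%}: scoring over present genes only",
                stacklevel=2,
            )

    values = expr.values
    if standardize == "zscore":
        if expr.shape[1] < 2:
            raise ValueError("zscore standardization needs >= 2 samples")
        sub = values.loc[present_r + present_l]
        sd = sub.std(axis=1, ddof=1)
        flat = sd == 0
        if flat.any():
            skipped = list(sub.index[flat])
            warnings.warn(
                f"dropping zero-variance gene(s) under zscore: {skipped[:5]}",
                stacklevel=2,
            )
            present_r = [g for g in present_r if g not in skipped]
            present_l = [g for g in present_l if g not in skipped]
            if not present_r and not present_l:
                raise ValueError("no signature gene with variance under zscore")
        values = sub.sub(sub.mean(axis=1), axis=0).div(sd.where(sd > 0), axis=0)

    mean_r = values.loc[present_r].mean(axis=0) if present_r else 0.0
    mean_l = values.loc[present_l].mean(axis=0) if present_l else 0.0
    scores = pd.Series(mean_r - mean_l, index=expr.sample_ids, name="rest_score")
    return RestScoreVector(scores=scores, coverage=coverage)


def dichotomize_by_median(scores: RestScoreVector) -> RestScoreVector:
    """Split samples into 'low' (S <= median) and 'high' (S > median) groups."""
    s = scores.scores
    if len(s) < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    med = float(s.median())
    if (s == s.iloc[0]).all():
        raise ValueError("degenerate split: all scores identical")
    groups = pd.Series(np.where(s <= med, "low", "high"), index=s.index, name="group")
    return RestScoreVector(scores=s, groups=groups, coverage=dict(scores.coverage))
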