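"""Synthetic cohorts with a known latent REST-activity factor.

Every downstream stage of the pipeline is benchmarked against these
cohorts because the ground truth is known exactly.  The generative model
is a one-dimensional latent factor per sample,

    z_i ~ N(0, 1)
    e_gi = mu_g + beta_g * z_i + eps_gi,   eps_gi ~ N(0, sigma^2)

with beta_g = +beta for planted REST-type genes, -beta for planted
RESTless-type genes and 0 for null genes.  The designated seed gene
("REST") is an affine readout of z itself (noise sd ``seed_noise_sd``,
zero by default), so its expression is the latent activity on the
expression scale and gene-seed correlations equal the planted
r* = beta / sqrt(beta^2 + sigma^2).

Survival times are exponential with hazard h0 * exp(gamma * z_i) and
independent uniform censoring on [0, T_max], T_max solved numerically so
the expected censored fraction matches ``censor_frac``.  Binary features
(mutations) are Bernoulli(logistic(alpha + delta * z_i)); Gaussian
feature panels (miRNA) reuse the expression model; log-IC50 drug
responses are Gaussian with per-(drug, group) means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io_formats import ExpressionMatrix, SurvivalTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_survival",
    "generate_feature_matrix",
    "generate_drug_response",
    "generate_healthy_panel",
]

_TISSUES = [
    "adipose", "adrenal", "colon", "heart", "kidney", "liver",
    "lung", "muscle", "pancreas", "skin", "spleen", "thyroid",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are the benchmark conditions used throughout the test
    battery: a 400-sample tumor cohort paired with a 50-sample cell-line
    cohort, 30 positively and 10 negatively loaded genes at planted
    correlation r* = 0.5 (beta = sigma / sqrt(3)) among 500 nulls, a
    survival effect of log(1.5) per unit latent factor with 30%
    censoring, and one drug with a -2 log-IC50 shift among 30 nulls.
    """

    n_tumor: int = 400
    n_cellline: int = 50
    n_pos: int = 30
    n_neg: int = 10
    n_null: int = 500
    beta: float = 1.0 / math.sqrt(3.0)   # planted loading; r* = beta/sqrt(beta^2+sigma^2)
    sigma: float = 1.0                   # per-gene noise sd
    seed_gene: str = "REST"
    seed_noise_sd: float = 0.0           # seed mRNA = latent activity by default
    mu_mean: float = 8.0                 # baseline log-expression level
    mu_sd: float = 1.0
    shared_z: bool = False               # reuse one z across paired cohorts (debugging)
    # survival
    gamma: float = math.log(1.5)         # log-hazard per unit z
    h0: float = 1.0 / 1000.0             # baseline hazard per day
    censor_frac: float = 0.3
    # mutations
    n_mutations: int = 20
    n_planted_mutations: int = 3
    mutation_delta: float = 2.0          # log-odds per unit z for planted mutations
    mutation_alpha: float = -1.5         # baseline log-odds (~18% prevalence at z=0)
    # miRNA panel
    n_mirna: int = 50
    n_planted_mirna: int = 10
    mirna_beta: float = 1.0 / math.sqrt(3.0)
    # drugs
    n_drugs: int = 31
    n_planted_drugs: int = 1
    drug_delta: float = -2.0             # log-IC50 shift in the high-activity group
    ic50_sigma: float = 0.5
    # healthy panel
    n_brain: int = 7
    n_other_tissue: int = 36
    delta_brain: float = 2.0             # depression of z in brain tissue, in sd units

    def __post_init__(self):
        for name in ("n_tumor", "n_cellline", "n_pos", "n_neg", "n_null",
                     "n_mutations", "n_mirna", "n_drugs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must be in [0, 1)")
        if self.h0 <= 0:
            raise ValueError("h0 must be > 0")

    @property
    def r_star(self) -> float:
        return self.beta / math.sqrt(self.beta**2 + self.sigma**2)

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated cohort."""

    z: pd.Series
    planted_pos: list[str]
    planted_neg: list[str]
    null_genes: list[str]
    seed_gene: str
    r_star: float
    true_hr_per_unit: float = float("nan")

    def __post_init__(self):
        classes = [set(self.planted_pos), set(self.planted_neg), set(self.null_genes)]
        total = sum(len(c) for c in classes)
        union = set().union(*classes)
        if total != len(union):
            raise ValueError("truth classes overlap")

    @property
    def all_genes(self) -> set[str]:
        return {self.seed_gene} | set(self.planted_pos) | set(self.planted_neg) | set(self.null_genes)


def _gene_names(cfg: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    pos = [f"POS{i:04d}" for i in range(1, cfg.n_pos + 1)]
    neg = [f"NEG{i:04d}" for i in range(1, cfg.n_neg + 1)]
    null = [f"NULL{i:04d}" for i in range(1, cfg.n_null + 1)]
    return pos, neg, null


def _expression_from_z(cfg: SimulationConfig, z: np.ndarray, rng: np.random.Generator,
                       sample_ids: list[str]) -> tuple[ExpressionMatrix, SyntheticTruth]:
    pos, neg, null = _gene_names(cfg)
    genes = [cfg.seed_gene] + pos + neg + null
    n_genes, n = len(genes), len(z)
    beta_g = np.concatenate([
        [cfg.beta], np.full(cfg.n_pos, cfg.beta), np.full(cfg.n_neg, -cfg.beta),
        np.zeros(cfg.n_null),
    ])
    noise_sd = np.full(n_genes, cfg.sigma)
    noise_sd[0] = cfg.seed_noise_sd
    mu = rng.normal(cfg.mu_mean, cfg.mu_sd, size=n_genes)
    eps = rng.normal(0.0, 1.0, size=(n_genes, n)) * noise_sd[:, None]
    values = mu[:, None] + beta_g[:, None] * z[None, :] + eps
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    truth = SyntheticTruth(
        z=pd.Series(z, index=sample_ids, name="z"),
        planted_pos=pos, planted_neg=neg, null_genes=null,
        seed_gene=cfg.seed_gene, r_star=cfg.r_star,
        true_hr_per_unit=math.exp(cfg.gamma),
    )
    return expr, truth


def generate_cohort(
    config: SimulationConfig,
    seed: int,
    n_samples: int | None = None,
    prefix: str = "S",
    z: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one expression cohort and its ground truth.

    ``n_samples`` defaults to ``config.n_tumor``.  Pass the ``z`` of a
    previous cohort to share the latent factor across paired cohorts
    (equivalently set ``config.shared_z`` and reuse ``truth.z``).
    """
    n = config.n_tumor if n_samples is None else int(n_samples)
    if n < 3:
        raise ValueError("n_samples must be >= 3 (correlations undefined below)")
    rng = np.random.default_rng(seed)
    zvec = rng.normal(0.0, 1.0, size=n) if z is None else np.asarray(z, dtype=float)
    if len(zvec) != n:
        raise ValueError("provided z length does not match n_samples")
    samples = [f"{prefix}{i:04d}" for i in range(1, n + 1)]
    return _expression_from_z(config, zvec, rng, samples)


def generate_survival(
    z: pd.Series,
    gamma: float,
    h0: float,
    censor_frac: float,
    seed: int,
) -> SurvivalTable:
    """Exponential survival with hazard h0*exp(gamma*z) and uniform censoring.

    Censoring times are uniform on [0, T_max] with T_max solved so the
    expected censored fraction over the given z equals ``censor_frac``.
    """
    z = pd.Series(z)
    zv = z.to_numpy(dtype=float)
    if not np.isfinite(zv).all():
        raise ValueError("z must be finite")
    if h0 <= 0:
        raise ValueError("h0 must be > 0")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lam = h0 * np.exp(gamma * zv)
    T = rng.exponential(1.0 / lam)
    if censor_frac == 0:
        time, event = T, np.ones(len(zv), dtype=int)
    else:
        # P(censored | T_max) = mean_i (1 - exp(-lam_i t)) / (lam_i t), decreasing in t
        def p_cens(t):
            x = lam * t
            return float(np.mean(-np.expm1(-x) / x)) - censor_frac

        lo, hi = 1e-9 / h0, 1e9 / h0
        t_max = brentq(p_cens, lo, hi, xtol=1e-12, rtol=1e-12)
        C = rng.uniform(0.0, t_max, size=len(zv))
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
    df = pd.DataFrame({"time": time, "event": event}, index=z.index)
    return SurvivalTable(df)


def generate_feature_matrix(
    z: pd.Series,
    n_features: int,
    planted_effects,
    family: str,
    seed: int,
    alpha: float = -1.5,
    mu: float = 0.0,
    sigma: float = 1.0,
    prefix: str | None = None,
) -> pd.DataFrame:
    """Features x samples panel driven by the latent factor.

    ``gaussian``: feature_fi = mu + delta_f * z_i + N(0, sigma^2) (miRNA-like).
    ``binary``: feature_fi ~ Bernoulli(logistic(alpha + delta_f * z_i)) (mutation-like).
    ``planted_effects`` gives delta_f per feature (scalar or length n_features).
    """
    z = pd.Series(z)
    zv = z.to_numpy(dtype=float)
    delta = np.broadcast_to(np.asarray(planted_effects, dtype=float), (n_features,)).copy()
    rng = np.random.default_rng(seed)
    if prefix is None:
        prefix = {"gaussian": "FEAT", "binary": "MUT"}.get(family, "FEAT")
    names = [f"{prefix}{i:04d}" for i in range(1, n_features + 1)]
    if family == "gaussian":
        values = mu + delta[:, None] * zv[None, :] + rng.normal(0.0, sigma, size=(n_features, len(zv)))
    elif family == "binary":
        p = expit(alpha + delta[:, None] * zv[None, :])
        values = (rng.uniform(size=p.shape) < p).astype(int)
    else:
        raise ValueError(f"unknown feature family {family!r}")
    return pd.DataFrame(values, index=names, columns=z.index)


def generate_drug_response(
    group_labels: pd.Series,
    drug_effects: pd.Series,
    sigma_ic50: float,
    seed: int,
    baselines: pd.Series | None = None,
) -> pd.DataFrame:
    """Drugs x cell-lines table of log-IC50 values.

    ``group_labels`` maps cell line -> 'low'/'high'; ``drug_effects``
    maps drug -> shift of the high-group mean log-IC50 (negative means
    the high-activity group is more sensitive).
    """
    group_labels = pd.Series(group_labels)
    levels = group_labels.unique()
    if len(levels) < 2:
        raise ValueError("need >= 2 groups of cell lines")
    counts = group_labels.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 cell lines")
    drug_effects = pd.Series(drug_effects)
    if baselines is None:
        baselines = pd.Series(0.0, index=drug_effects.index)
    rng = np.random.default_rng(seed)
    is_high = (group_labels == "high").to_numpy()
    means = baselines.to_numpy()[:, None] + drug_effects.to_numpy()[:, None] * is_high[None, :]
    noise = rng.normal(0.0, sigma_ic50, size=means.shape) if sigma_ic50 > 0 else 0.0
    return pd.DataFrame(means + noise, index=drug_effects.index, columns=group_labels.index)


def generate_healthy_panel(
    config: SimulationConfig,
    seed: int,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Healthy-tissue panel in which brain samples have depressed activity.

    Brain samples draw z ~ N(-delta_brain, 1); other tissues draw
    z ~ N(0, 1) and cycle through a fixed list of tissue names.
    """
    import warnings as _warnings

    n_brain, n_other = config.n_brain, config.n_other_tissue
    if n_other <= 0:
        raise ValueError("need >= 1 non-brain tissue sample")
    if n_brain == 0 and config.delta_brain != 0:
        _warnings.warn("delta_brain != 0 but no brain samples generated", stacklevel=2)
    rng = np.random.default_rng(seed)
    z = np.concatenate([
        rng.normal(-config.delta_brain, 1.0, size=n_brain),
        rng.normal(0.0, 1.0, size=n_other),
    ])
    labels = ["brain"] * n_brain + [_TISSUES[i % len(_TISSUES)] for i in range(n_other)]
    samples = [f"T{i:04d}" for i in range(1, n_brain + n_other + 1)]
    expr, _ = _expression_from_z(config, z, rng, samples)
    return expr, pd.Series(labels, index=samples, name="tissue")
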