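"""End-to-end orchestration: derive -> score -> split -> associate -> survive.

A run is driven by a :class:`RunConfig` (usually loaded from YAML).  The
pipeline either simulates its inputs with :mod:`exprest.synthetic` or
loads them from disk, then writes the full report bundle —
signature.tsv, scores.tsv, groups.tsv, assoc_mrna.tsv, assoc_mirna.tsv,
assoc_mutations.tsv, drugs.tsv, enrich.tsv, survival.json and a
manifest.json with parameters, seed and content hashes.  Identical
(config, seed) pairs produce byte-identical outputs; every stage is
recomputed on each run (runs take seconds, so caching would only add
staleness risk).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, signature as sig, survival_analysis as surv, synthetic
from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SurvivalTable,
    read_clinical_table,
    read_expression_matrix,
    read_gene_sets,
    write_clinical_table,
    write_expression_matrix,
    write_gmt,
    write_signature,
)

logger = logging.getLogger("exprest")

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "exprest_run"
    seed: int = 0
    seed_gene: str = "REST"
    cutoff: float = 0.3
    cutoff_rule: str = "both"
    standardize: str = "zscore"
    fdr_method: str = "bum"
    fdr_level: float = 0.01
    simulate: dict | None = None          # SimulationConfig overrides, or None
    inputs: dict = field(default_factory=dict)  # cohort_a/cohort_b/clinical/...

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        fdr = raw.pop("fdr", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if isinstance(fdr, dict):
            cfg.fdr_method = fdr.get("method", cfg.fdr_method)
            cfg.fdr_level = float(fdr.get("level", cfg.fdr_level))
        return cfg

    def validate(self) -> None:
        if self.simulate is None and not self.inputs:
            raise ValueError("config must provide either 'simulate' or 'inputs'")
        for key, path in (self.inputs or {}).items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {key!r}: no such file {path}")
        if not 0 < self.fdr_level <= 1:
            raise ValueError("fdr_level must be in (0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, index_label: str) -> None:
    out = df.copy()
    out.index.name = index_label
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _simulate_inputs(config: RunConfig, outdir: Path):
    """Generate the packaged synthetic study and write its input files."""
    sim_kw = dict(config.simulate or {})
    scfg = synthetic.SimulationConfig(**sim_kw)
    seed = int(config.seed)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)

    expr_a, truth_a = synthetic.generate_cohort(scfg, seed=seed, n_samples=scfg.n_tumor, prefix="TUM")
    if scfg.shared_z:
        if scfg.n_cellline > scfg.n_tumor:
            raise ValueError("shared_z requires n_cellline <= n_tumor")
        expr_b, truth_b = synthetic.generate_cohort(
            scfg, seed=seed + 1, n_samples=scfg.n_cellline, prefix="CL",
            z=truth_a.z.to_numpy()[: scfg.n_cellline])
    else:
        expr_b, truth_b = synthetic.generate_cohort(
            scfg, seed=seed + 1, n_samples=scfg.n_cellline, prefix="CL")
    clinical = synthetic.generate_survival(
        truth_a.z, scfg.gamma, scfg.h0, scfg.censor_frac, seed=seed + 2)
    mut_delta = np.concatenate([
        np.full(scfg.n_planted_mutations, scfg.mutation_delta),
        np.zeros(scfg.n_mutations - scfg.n_planted_mutations),
    ])
    mutations = synthetic.generate_feature_matrix(
        truth_a.z, scfg.n_mutations, mut_delta, family="binary",
        seed=seed + 3, alpha=scfg.mutation_alpha)
    mirna_delta = np.concatenate([
        np.full(scfg.n_planted_mirna, scfg.mirna_beta),
        np.zeros(scfg.n_mirna - scfg.n_planted_mirna),
    ])
    mirna = synthetic.generate_feature_matrix(
        truth_a.z, scfg.n_mirna, mirna_delta, family="gaussian",
        seed=seed + 4, mu=5.0, sigma=scfg.sigma, prefix="MIR")
    # true (z-based) cell-line groups drive the planted drug effects
    z_b = truth_b.z
    true_groups = pd.Series(
        np.where(z_b <= z_b.median(), "low", "high"), index=z_b.index, name="group")
    drug_effects = pd.Series(
        np.concatenate([
            np.full(scfg.n_planted_drugs, scfg.drug_delta),
            np.zeros(scfg.n_drugs - scfg.n_planted_drugs),
        ]),
        index=[f"DRUG{i:03d}" for i in range(1, scfg.n_drugs + 1)],
    )
    ic50 = synthetic.generate_drug_response(
        true_groups, drug_effects, scfg.ic50_sigma, seed=seed + 5)

    # gene sets: the planted signature plus null sets drawn from null genes
    rng = np.random.default_rng(seed + 6)
    null_pool = list(truth_a.null_genes)
    sets = {"PLANTED_SIGNATURE": GeneSet("planted positively and negatively loaded genes",
                                         truth_a.planted_pos + truth_a.planted_neg)}
    for i in range(1, 6):
        members = sorted(rng.choice(null_pool, size=25, replace=False))
        sets[f"NULL_SET_{i}"] = GeneSet("random null genes", list(members))
    collection = GeneSetCollection(sets)

    write_expression_matrix(expr_a, indir / "cohort_a.tsv")
    write_expression_matrix(expr_b, indir / "cohort_b.tsv")
    write_clinical_table(clinical, indir / "clinical.tsv")
    _write_table(mutations, indir / "mutations.tsv", "feature")
    mirna_out = mirna.copy()
    mirna_out.index.name = "mirna"
    mirna_out.to_csv(indir / "mirna.tsv", sep="\t", float_format="%.17g")
    _write_table(ic50, indir / "ic50.tsv", "drug")
    write_gmt(collection, indir / "sets.gmt")
    truth_json = {
        "r_star": truth_a.r_star,
        "true_hr_per_unit_z": truth_a.true_hr_per_unit,
        "planted_pos": truth_a.planted_pos,
        "planted_neg": truth_a.planted_neg,
        "z_tumor": {k: round(float(v), 10) for k, v in truth_a.z.items()},
        "z_cellline": {k: round(float(v), 10) for k, v in truth_b.z.items()},
        "planted_drugs": list(drug_effects.index[drug_effects != 0]),
        "planted_mutations": list(mutations.index[: scfg.n_planted_mutations]),
    }
    with open(indir / "truth.json", "wt", encoding="utf-8") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True)
    return {
        "expr_a": expr_a, "expr_b": expr_b, "clinical": clinical,
        "mutations": mutations, "mirna": mirna, "ic50": ic50,
        "gene_sets": collection,
    }


def _load_inputs(config: RunConfig):
    paths = config.inputs
    data = {
        "expr_a": read_expression_matrix(paths["cohort_a"]),
        "expr_b": read_expression_matrix(paths["cohort_b"]),
    }
    data["clinical"] = read_clinical_table(paths["clinical"]) if "clinical" in paths else None
    for key, name in (("mutations", "mutations"), ("mirna", "mirna"), ("ic50", "ic50")):
        data[key] = (pd.read_csv(paths[name], sep="\t", index_col=0)
                     if name in paths else None)
        if key == "mutations" and data[key] is not None:
            data[key] = data[key].astype(int)
    data["gene_sets"] = read_gene_sets(paths["gene_sets"]) if "gene_sets" in paths else None
    return data


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the manifest dictionary.  Any stage failure aborts the run
    with a :class:`PipelineError` naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    outputs: dict[str, Path] = {}
    partial = False
    try:
        stage = "inputs"
        data = _simulate_inputs(config, outdir) if config.simulate is not None else _load_inputs(config)
        logger.info("inputs ready: cohort A %s, cohort B %s",
                    data["expr_a"].shape, data["expr_b"].shape)

        stage = "derive"
        prof_a = sig.pearson_profile(data["expr_a"], config.seed_gene, cohort="A")
        prof_b = sig.pearson_profile(data["expr_b"], config.seed_gene, cohort="B")
        signature = sig.derive_signature(prof_a, prof_b, cutoff=config.cutoff,
                                         rule=config.cutoff_rule)
        write_signature(signature, outdir / "signature.tsv")
        outputs["signature.tsv"] = outdir / "signature.tsv"
        logger.info("signature: %d REST-type, %d RESTless-type genes",
                    len(signature.rest_type), len(signature.restless_type))

        stage = "score"
        scores = sig.compute_rest_score(data["expr_a"], signature,
                                        standardize=config.standardize)
        split = sig.dichotomize_by_median(scores)
        score_df = pd.DataFrame({"rest_score": split.scores, "group": split.groups})
        _write_table(score_df[["rest_score"]], outdir / "scores.tsv", "sample")
        _write_table(score_df[["group"]], outdir / "groups.tsv", "sample")
        outputs["scores.tsv"] = outdir / "scores.tsv"
        outputs["groups.tsv"] = outdir / "groups.tsv"

        stage = "assoc_mrna"
        mrna = assoc.spearman_scan(split, data["expr_a"].values)
        if config.fdr_method == "bum":
            fit = assoc.fit_bum(np.clip(mrna["p"].to_numpy(), 1e-300, 1.0))
            tau, mask, count = assoc.bum_significant(fit, mrna["p"].to_numpy(),
                                                     config.fdr_level)
            mrna["bum_significant"] = mask
            mrna.attrs.update(bum_lam=fit.lam, bum_a=fit.a,
                              bum_pi0_upper=fit.pi0_upper, bum_tau=tau)
            logger.info("BUM fit lam=%.3f a=%.3f pi0_upper=%.3f; %d genes at FDR %g",
                        fit.lam, fit.a, fit.pi0_upper, count, config.fdr_level)
        _write_table(mrna, outdir / "assoc_mrna.tsv", "gene")
        outputs["assoc_mrna.tsv"] = outdir / "assoc_mrna.tsv"

        stage = "assoc_mirna"
        if data["mirna"] is not None:
            mir = assoc.spearman_scan(split, data["mirna"])
            _write_table(mir, outdir / "assoc_mirna.tsv", "mirna")
            outputs["assoc_mirna.tsv"] = outdir / "assoc_mirna.tsv"

        stage = "assoc_mutations"
        if data["mutations"] is not None:
            mut = assoc.mutation_scan(split, data["mutations"])
            _write_table(mut, outdir / "assoc_mutations.tsv", "feature")
            outputs["assoc_mutations.tsv"] = outdir / "assoc_mutations.tsv"

        stage = "drugs"
        if data["ic50"] is not None:
            cl_scores = sig.compute_rest_score(data["expr_b"], signature,
                                               standardize=config.standardize)
            cl_split = sig.dichotomize_by_median(cl_scores)
            drugs = assoc.drug_sensitivity_scan(cl_split.groups, data["ic50"])
            _write_table(drugs, outdir / "drugs.tsv", "drug")
            outputs["drugs.tsv"] = outdir / "drugs.tsv"

        stage = "enrich"
        if data["gene_sets"] is not None:
            universe = set(data["expr_a"].gene_ids)
            query = [g for g in signature.genes if g in universe]
            enrich = assoc.hypergeom_geneset_scan(query, data["gene_sets"], universe)
            _write_table(enrich, outdir / "enrich.tsv", "set")
            outputs["enrich.tsv"] = outdir / "enrich.tsv"

        stage = "survival"
        if data["clinical"] is not None:
            clinical = data["clinical"]
            groups = split.groups.loc[split.groups.index.intersection(clinical.data.index)]
            chi2, p_lr = surv.logrank(clinical, groups)
            cox_bin = surv.cox_hr(clinical, groups, type="binary")
            cox_cont = surv.cox_hr(clinical, split.scores.loc[groups.index],
                                   type="continuous")
            curves = surv.km_estimate(clinical, groups)
            result = {
                "logrank": {"chi2": chi2, "p": p_lr},
                "cox_binary": {"hr": cox_bin.hr, "ci": [cox_bin.ci_low, cox_bin.ci_high],
                               "p": cox_bin.p_wald, "n_events": cox_bin.n_events},
                "cox_continuous": {"hr_per_unit": cox_cont.hr,
                                   "ci": [cox_cont.ci_low, cox_cont.ci_high],
                                   "p": cox_cont.p_wald},
                "km": {c.label: {"times": [round(float(t), 6) for t in c.times],
                                 "survival": [round(float(s), 6) for s in c.survival],
                                 "n": c.n, "n_events": c.n_events}
                       for c in curves},
            }
            with open(outdir / "survival.json", "wt", encoding="utf-8") as fh:
                json.dump(result, fh, indent=2, sort_keys=True)
            outputs["survival.json"] = outdir / "survival.json"
            logger.info("log-rank chi2=%.3f p=%.4g; HR(high vs low)=%.3f", chi2, p_lr, cox_bin.hr)
    except Exception as exc:
        partial = True
        manifest = _manifest(config, outputs, partial=True)
        with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.removeHandler(handler)
        handler.close()
        raise PipelineError(stage, exc) from exc

    manifest = _manifest(config, outputs, partial=partial)
    with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.removeHandler(handler)
    handler.close()
    return manifest


def _manifest(config: RunConfig, outputs: dict[str, Path], partial: bool) -> dict:
    import lifelines
    import scipy
    import statsmodels

    from . import __version__

    return {
        "parameters": asdict(config),
        "seed": config.seed,
        "partial": partial,
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in outputs.items()},
        "versions": {
            "exprest": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "lifelines": lifelines.__version__,
        },
    }
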