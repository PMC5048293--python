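# exprest

Seed-guided derivation of a two-set expression signature, per-sample
activity scoring, and the downstream association / survival /
drug-sensitivity statistics — with a synthetic cohort generator that
plants a known latent activity factor so every stage can be benchmarked
against ground truth.

The package is aimed at computational biologists who want to quantify
the activity of a transcriptional regulator (the motivating case is the
repressor REST/NRSF in glioblastoma) from bulk expression profiles when
no direct assay of that activity is available, and to ask whether the
resulting score stratifies tumors by subtype, mutation status, drug
response and overall survival.

## The method

**Signature derivation.** Given two independent cohorts (e.g. CNS cell
lines and tumors), every gene *g* is correlated with a seed gene (REST)
in each cohort. Genes whose Pearson correlations are sign-consistent
across cohorts and satisfy |r| ≥ 0.3 in both are kept: positively
correlated genes form the REST-type set G_R, negatively correlated genes
the RESTless-type set G_L.

**Activity score.** For sample *i* with expression e_gi,

```
S_i = (1/|G_R|) Σ_{g∈G_R} e_gi − (1/|G_L|) Σ_{g∈G_L} e_gi
```

so a large S_i means enhanced REST activity. Samples are split into
low/high groups at the median score for Kaplan–Meier analysis. When a
signature is applied across platforms, genes are z-scored within the
scored cohort first (`standardize="zscore"`); `standardize="none"`
reproduces the literal formula.

**Statistics.** Spearman scans against mRNA/miRNA panels with
beta-uniform-mixture (BUM) FDR estimation — the p-value density is
modelled as f(p) = λ + (1−λ)·a·p^(a−1), the null proportion is bounded
by π₀ = λ + (1−λ)·a, and the plug-in FDR at threshold τ is
π₀τ / (λτ + (1−λ)τ^a) — plus Benjamini–Hochberg adjustment, pooled t
tests for mutations and IC50 comparisons (fold change = exp of the mean
log-IC50 difference, < 1 meaning high-activity lines are more
sensitive), one-way ANOVA with Tukey HSD for subtypes, Fisher/
hypergeometric gene-set enrichment, Kolmogorov–Smirnov shift tests,
Ward clustering under 1 − Pearson distance, log-rank tests and Cox
proportional-hazards regression (Efron ties, Wald intervals).

## Worked example

```python
import numpy as np
from exprest import (SimulationConfig, generate_cohort, pearson_profile,
                     derive_signature, compute_rest_score, dichotomize_by_median)
from exprest.synthetic import generate_survival
from exprest import survival_analysis as surv

cfg = SimulationConfig()   # 400 tumors, 50 cell lines, 30+10 planted genes, r* = 0.5
tumors, truth = generate_cohort(cfg, seed=1, n_samples=cfg.n_tumor, prefix="TUM")
cells, _ = generate_cohort(cfg, seed=2, n_samples=cfg.n_cellline, prefix="CL")

signature = derive_signature(pearson_profile(tumors, "REST"),
                             pearson_profile(cells, "REST"), cutoff=0.3)
scores = dichotomize_by_median(compute_rest_score(tumors, signature,
                                                  standardize="zscore"))
print(np.corrcoef(scores.scores, truth.z)[0, 1])

clinical = generate_survival(truth.z, cfg.gamma, cfg.h0, cfg.censor_frac, seed=3)
chi2, p = surv.logrank(clinical, scores.groups)
cox = surv.cox_hr(clinical, scores.groups, type="binary")
```

Output:

```
signature: 30 REST-type + 10 RESTless-type genes
score vs latent activity: r = 0.941
log-rank chi2 = 6.99, p = 0.0082
Cox HR (high vs low) = 1.39, 95% CI 1.09-1.77
```

The derived signature recovers the planted gene sets, the score tracks
the latent activity factor it was never shown (r = 0.94), and the
median split detects the planted survival effect (true hazard ratio 1.5
per unit of latent activity).

The same analysis runs from the shell:

```
exprest simulate --outdir demo --seed 1
exprest derive --cohort-a demo/inputs/cohort_a.tsv \
               --cohort-b demo/inputs/cohort_b.tsv -o demo/signature.tsv
exprest score  --expr demo/inputs/cohort_a.tsv \
               --signature demo/signature.tsv -o demo/scores.tsv
exprest survival --clinical demo/inputs/clinical.tsv \
                 --scores demo/scores.tsv -o demo/survival.json
```

or as one reproducible pipeline, `exprest run --config run.yaml`, which
writes the full report bundle (signature, scores, groups, mRNA/miRNA/
mutation associations, drug screen, enrichment, survival JSON) plus a
manifest with content hashes.

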