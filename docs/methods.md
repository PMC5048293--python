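# Methods

## Model and procedure

The package treats the activity of a transcriptional regulator (REST in
the motivating application) as a scalar per sample that is not directly
observed. Two proxies connect it to data:

1. **Seed-guided signature derivation.** In each of two cohorts, every
   gene is correlated (Pearson) with the seed gene's own expression.
   Genes are retained when the two cohort correlations share a sign and
   both magnitudes reach the cutoff (default 0.3). Positive members form
   the REST-type set G_R, negative members the RESTless-type set G_L.
   Requiring the cutoff in *both* cohorts (rather than in either, or on
   the mean) is the strictest of the three plausible rules and is the
   default because it maximizes cross-cohort consistency of the
   resulting signature; `rule="either"` and `rule="mean"` are available.
   The seed gene itself is kept in G_R by default (`include_seed=False`
   removes it).

2. **Mean-difference score.** S_i = mean expression over G_R minus mean
   expression over G_L. The score is linear, so adding a per-sample
   constant to all genes cancels whenever both sets are non-empty, and
   scaling all expression by c > 0 scales S by c. For cross-platform
   application the default is to z-score each gene within the scored
   cohort before averaging, which makes S invariant to per-gene affine
   rescalings (different array platforms); `standardize="none"` is the
   literal formula and is what the raw-scale worked examples use.
   Signature genes absent from a matrix are skipped, with the per-set
   coverage fraction reported and a warning under 80% coverage. Samples
   are dichotomized at the median with ties assigned to "low" — a
   deterministic rule that keeps groups within one sample of balance.

## Synthetic cohorts

The generator emulates the study design end to end with a
one-dimensional latent factor:

- z_i ~ N(0,1); expression e_gi = μ_g + β_g z_i + ε_gi with
  ε ~ N(0, σ²); β_g is +β for planted REST-type genes, −β for planted
  RESTless-type genes, 0 for nulls. The planted gene–factor correlation
  is r* = β/√(β²+σ²).
- The seed gene is generated with zero intrinsic noise by default
  (`seed_noise_sd = 0`): its expression *is* the latent activity on the
  expression scale. This is the modelling statement that seed mRNA is a
  faithful readout of activity; it also makes gene–seed correlations
  equal r*, so the planted correlation is the quantity the derivation
  step actually sees. Setting `seed_noise_sd = σ` instead attenuates
  gene–seed correlations to r*², which is the regime where seed mRNA is
  itself a noisy proxy.
- Survival times are exponential with hazard h₀·exp(γ·z_i) and uniform
  censoring on [0, T_max], with T_max solved by root finding so the
  expected censored fraction over the realized z equals `censor_frac`.
- Binary features (mutations) are Bernoulli(logistic(α + δ·z_i));
  Gaussian panels (miRNA) reuse the expression model; log-IC50 values
  are N(baseline + Δ·1[group = high], σ²) per drug, with the *true*
  (z-based) median split defining the groups that carry the planted
  drug effects.
- The healthy-tissue panel draws brain samples with z shifted by
  −δ_brain (default 2 latent-sd) against a background of 36 samples
  cycling through 12 non-neural tissue labels.

Default sizes are the benchmark conditions used throughout the tests:
400 tumors / 50 cell lines, 30 positive + 10 negative planted genes at
r* = 0.5 among 500 nulls, survival effect γ = ln(1.5) per unit z with
30% censoring, 3 planted mutations among 20, 10 loaded miRNAs among 50,
and 1 drug with Δ = −2 log-IC50 among 31. These sizes keep every
benchmark comfortably powered while running in seconds.

What the generator does **not** emulate: realistic marginal expression
distributions, batch or platform effects, gene–gene correlation beyond
the single shared factor, non-proportional hazards, or informative
censoring. Passing benchmarks therefore demonstrate correctness of the
machinery under the stated generative model, not robustness to the
messiness of real cohorts.

## Statistical components

- **Spearman scan**: midranks for ties; two-sided p from the
  t approximation for n > 10 and from exhaustive permutation
  (all n! pairings, evaluated in chunks) for n ≤ 10, where the
  t approximation is unreliable.
- **BUM FDR**: f(p) = λ + (1−λ)·a·p^(a−1) fitted by maximum likelihood
  with λ and a logit-reparameterized (box constraints without clipping)
  and L-BFGS restarted from five fixed interior starts. π₀ is reported
  as the upper bound λ + (1−λ)a. The plug-in FDR(τ) =
  π₀τ/(λτ + (1−λ)τ^a) is increasing in τ, so the significance threshold
  at a target level is found by root bracketing. Fits pinned against a
  boundary (notably a → 1, where the density is uniform and λ is not
  identifiable) are flagged; in that pure-null regime FDR(τ) = π₀ for
  every τ, so no threshold satisfies a target below π₀ and nothing is
  called — the conservative behaviour.
- **Two-group comparisons**: pooled-variance Student t (two-sided) with
  Cohen's d; mutations and drug screens apply it per feature with BH
  adjustment across features. IC50 fold changes are exp(Δ mean log-IC50)
  — the geometric-mean ratio, robust to the outliers that dominate
  arithmetic means of raw IC50s — oriented high/low so fold change < 1
  means high-activity lines are more sensitive.
- **ANOVA/Tukey**: one-way F test; Tukey HSD p-values from the
  studentized range for every pair regardless of the omnibus result.
- **Enrichment**: exact hypergeometric tails (one-sided, greater) per
  gene set after intersecting each set with the declared universe, BH
  across sets. The KS target-vs-nontarget comparison defaults to the
  one-sided "targets stochastically smaller" alternative, with the exact
  null distribution when m·n ≤ 10⁴.
- **Survival**: lifelines supplies the product-limit estimator,
  log-rank statistic and Cox partial likelihood (Efron tie handling —
  appropriate for day-resolution data with many ties). Confidence
  intervals are Wald intervals on the log-HR scale. Subjects with
  time 0 and no event are dropped with a warning. Sidedness defaults
  (two-sided everywhere except the enrichment and KS tests) are
  configurable at each call.

## Numerical choices

- Expression and clinical tables are written at full float precision so
  write→read round-trips are loss-free; signature correlations are
  written at six decimals; report tables at six significant digits.
- Missing expression values are rejected by default; row-mean
  imputation is opt-in.
- Correlations are clipped to [−1, 1] after computation to absorb
  floating-point overshoot; zero-variance genes are excluded from
  profiles (reported) and refused by the clustering step (named in the
  error).
- Ward clustering uses the Lance–Williams recurrence on 1 − Pearson
  distances with ties broken by input order, giving a deterministic
  leaf order.
- All generators accept an integer seed and are bitwise reproducible;
  the pipeline writes a manifest with SHA-256 hashes of every output and
  produces byte-identical bundles for identical (config, seed).
- The pipeline recomputes every stage on each run rather than caching
  intermediates on disk: runs take seconds at these problem sizes and a
  cache would only introduce staleness risk.

## Benchmark sizes

The acceptance battery uses 20 replicate cohort pairs for signature
recovery, 1000 replicates per type-I calibration, exhaustive
enumeration of all hypergeometric tables with N ≤ 12, 200/100
replicates for binary/continuous Cox recovery, 100 replicates of the
31-drug screen, and two full pipeline runs for the determinism check —
about one minute of compute in total.

## Known limitations

- The BUM π₀ is an upper bound; realized FDR at a target level is
  therefore conservative by roughly the ratio of true null fraction to
  the bound.
- Exact permutation Spearman p-values cost n! statistic evaluations and
  are restricted to n ≤ 10 by design.
- Cox fitting is univariable by design; no proportional-hazards
  diagnostics are provided.
- The probe-to-gene mapping, expression normalization (RSEM/MAS5) and
  subtype classification are assumed to happen upstream; identifiers
  are matched case-sensitively as given.
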