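# Methods

## The measurement protocol being modelled

A slide is read as three representative 100X fields. Every *complete*
epithelial cell — one whose outline lies entirely within the image,
boundary-inclusive — is counted, and the per-slide measure is the mean of
the three field counts. One representative cell-aggregate outline is
measured per field ("measure outline" area, µm²); the per-slide measure is
the mean of the three areas, taking the largest outline when a field shows
several. When the mean count is at or below 50 cells per field, all
complete cells are classified by maturity and the superficial cell index
SCI = n_superficial / n_total is computed over the three fields pooled.
The ≤ 50 gate is boundary-inclusive: a mean count of exactly 50 is scored.

In the original protocol cells were classified by eye. Here the
qualitative cytology — condensed nucleus, large cytoplasmic space,
polygonal shape with thin angular margins — is operationalised as a
deterministic rule on three features: nucleus fraction
f = nucleus area / cell area, cell area A, and angularity g (fraction of
interior vertex angles below 150°). Defaults: superficial iff f ≤ 0.10,
A ≥ 2,000 µm² and g ≥ 0.5; parabasal iff f ≥ 0.30 and A ≤ 800 µm²;
intermediate otherwise. These thresholds are this package's calibration of
a visual judgement, not measured constants; they are exposed in
`ClassifierThresholds` and should be re-tuned before any use on real
segmentations. Fields are continuous-µm frames with origin at the
lower-left corner, default 1,340 × 1,000 µm (a nominal 100X field; the
absolute frame is a package choice, only the scale matters).

## Statistical models

All models share weakly-informative priors — Normal(0, 10) on locations on
the modelled scale, half-Cauchy(2.5) on every positive scale — and are
sampled with an adaptive Metropolis-within-Gibbs engine (below). The model
families are the ones standard for this design; the specific linear
predictors, priors and sampler settings are this package's choices and are
fully config-overridable.

**Counts and aggregate areas** (robust location comparison).
z_ij = log10 y_ij for sample j of woman i:

    z_ij ~ Laplace(μ_g(ij) + b_i, s),   b_i ~ Normal(0, σ_b).

The Laplace likelihood makes μ_g a median-type location, insensitive to
the occasional extreme smear; 10^μ_g is reported on the original scale.
Samples, not women, are the rows; within-woman correlation is carried by
the subject intercepts b_i. Units entering the model are per-slide means
(the three per-field measurements are averaged upstream).

**SCI** (binomial mixed model, fitted only to gated samples with scored
cells):

    s_ij ~ Binomial(n_ij, p_ij),   logit p_ij = α_g(ij) + u_i,
    u_i ~ Normal(0, σ_u).

The group-level SCI summary is expit(α_g) — the median-subject proportion,
deliberately not the population-averaged one.

**Within-woman comparison** (for the subset of women observed in both
groups of one contrast, e.g. sBV and aBV):

    y_ij ~ Poisson(λ_ij),   log λ_ij = θ_i + δ·1[g_ij = g₂],

with θ_i ~ Normal(log ȳ, 10) and δ ~ Normal(0, 10); δ is the within-woman
natural-log rate ratio (divide by ln 10 for log10 reporting; responses are
rounded to integers first). *Known limitation:* per-slide mean counts are
strongly overdispersed relative to Poisson (slide-to-slide intensity
variation dominates), so this model's tail probabilities are
anticonservative; treat δ as an effect summary rather than a calibrated
test. The location model above is the calibrated primary comparison.

**Contrasts and multiplicity.** A contrast Δ = μ_g1 − μ_g2 is summarised
by the posterior mean, sd and central 95% credible interval of its draws.
The two-sided p is computed from the Gaussian approximation
p = 2·Φ(−|mean|/sd), which can resolve magnitudes far below 1/(number of
draws); the raw empirical tail fraction is reported alongside, and the two
agree wherever the empirical fraction is resolvable. All contrasts of one
pipeline run — counts, aggregates and SCI, overall and CST IV stratum, and
any paired-model effect — form a single Benjamini–Hochberg family: the
most conservative reproducible family definition.

## The MCMC engine

Componentwise random-walk Metropolis inside a Gibbs sweep, vectorised
across chains and across the components of each block (group locations,
subject effects, scales on the log scale with the Jacobian term). Step
sizes adapt during warmup by Robbins–Monro toward 0.35 acceptance with
gain t^(−0.6), then freeze. Two extra moves fix the slow modes inherent to
hierarchical centred parameterisations:

* an interweaved non-centred scale update — propose σ' and rescale the
  whole random-effect vector by σ'/σ with the standardised effects held
  fixed — which restores mixing when σ sits near zero (the "funnel");
* a likelihood-invariant translation (all group locations +e, all subject
  effects −e), which decorrelates the group means from the subject-effect
  mean.

Defaults: 4 chains × 5,000 iterations, first 2,500 warmup. Every stored
parameter gets a split-R̂ and bulk ESS (via arviz); a fit raises with the
full R̂ table if any R̂ ≥ 1.05. Initial states are dispersed around
data-driven values (per-group medians, pooled proportions) so R̂ is
meaningful. Degenerate inputs are refused early: non-positive responses
under log10, groups with no rows (named in the error), unpaired subjects
(listed), all-zero Poisson responses.

## Synthetic cohort generator

The generator emulates the study design: up to 126 women with scheduled
visits at weeks 0, 5 and 10; each attended visit yields one smear. A
visit-attendance probability (default 192/378) reproduces the study's
~192 analysable smears from 126 women; subjects can change Amsel group
between visits, which also yields the handful of women seen in both sBV
and aBV needed by the paired model. Group probabilities default to the
study's 104:71:17; CST IV probability per group to 31/104, 62/71, 13/17,
with the non-IV remainder spread over *Lactobacillus* CSTs (BV groups'
non-IV samples almost exclusively CST III, matching the study's pattern);
Nugent scores are drawn low (0–3) for noBV and high (7–10) for BV groups,
as metadata only.

Measurements are generated at the level the analysis models them — the
slide. Counts: z ~ Laplace(loc_g + b_i, 0.15) with b_i ~ N(0, 0.10), and
three field counts Poisson around 10^z; the configured location is then
the median of the modelled per-slide mean count, so the defaults
(log10 91, log10 35, log10 158) are calibrated to the published medians.
Aggregates: slide intensity 10^w, w ~ N(log10 median_g, 0.30), defaults
(50,000; 7,000; 220,000) µm², with field-to-field log10 jitter 0.10.
SCI: for gated samples, total = pooled field count and superficial ~
Binomial(total, expit(logit(p_g) + u_i)), u_i ~ N(0, 0.4), p defaults
(0.86, 0.35) for noBV/aBV (0.86 for the essentially-never-gated sBV).
The ≤ 50 gate then *emerges*: with defaults, ~75–85% of aBV samples, a
minority of noBV samples and essentially no sBV samples are gated in,
mirroring the study. Aggregate areas are rounded to 6 significant digits
at generation so tables round-trip bit-stably through the CSV format.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no dependence of morphometry on CST *within* an
Amsel group (the real data's noBV/CST IV samples shed fewer, more immature
cells than other noBV samples — e.g. the published CST IV noBV medians of
64 cells and 0.94 SCI differ from the overall noBV values, a dependence
the generator has no knob for); per-visit group assignment is independent
(no real transition dynamics); no menstrual-cycle or measurement-reader
effects; Poisson field-to-field count variation is idealised.

Scene generation places non-overlapping polygonal cells on a jittered grid
(complete cells fully inside; straddling cells centred on the boundary),
with per-class shape recipes (octagonal angular outlines for superficial
cells, near-circular many-vertex outlines for intermediate/parabasal) that
are exactly separable under the default classifier thresholds, and one
blob-shaped aggregate outline rescaled to the requested area exactly.

## Numerical and design choices

* Quantiles: linear interpolation between order statistics (the common
  default of mainstream numeric stacks), recorded in the run manifest,
  since IQR reproduction depends on the convention.
* Descriptives are per sample, not per woman, matching the study's n's;
  models handle the correlation.
* CSV dialect: UTF-8, comma, '.' decimal, fixed column order; missing
  optional values are empty cells (0 is a legal SCI count and must stay
  distinguishable from "not scored"); reals carry 6 significant digits,
  making write → read → write byte-stable.
* "Complete cell" = every outline vertex inside the field,
  boundary-inclusive — a deterministic tie rule for "partly outside".
* Determinism: every pipeline stage's seed derives from the run seed via
  a seed sequence; identical config + seed give byte-identical exports,
  and the manifest (config hash, seed, version) suffices to re-run.
* Test-time problem sizes are scaled for a single CPU: calibration and
  recovery at 500 subjects; interval coverage over 100 replicates of
  study-sized cohorts with shortened chains; simulation-based calibration
  (rank-uniformity of the generating parameter) over 60 prior-predictive
  replicates per model at small n with tightened prior scales.

## Known limitations

* The maturity classifier is a stand-in for expert reading; its thresholds
  define the synthetic ground truth rather than being validated against
  stained micrographs.
* The paired Poisson model ignores overdispersion (above).
* Tail probabilities rely on approximate posterior normality of the
  contrast; for very small groups the Gaussian-approximate p can deviate
  from the (unresolvable) exact tail mass.
* The generator's independence assumptions mean stratum-level descriptives
  inherit the group-level values; real CST-conditional structure must come
  from real data.
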