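# smearshed

Morphometry and Bayesian group comparison for epithelial cell-shedding
studies of the vaginal microbiome.

Bacterial vaginosis (BV) — diagnosed clinically by Amsel criteria and
split into symptomatic (sBV) and asymptomatic (aBV) forms — is associated
with disturbed shedding of cells from the vaginal epithelium. A
cell-shedding smear study quantifies this from mid-vaginal smears read at
100X magnification: the number of complete epithelial cells per field, the
outline area of cell-aggregates (µm²), and, for sparse smears (mean count
≤ 50 per field), the **superficial cell index**

    SCI = n_superficial / n_total  ∈ [0, 1],

the fraction of shed cells that are mature superficial squames. Groups are
compared overall and within the CST IV microbiota stratum (diverse
anaerobes, no *Lactobacillus* dominance — "molecular BV").

This package implements that analysis end to end for epidemiologists and
microbiome researchers:

* **Measurement table I/O** — a validated CSV schema for per-sample counts,
  aggregate areas, SCI counts, Amsel group, Nugent score and CST label.
* **Morphometry** — complete-cell counting (boundary-inclusive containment
  in the field), shoelace outline areas, a configurable three-feature
  maturity classifier (nucleus fraction, cell area, margin angularity), and
  slide-level read-outs with the ≤ 50 SCI gate.
* **Synthetic cohort generator** — a longitudinal study emulator (126
  women, visits at weeks 0/5/10, ~192 smears) calibrated to the published
  group summaries, with stored ground truth for recovery testing.
* **Bayesian hierarchical models**, sampled with an adaptive
  Metropolis-within-Gibbs engine written here:
  * counts and aggregate areas: `log10 y_ij ~ Laplace(μ_g(ij) + b_i, s)`,
    `b_i ~ N(0, σ_b)` — a robust, median-like location comparison;
  * SCI: `s_ij ~ Binomial(n_ij, p_ij)`, `logit p_ij = α_g(ij) + u_i`;
  * within-woman comparison: `y_ij ~ Poisson(λ_ij)`,
    `log λ_ij = θ_i + δ·1[g_ij = g₂]`.

  Priors are `N(0, 10)` on locations and half-Cauchy(2.5) on scales;
  convergence is enforced at split-R̂ < 1.05.
* **Contrasts and FDR** — posterior group differences with two-sided
  Gaussian-approximate tail probabilities (resolving p ≪ 1/draws) and
  Benjamini–Hochberg adjustment over the whole contrast family of a run.

## Worked example

```python
from smearshed import (AnalysisConfig, CohortConfig, generate_cohort,
                       run_pipeline)

table, truth = generate_cohort(CohortConfig(seed=1))   # ~192 smears
bundle = run_pipeline(AnalysisConfig(seed=7, output_dir="results"), table=table)
print(bundle.contrasts[["outcome", "stratum", "contrast", "mean", "p", "q"]])
```

prints (abridged):

```
                outcome stratum  contrast      mean             p             q
             mean_count overall  noBV-sBV -0.255319  5.548902e-06  5.548902e-06
             mean_count overall  noBV-aBV  0.366940  3.700236e-38  9.867297e-38
mean_aggregate_area_um2 overall  noBV-aBV  0.814470  2.349780e-78  1.253216e-77
                    sci overall  noBV-aBV  2.363076 2.950842e-123 2.360674e-122
```

Read: on the log10 scale, symptomatic-BV smears shed *more* cells than
no-BV smears (negative noBV−sBV difference), asymptomatic-BV smears shed
*fewer* (positive noBV−aBV difference), and the SCI of aBV smears is far
below that of noBV smears on the logit scale — all FDR-significant, and the
pattern persists within the CST IV stratum. `results/` receives
`descriptives.csv` (medians/IQRs per group and stratum), `contrasts.csv`,
`cst_frequencies.csv` and a `manifest.json` that reproduces the run
bit-for-bit.

The `examples/` directory walks through each capability (cohort
simulation, scene morphometry, model fitting, full pipeline); a thin CLI
(`smearshed simulate|morphometry|analyze`) wraps the same functions.

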