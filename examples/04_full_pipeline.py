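"""The full analysis in one call: descriptives, fits, contrasts, FDR.

Produces the study's summary tables — per-group medians/IQRs overall and
within the CST IV stratum, CST frequencies, and the FDR-adjusted contrast
family — and writes them under results_example/ with a reproducibility
manifest.
"""

from smearshed import AnalysisConfig, CohortConfig, generate_cohort, run_pipeline

table, _ = generate_cohort(CohortConfig(seed=1))
bundle = run_pipeline(AnalysisConfig(seed=7, output_dir="results_example"), table=table)

print("descriptives (medians and IQRs, sample level):")
print(bundle.descriptives.round(3).to_string(index=False))

print("\ncontrasts (single BH-FDR family):")
cols = ["outcome", "stratum", "contrast", "mean", "p", "q"]
print(bundle.contrasts[cols].to_string(index=False))
# Expected pattern: sBV > noBV > aBV for counts and aggregate areas
# (negative noBV-sBV mean, positive noBV-aBV and sBV-aBV), noBV > aBV for
# SCI, all with q < 0.05 — including within the CST IV stratum.

print("\nwrote descriptives.csv, contrasts.csv, cst_frequencies.csv, "
      "manifest.json to results_example/")
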