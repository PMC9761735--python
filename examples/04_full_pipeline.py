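"""Run the full causal pipeline: usual intakes -> weights -> risk contrasts.

Executes every analysis stage on a synthetic cohort generated with a true
protective effect of hazard ratio 0.8 per +10 HEFI-2019 points: sodium
derivation, measurement-error-corrected usual scores, stabilized IPTW x
IPCW, the weighted Cox model with restricted cubic splines, and the
counterfactual 11-y risk table at prespecified score percentiles.
"""

from hefi_cvd import GeneratorConfig, PipelineConfig, generate_cohort, run_pipeline

cohort = generate_cohort(GeneratorConfig(n_participants=10_000, seed=3))
result = run_pipeline(
    cohort.observed(),
    PipelineConfig(M=50, seed=4, lambda_grid=(0.0, 0.5)),
)

print(result.risk_table.round(3).to_string(index=False))
print(f"\nreference energy intake: {result.energy_ref:.0f} kcal")
print(f"max covariate imbalance after weighting: "
      f"{result.balance['weighted_corr'].abs().max():.3f} "
      f"(before: {result.balance['unweighted_corr'].abs().max():.3f})")
print(
    "\nEach row: had everyone attained that score percentile, the 11-y CVD"
    "\nrisk, its percentage-point difference vs the no-change (median)"
    "\nscenario, and the risk ratio. Rows above the median are protective"
    "\n(rr < 1) because the cohort was generated with HR 0.8 per +10 points."
)
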