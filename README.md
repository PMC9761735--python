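# hefi-cvd

Diet-quality scoring and measurement-error-corrected causal survival
analysis, at desk scale.

## The problem

How much would cardiovascular risk change if a whole population ate the way
a food guide recommends? Answering that from cohort data requires solving
four problems at once:

1. **Scoring adherence.** The HEFI-2019 (Healthy Eating Food Index 2019)
   measures adherence to Canada's Food Guide 2019 recommendations on
   healthy food choices: 10 components (5 foods, 1 beverage, 4 nutrients)
   worth 80 points, each allocating points proportionally between a
   zero-credit and a full-credit cutoff on a ratio such as the share of
   food intake (in reference amounts) from vegetables and fruits, the
   percent of energy from free sugars, or mg sodium per kcal.
2. **Measurement error.** Diet is observed through repeated 24-h recalls,
   which are noisy snapshots of the latent *usual* (long-term average)
   intake. Two-part random-intercept models per component (probit
   consumption part for episodic foods, Box-Cox linear amount part) with a
   cross-part random-effect covariance are fit to the recalls; per-person
   usual intakes are then simulated by Monte Carlo conditional on each
   person's own recalls, scored, and averaged — the NCI-multivariate-style
   correction.
3. **Confounding and informative censoring.** Health-conscious people both
   eat better and have lower risk. The usual score *A* is treated as a
   continuous exposure: stabilized inverse-probability-of-treatment weights
   `sw_i = φ(a_i; ā, s²) / φ(a_i; x_iβ̂, σ̂²)` come from a linear exposure
   model on spline-expanded confounders; censoring by competing (non-CVD)
   death or loss to follow-up gets inverse-probability-of-censoring weights
   from a logistic model; both factors are rescaled to mean 1 and
   multiplied.
4. **Counterfactual contrasts.** A weighted Cox model with restricted cubic
   splines (4 knots) in the usual score and energy yields standardized
   survival curves `S(t | A = s_p, E = ē)` at prespecified score
   percentiles {5, 10, 25, 50, 75, 90, 95}; 11-year (132-month) risks are
   contrasted against the median ("no change") scenario as absolute (RD)
   and relative (RR) differences, with percentile bootstrap CIs that
   propagate uncertainty from every stage, an HR curve, a pooled-logistic
   sex-stratified analogue, proportional-hazards checks, and E-values.

Real cohorts of this kind are access-controlled, so the package ships a
**synthetic cohort generator** with the same statistical structure —
within-person recall error, episodic foods, a spot-urine sodium assay
generated by inverting the INTERSALT prediction equation, confounding, a
designed exposure effect, ~2.1% 11-y CVD incidence, ~2.6% competing
mortality, ~0.3% loss — and a truth table used only by parameter-recovery
tests.

## Worked example

```python
from hefi_cvd import GeneratorConfig, PipelineConfig, generate_cohort, run_pipeline

cohort = generate_cohort(GeneratorConfig(n_participants=10_000, seed=3))
result = run_pipeline(cohort.observed(),
                      PipelineConfig(M=50, seed=4, lambda_grid=(0.0, 0.5)))
print(result.risk_table.round(3).to_string(index=False))
```

```
 percentile  score  change  risk     rd    rr
       95.0 59.319  13.410 0.006 -1.079 0.373
       90.0 56.801  10.892 0.008 -0.910 0.471
       75.0 51.903   5.994 0.012 -0.498 0.711
       50.0 45.909   0.000 0.017  0.000 1.000
       25.0 39.816  -6.094 0.022  0.491 1.285
       10.0 34.268 -11.641 0.029  1.135 1.660
        5.0 31.072 -14.837 0.033  1.611 1.936
```

Read: this cohort was generated with a true protective hazard ratio of 0.8
per +10 HEFI-2019 points. Had everyone reached the 90th percentile of the
usual-score distribution (56.8 points, +10.9 above the median), the
estimated 11-y CVD risk would fall from 1.7% to 0.8% — a risk ratio of
0.47 and an absolute reduction of 0.91 percentage points; dropping
everyone to the 10th percentile raises risk by 1.1 points (RR 1.66).
Percentile contrasts at ~200 events carry substantial spread and a known
protective overshoot at the tails (`docs/methods.md` §8);
`examples/05_bootstrap_and_evalue.py` attaches bootstrap CIs.

The `examples/` directory has one short script per capability: scoring a
day of eating, generating cohorts, usual-intake correction, the full
pipeline, and bootstrap + E-value.

## Layout

| module | contents |
| --- | --- |
| `hefi_cvd.scoring` | cutoff-agnostic HEFI-2019 engine + packaged standards |
| `hefi_cvd.derivations` | INTERSALT spot-urine sodium, free sugars, energy-reporting plausibility |
| `hefi_cvd.synthetic` | cohort generator (recalls, urine, covariates, outcomes, truth) |
| `hefi_cvd.usual_intake` | two-part measurement-error models, conditional Monte-Carlo draws, percentiles |
| `hefi_cvd.weights` | stabilized IPTW (normal-density), IPCW, balance report |
| `hefi_cvd.outcomes` | weighted Cox + standardized risks, HR curve, pooled logistic, E-value, PH checks |
| `hefi_cvd.pipeline` | imputation, end-to-end orchestration, parametric/resampling bootstrap, report bundle |

Methodological details, defaults and limitations: `docs/methods.md`.
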