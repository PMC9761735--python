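"""End-to-end orchestration and bootstrap inference.

``run_pipeline`` executes the full analysis on observed tables only (the
synthetic truth never enters): single imputation of sparse missing
covariates, urine-based sodium prediction, the multivariate measurement-
error model with Monte-Carlo usual-intake simulation and HEFI-2019 scoring,
score percentiles, stabilized IPTW x IPCW, the weighted Cox model, and the
counterfactual risk table, HR curve, survival curves, covariate balance and
E-values.

``bootstrap_ci`` repeats the post-fit steps B times (default 250) for
percentile confidence intervals. The default "parametric" mode redraws, in
each replicate, (i) the measurement-error model's fixed effects from their
asymptotic normal distribution together with fresh Monte-Carlo usual-intake
draws, (ii) the weight-model coefficients, and (iii) the outcome-model
coefficients from their robust covariance — propagating uncertainty from
every stage without re-fitting the measurement-error model. The
"resample" mode re-runs everything on person-resampled cohorts instead.
Score percentiles are computed once on the full-data run and held fixed
across replicates (they define the estimand).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .derivations import predict_sodium_24h
from .design import covariate_design
from .outcomes import (
    CoxFit,
    evalue,
    fit_weighted_cox,
    hr_curve,
    risk_table_from_params,
    standardized_risk_table,
)
from .scoring import default_standards
from .synthetic import DEFAULT_NATURAL_SUGAR_FACTORS, ObservedCohort, SyntheticCohort
from .usual_intake import (
    DEFAULT_PERCENTILES,
    MeasurementErrorFit,
    draw_usual_intakes,
    fit_measurement_error_model,
    usual_hefi_from_draws,
    usual_score_percentiles,
)
from .weights import balance_report, combine_weights, estimate_ipcw, estimate_iptw

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "BootstrapResult",
    "impute_single",
    "run_pipeline",
    "bootstrap_ci",
    "report",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the end-to-end analysis."""

    M: int = 1000                       # Monte-Carlo usual-intake draws/person
    B: int = 250                        # bootstrap replicates
    percentiles: Sequence[float] = DEFAULT_PERCENTILES
    horizon_months: float = 132.0       # 11 years
    energy_ref: float | None = None     # None: weighted mean energy
    seed: int = 0
    bootstrap_mode: str = "parametric"  # or "resample"
    lambda_grid: Sequence[float] | None = None
    conditional_draws: bool = True
    weight_truncation_percentile: float | None = None
    min_events: int = 50
    max_missing: float = 0.10
    imputation: str = "regression-mean/mode"

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2 for confidence intervals")
        if self.bootstrap_mode not in ("parametric", "resample"):
            raise ValueError("bootstrap_mode must be 'parametric' or 'resample'")


@dataclass
class PipelineResult:
    risk_table: pd.DataFrame
    percentile_table: pd.DataFrame
    usual_summary: pd.DataFrame
    weights: pd.DataFrame
    balance: pd.DataFrame
    hr_curve: pd.DataFrame
    survival_curves: pd.DataFrame
    radar: pd.DataFrame
    evalues: dict
    energy_ref: float
    me_fit: MeasurementErrorFit
    cox_fit: CoxFit
    imputation_flags: pd.DataFrame
    config: PipelineConfig
    seeds: dict


@dataclass
class BootstrapResult:
    point: pd.DataFrame          # risk table with CI columns
    replicates: pd.DataFrame     # replicate-level rows for audit
    n_failed: int
    mode: str


# ---------------------------------------------------------------------------

def impute_single(
    covariates: pd.DataFrame, max_missing: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single imputation of sparse missing covariates.

    Continuous covariates get the conditional mean from a regression on the
    complete covariates; categorical/binary covariates the modal category.
    Returns the completed table and a boolean flag table of imputed cells.
    """
    out = covariates.copy()
    flags = pd.DataFrame(False, index=out.index, columns=[c for c in out.columns if c != "person_id"])
    cols = [c for c in out.columns if c != "person_id"]
    complete_cols = [c for c in cols if out[c].notna().all()]
    for col in cols:
        miss = out[col].isna()
        if not miss.any():
            continue
        frac = float(miss.mean())
        if frac == 1.0:
            raise ValueError(f"covariate {col!r} entirely missing")
        if frac > max_missing:
            raise ValueError(
                f"covariate {col!r} missing {frac:.1%} (> ceiling {max_missing:.0%})"
            )
        x = out[col]
        continuous = pd.api.types.is_float_dtype(x) and x.nunique() > 10
        if continuous and complete_cols:
            X = sm.add_constant(out.loc[:, complete_cols].astype(float))
            model = sm.OLS(x[~miss], X[~miss]).fit()
            out.loc[miss, col] = model.predict(X[miss])
        elif continuous:
            out.loc[miss, col] = x.mean()
        else:
            out.loc[miss, col] = x.mode().iloc[0]
        flags.loc[miss, col] = True
    return out, flags


def _check_observed(cohort) -> ObservedCohort:
    if isinstance(cohort, SyntheticCohort):
        raise TypeError(
            "run_pipeline consumes observed tables only; pass cohort.observed()"
        )
    for table_name in ("recalls", "urine", "covariates", "outcomes"):
        table = getattr(cohort, table_name)
        leaked = [c for c in table.columns if c.startswith("true_")]
        if leaked:
            raise ValueError(f"{table_name} table contains truth columns {leaked}")
    return cohort


def _stage_inputs(observed: ObservedCohort, config: PipelineConfig):
    """Imputation, sodium prediction and the two covariate designs."""
    covariates, flags = impute_single(observed.covariates, config.max_missing)
    sodium = predict_sodium_24h(observed.urine)["sodium_mg"].to_numpy()
    cov_cols = [c for c in covariates.columns if c != "person_id"]
    X_me, me_names = covariate_design(
        covariates, spline_continuous=False, extra={"sodium_pred": sodium},
        columns=cov_cols,
    )
    X_w, w_names = covariate_design(
        covariates, spline_continuous=True, columns=cov_cols
    )
    return covariates, flags, sodium, (X_me, me_names), (X_w, w_names)


def run_pipeline(cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the five analysis stages under a single master seed."""
    if config is None:
        config = PipelineConfig()
    observed = _check_observed(cohort)
    rng = np.random.default_rng(config.seed)
    seeds = {"master": config.seed, "draws": int(rng.integers(2**31 - 1))}

    covariates, flags, sodium, (X_me, me_names), (X_w, w_names) = _stage_inputs(
        observed, config
    )
    person_id = covariates["person_id"].to_numpy()

    lam_grid = config.lambda_grid
    kwargs = {} if lam_grid is None else {"lambda_grid": lam_grid}
    me_fit = fit_measurement_error_model(
        observed.recalls, X_me, person_id, design_names=me_names, **kwargs
    )
    draws = draw_usual_intakes(
        me_fit, observed.recalls, M=config.M, seed=seeds["draws"],
        conditional=config.conditional_draws,
    )
    summary = usual_hefi_from_draws(draws, sodium)
    score = summary["usual_hefi"].to_numpy()
    energy = summary["energy"].to_numpy()
    percentile_table = usual_score_percentiles(score, config.percentiles)

    iptw = estimate_iptw(score, X_w, person_id)
    ipcw = estimate_ipcw(observed.outcomes, X_w, person_id)
    wset = combine_weights(iptw, ipcw, config.weight_truncation_percentile)
    w = wset.weight
    balance = balance_report(score, covariates, w).table

    energy_ref = (
        float(np.average(energy, weights=w))
        if config.energy_ref is None
        else float(config.energy_ref)
    )
    cox = fit_weighted_cox(
        observed.outcomes, score, energy, w, min_events=config.min_events
    )
    risk_table = standardized_risk_table(
        cox, percentile_table, energy_ref, config.horizon_months
    )
    curve = hr_curve(cox, score)
    surv = _survival_curves(cox, percentile_table, energy_ref, config.horizon_months)
    radar = _radar_data(summary)
    rr90 = float(
        risk_table.loc[risk_table["percentile"] == 90.0, "rr"].iloc[0]
    ) if (risk_table["percentile"] == 90.0).any() else None
    evalues = {"rr_p90": evalue(rr90) if rr90 is not None else None}

    return PipelineResult(
        risk_table=risk_table,
        percentile_table=percentile_table,
        usual_summary=summary,
        weights=wset.table,
        balance=balance,
        hr_curve=curve,
        survival_curves=surv,
        radar=radar,
        evalues=evalues,
        energy_ref=energy_ref,
        me_fit=me_fit,
        cox_fit=cox,
        imputation_flags=flags,
        config=config,
        seeds=seeds,
    )


def _survival_curves(
    cox: CoxFit, percentile_table: pd.DataFrame, energy_ref: float, horizon: float
) -> pd.DataFrame:
    from .outcomes import _spline_frame

    times = np.linspace(0.0, horizon, 45)
    hefi_df, _ = _spline_frame(
        percentile_table["score"].to_numpy(float), cox.hefi_knots, "hefi"
    )
    energy_df, _ = _spline_frame(
        np.full(len(hefi_df), energy_ref), cox.energy_knots, "energy"
    )
    X = pd.concat([hefi_df, energy_df], axis=1)
    surv = cox.model.predict_survival_function(X, times=times)
    out = surv.T
    out.columns = [f"t_{t:.1f}" for t in out.columns]
    out.insert(0, "percentile", percentile_table["percentile"].to_numpy())
    out.insert(1, "score", percentile_table["score"].to_numpy())
    return out.reset_index(drop=True)


def _radar_data(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean component scores as % of their maxima, by quarter of the usual
    total score (radar-plot export)."""
    maxima = {st.name: st.max_points for st in default_standards()}
    quarters = pd.qcut(summary["usual_hefi"], 4, labels=["Q1", "Q2", "Q3", "Q4"])
    rows = []
    for q, grp in summary.groupby(quarters, observed=True):
        for name, mx in maxima.items():
            rows.append(
                {
                    "quarter": str(q),
                    "component": name,
                    "pct_of_max": float(grp[f"score_{name}"].mean() / mx * 100.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap

def _perturbed_me_fit(me_fit: MeasurementErrorFit, rng: np.random.Generator):
    """Redraw the fixed effects of every model part from its asymptotic
    normal distribution (variance parameters held at their estimates)."""
    new = copy.deepcopy(me_fit)
    for model in new.models.values():
        fit = model.amount
        fit.beta = rng.multivariate_normal(fit.beta, fit.cov_beta)
        if model.prob is not None:
            cov = (model.prob.cov_gamma + model.prob.cov_gamma.T) / 2.0
            model.prob.gamma = rng.multivariate_normal(model.prob.gamma, cov)
    return new


def _replicate_seeds(master_seed: int, B: int) -> np.ndarray:
    rng = np.random.default_rng(master_seed + 1)
    seeds = rng.choice(2**31 - 1, size=B, replace=False)
    return seeds


def bootstrap_ci(cohort, config: PipelineConfig | None = None) -> BootstrapResult:
    """Percentile bootstrap CIs for the counterfactual risk table.

    The point estimates come from the full-data run; each replicate then
    reruns the simulation/weighting/outcome stages under redrawn parameters
    (parametric mode) or on a person-resampled cohort (resample mode).
    Individual replicate failures are skipped; more than 20% failures aborts.
    """
    if config is None:
        config = PipelineConfig()
    observed = _check_observed(cohort)
    full = run_pipeline(observed, config)
    seeds = _replicate_seeds(config.seed, config.B)
    rows = []
    n_failed = 0
    for b, rep_seed in enumerate(seeds):
        try:
            if config.bootstrap_mode == "parametric":
                tbl = _parametric_replicate(observed, config, full, int(rep_seed))
            else:
                tbl = _resample_replicate(observed, config, full, int(rep_seed))
            tbl = tbl.assign(replicate=b)
            rows.append(tbl)
        except Exception:
            n_failed += 1
    if n_failed > 0.2 * config.B:
        raise RuntimeError(
            f"bootstrap failure rate {n_failed}/{config.B} exceeds 20%"
        )
    reps = pd.concat(rows, ignore_index=True)
    point = full.risk_table.copy()
    for col in ("risk", "rd", "rr"):
        lo = reps.groupby("percentile")[col].quantile(0.025)
        hi = reps.groupby("percentile")[col].quantile(0.975)
        point[f"{col}_lo"] = point["percentile"].map(lo)
        point[f"{col}_hi"] = point["percentile"].map(hi)
    return BootstrapResult(
        point=point, replicates=reps, n_failed=n_failed, mode=config.bootstrap_mode
    )


def _refit_outcome_stage(
    observed: ObservedCohort,
    config: PipelineConfig,
    full: PipelineResult,
    score: np.ndarray,
    energy: np.ndarray,
    X_w: np.ndarray,
    outcomes: pd.DataFrame,
    person_id: np.ndarray,
    rng: np.random.Generator,
    perturb_weight_models: bool = False,
) -> pd.DataFrame:
    w_rng = rng if perturb_weight_models else None
    iptw = estimate_iptw(score, X_w, person_id, rng=w_rng)
    ipcw = estimate_ipcw(outcomes, X_w, person_id, rng=w_rng)
    w = combine_weights(iptw, ipcw, config.weight_truncation_percentile).weight
    cox = fit_weighted_cox(
        outcomes, score, energy, w, min_events=max(5, config.min_events // 5)
    )
    cols = cox.hefi_cols + cox.energy_cols
    params = cox.model.params_[cols].to_numpy()
    cov = cox.model.variance_matrix_.loc[cols, cols].to_numpy()
    params_star = rng.multivariate_normal(params, (cov + cov.T) / 2.0)
    return risk_table_from_params(
        cox, params_star, full.percentile_table, full.energy_ref, config.horizon_months
    )


def _parametric_replicate(
    observed: ObservedCohort, config: PipelineConfig, full: PipelineResult, seed: int
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    me_b = _perturbed_me_fit(full.me_fit, rng)
    draws = draw_usual_intakes(
        me_b, observed.recalls, M=config.M, seed=int(rng.integers(2**31 - 1)),
        conditional=config.conditional_draws,
    )
    sodium = predict_sodium_24h(observed.urine)["sodium_mg"].to_numpy()
    summary = usual_hefi_from_draws(draws, sodium)
    score = summary["usual_hefi"].to_numpy()
    energy = summary["energy"].to_numpy()
    covariates, _, _, _, (X_w, _) = _stage_inputs(observed, config)
    return _refit_outcome_stage(
        observed, config, full, score, energy, X_w, observed.outcomes,
        covariates["person_id"].to_numpy(), rng, perturb_weight_models=True,
    )


def _resample_replicate(
    observed: ObservedCohort, config: PipelineConfig, full: PipelineResult, seed: int
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n = len(observed.covariates)
    idx = rng.integers(0, n, size=n)
    new_id = np.arange(n)
    cov_b = observed.covariates.iloc[idx].reset_index(drop=True).copy()
    old_id = cov_b["person_id"].to_numpy().copy()
    cov_b["person_id"] = new_id
    urine_b = observed.urine.set_index("person_id").loc[old_id].reset_index()
    urine_b["person_id"] = new_id
    out_b = observed.outcomes.set_index("person_id").loc[old_id].reset_index()
    out_b["person_id"] = new_id
    rec_groups = dict(tuple(observed.recalls.groupby("person_id")))
    rec_list = []
    for nid, oid in zip(new_id, old_id):
        g = rec_groups[oid].copy()
        g["person_id"] = nid
        rec_list.append(g)
    recalls_b = pd.concat(rec_list, ignore_index=True)
    boot = ObservedCohort(recalls_b, urine_b, cov_b, out_b)

    covariates, _, sodium, (X_me, me_names), (X_w, _) = _stage_inputs(boot, config)
    kwargs = {} if config.lambda_grid is None else {"lambda_grid": config.lambda_grid}
    me_fit = fit_measurement_error_model(
        recalls_b, X_me, covariates["person_id"].to_numpy(), design_names=me_names,
        **kwargs,
    )
    draws = draw_usual_intakes(
        me_fit, recalls_b, M=config.M, seed=int(rng.integers(2**31 - 1)),
        conditional=config.conditional_draws,
    )
    summary = usual_hefi_from_draws(draws, sodium)
    return _refit_outcome_stage(
        boot, config, full, summary["usual_hefi"].to_numpy(),
        summary["energy"].to_numpy(), X_w, out_b,
        covariates["person_id"].to_numpy(), rng,
    )


def sex_stratified_risks(
    cohort,
    result: PipelineResult,
    config: PipelineConfig | None = None,
    period_months: float = 3.0,
) -> dict:
    """Discrete-time (pooled logistic) risk tables by sex, with Wald tests
    that male and female risk ratios at each percentile agree.

    Uses the usual scores from the full run; weights are re-estimated within
    each stratum (sex itself drops out of the stratum design); percentile
    values are the population (not sex-specific) ones.
    """
    from .outcomes import compare_stratum_rr, pooled_logistic_risks

    if config is None:
        config = result.config
    observed = _check_observed(cohort)
    covariates, _, _, _, _ = _stage_inputs(observed, config)
    score = result.usual_summary["usual_hefi"].to_numpy()
    energy = result.usual_summary["energy"].to_numpy()
    female = covariates["female"].to_numpy(bool)
    rng = np.random.default_rng(config.seed + 17)
    tables = {}
    for label, mask in (("female", female), ("male", ~female)):
        cov_s = covariates.loc[mask].reset_index(drop=True)
        cols = [
            c for c in cov_s.columns
            if c != "person_id" and cov_s[c].nunique() > 1
        ]
        X_s, _ = covariate_design(cov_s, spline_continuous=True, columns=cols)
        out_s = observed.outcomes.loc[mask].reset_index(drop=True)
        iptw = estimate_iptw(score[mask], X_s)
        ipcw = estimate_ipcw(out_s, X_s)
        w = combine_weights(iptw, ipcw, config.weight_truncation_percentile).weight
        tables[label] = pooled_logistic_risks(
            out_s, score[mask], energy[mask], w,
            percentile_table=result.percentile_table,
            period_months=period_months, horizon=config.horizon_months,
            energy_ref=result.energy_ref, rng=rng,
        )
    tables["interaction"] = compare_stratum_rr(tables["male"], tables["female"])
    return tables


# ---------------------------------------------------------------------------

def report(
    result: PipelineResult,
    outdir,
    bootstrap: BootstrapResult | None = None,
    stratified: dict | None = None,
) -> Path:
    """Write the artifact bundle (CSV tables + JSON manifest); returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    risk = bootstrap.point if bootstrap is not None else result.risk_table
    risk.to_csv(outdir / "risk_table.csv", index=False)
    if stratified is not None:
        for label, table in stratified.items():
            table.to_csv(outdir / f"risk_table_{label}.csv", index=False)
    result.me_fit.to_json(outdir / "measurement_model.json")
    result.percentile_table.to_csv(outdir / "score_percentiles.csv", index=False)
    result.hr_curve.to_csv(outdir / "hr_curve.csv", index=False)
    result.survival_curves.to_csv(outdir / "survival_curves.csv", index=False)
    result.balance.to_csv(outdir / "balance.csv", index=False)
    result.radar.to_csv(outdir / "radar_components.csv", index=False)
    result.weights.to_csv(outdir / "weights.csv", index=False)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(result.config).items()
        },
        "seeds": result.seeds,
        "energy_ref": result.energy_ref,
        "n": int(result.cox_fit.n),
        "events": int(result.cox_fit.n_events),
        "evalues": result.evalues,
        "bootstrap": None
        if bootstrap is None
        else {"mode": bootstrap.mode, "n_failed": bootstrap.n_failed},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return outdir
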