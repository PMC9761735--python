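"""Weighted outcome models and counterfactual risk contrasts.

The marginal structural model is a Cox proportional-hazards regression of
CVD on restricted-cubic-spline terms for the usual HEFI-2019 score and for
energy intake, with each person carrying their combined stabilized inverse
probability weight (confounders enter only through the weights). From the
fitted model, counterfactual "everyone at score s" survival curves are read
off at a fixed reference energy, and 11-y risks at prespecified score
percentiles are contrasted against the median (no-change) scenario as
absolute and relative differences.

Sensitivity machinery: an HR curve across the score distribution, a
discrete-time (pooled logistic) analogue with a score-by-time interaction
for sex-stratified risks, re-fits over nested follow-up windows plus a
Schoenfeld-type test for proportional hazards, and the E-value for
unmeasured confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.stats import norm

from .splines import knots_from_percentiles, rcs_basis

__all__ = [
    "CoxFit",
    "fit_weighted_cox",
    "standardized_risk_table",
    "hr_curve",
    "pooled_logistic_risks",
    "compare_stratum_rr",
    "evalue",
    "ph_check",
]

DEFAULT_HORIZON_MONTHS = 132.0
DEFAULT_PERCENTILES = (5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0)


@dataclass
class CoxFit:
    """Weighted Cox fit with the spline bases used to build it."""

    model: CoxPHFitter
    hefi_knots: np.ndarray
    energy_knots: np.ndarray
    hefi_cols: list[str]
    energy_cols: list[str]
    train_df: pd.DataFrame
    n: int
    n_events: int
    weight_summary: dict

    @property
    def hefi_coefs(self) -> np.ndarray:
        return self.model.params_[self.hefi_cols].to_numpy()


def _spline_frame(values, knots, prefix: str) -> tuple[pd.DataFrame, list[str]]:
    basis = rcs_basis(values, knots)
    cols = [f"{prefix}_rcs{j}" for j in range(basis.shape[1])]
    return pd.DataFrame(basis, columns=cols), cols


def fit_weighted_cox(
    outcomes: pd.DataFrame,
    score,
    energy,
    weights=None,
    hefi_knots=None,
    energy_knots=None,
    min_events: int = 50,
    robust: bool = True,
) -> CoxFit:
    """Fit the IP-weighted Cox model with RCS terms for score and energy.

    ``outcomes`` needs ``time_months`` and ``event`` (event of interest:
    ``"cvd"``); anything else counts as censored at its time. Knots default
    to percentiles 5/35/65/95 of the observed score and energy. The fit
    uses robust (sandwich) standard errors, appropriate under non-integer
    weights.
    """
    score = np.asarray(score, dtype=float)
    energy = np.asarray(energy, dtype=float)
    event = (outcomes["event"].to_numpy() == "cvd").astype(int)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events: cannot fit the outcome model")
    if n_events < min_events:
        raise ValueError(f"only {n_events} events (< configured floor {min_events})")
    if hefi_knots is None:
        hefi_knots = knots_from_percentiles(score)
    if energy_knots is None:
        energy_knots = knots_from_percentiles(energy)
    hefi_df, hefi_cols = _spline_frame(score, hefi_knots, "hefi")
    energy_df, energy_cols = _spline_frame(energy, energy_knots, "energy")
    w = np.ones(len(score)) if weights is None else np.asarray(weights, dtype=float)
    df = pd.concat([hefi_df, energy_df], axis=1)
    df["time"] = outcomes["time_months"].to_numpy(float)
    df["event"] = event
    df["w"] = w
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df, duration_col="time", event_col="event", weights_col="w",
            robust=robust, fit_options={"precision": 1e-9},
        )
    return CoxFit(
        model=cph,
        hefi_knots=np.asarray(hefi_knots, float),
        energy_knots=np.asarray(energy_knots, float),
        hefi_cols=hefi_cols,
        energy_cols=energy_cols,
        train_df=df,
        n=len(df),
        n_events=n_events,
        weight_summary={"mean": float(w.mean()), "max": float(w.max()), "min": float(w.min())},
    )


def _risk_at_scores(fit: CoxFit, scores: np.ndarray, energy_ref: float, horizon: float) -> np.ndarray:
    """1 - S(horizon | score, energy_ref) from the fitted model."""
    max_t = float(fit.train_df.loc[fit.train_df["event"] == 1, "time"].max())
    if horizon > max_t:
        warnings.warn(
            f"horizon {horizon} beyond last event time {max_t}; using last event time"
        )
        horizon = max_t
    hefi_df, _ = _spline_frame(np.asarray(scores, float), fit.hefi_knots, "hefi")
    energy_df, _ = _spline_frame(
        np.full(len(hefi_df), float(energy_ref)), fit.energy_knots, "energy"
    )
    X = pd.concat([hefi_df, energy_df], axis=1)
    surv = fit.model.predict_survival_function(X, times=[horizon])
    return 1.0 - surv.iloc[0].to_numpy()


def standardized_risk_table(
    fit: CoxFit,
    percentile_table: pd.DataFrame,
    energy_ref: float,
    horizon: float = DEFAULT_HORIZON_MONTHS,
    reference_percentile: float = 50.0,
) -> pd.DataFrame:
    """Counterfactual risks and contrasts at prespecified score percentiles.

    ``percentile_table`` has columns ``percentile`` and ``score`` (step-1
    output). Everyone is assigned each percentile's score in turn with
    energy held at ``energy_ref``; the row at the reference percentile (the
    median — "no change") has absolute risk difference exactly 0 and
    relative risk exactly 1 by construction. ``rd`` is in percentage points.
    """
    pct = percentile_table["percentile"].to_numpy(float)
    scores = percentile_table["score"].to_numpy(float)
    if reference_percentile not in pct:
        raise ValueError("reference percentile missing from percentile table")
    risks = _risk_at_scores(fit, scores, energy_ref, horizon)
    ref_score = float(scores[pct == reference_percentile][0])
    ref_risk = float(risks[pct == reference_percentile][0])
    table = pd.DataFrame(
        {
            "percentile": pct,
            "score": scores,
            "change": scores - ref_score,
            "risk": risks,
            "rd": (risks - ref_risk) * 100.0,
            "rr": risks / ref_risk,
        }
    )
    is_ref = table["percentile"] == reference_percentile
    table.loc[is_ref, "rd"] = 0.0
    table.loc[is_ref, "rr"] = 1.0
    return table.sort_values("percentile", ascending=False).reset_index(drop=True)


def hr_curve(
    fit: CoxFit,
    score_values,
    reference: float | None = None,
    grid_size: int = 100,
    bounds_percentiles: tuple[float, float] = (1.0, 99.0),
) -> pd.DataFrame:
    """Hazard ratio across the score distribution relative to the median.

    The grid spans percentiles 1-99 of the supplied scores (no extrapolation
    beyond observed values); HR(reference) = 1 exactly.
    """
    score_values = np.asarray(score_values, dtype=float)
    lo, hi = np.percentile(score_values, bounds_percentiles)
    grid = np.linspace(lo, hi, grid_size)
    if reference is None:
        reference = float(np.median(score_values))
    basis_grid = rcs_basis(grid, fit.hefi_knots)
    basis_ref = rcs_basis(np.array([reference]), fit.hefi_knots)
    lp = (basis_grid - basis_ref) @ fit.hefi_coefs
    return pd.DataFrame({"score": grid, "hr": np.exp(lp)})


def breslow_cumulative_hazard(fit: CoxFit, params: np.ndarray, t: float) -> float:
    """Weighted Breslow baseline cumulative hazard at time ``t`` for an
    arbitrary coefficient vector (uncentered covariates).

    Used by the parametric bootstrap to re-evaluate counterfactual risks
    under coefficient vectors drawn from the fit's asymptotic distribution;
    at the fitted coefficients it reproduces the lifelines-based risks.
    """
    df = fit.train_df
    cols = fit.hefi_cols + fit.energy_cols
    lp = df[cols].to_numpy() @ params
    w = df["w"].to_numpy()
    times = df["time"].to_numpy()
    events = df["event"].to_numpy().astype(bool)
    risk = w * np.exp(lp)
    order = np.argsort(times)
    times_s, risk_s = times[order], risk[order]
    # denominator: total weighted risk among those still at risk at each event time
    cum_from_end = np.concatenate([np.cumsum(risk_s[::-1])[::-1], [0.0]])
    ev_times = np.unique(times[events & (times <= t)])
    h0 = 0.0
    for et in ev_times:
        d = float(w[events & (times == et)].sum())
        at_risk = cum_from_end[np.searchsorted(times_s, et, side="left")]
        h0 += d / at_risk
    return float(h0)


def risk_table_from_params(
    fit: CoxFit,
    params: np.ndarray,
    percentile_table: pd.DataFrame,
    energy_ref: float,
    horizon: float = DEFAULT_HORIZON_MONTHS,
    reference_percentile: float = 50.0,
) -> pd.DataFrame:
    """Standardized risk table under an arbitrary coefficient vector.

    Same construction as :func:`standardized_risk_table` but with the
    baseline hazard and linear predictors recomputed from ``params``
    (ordered as hefi columns then energy columns).
    """
    max_t = float(fit.train_df.loc[fit.train_df["event"] == 1, "time"].max())
    horizon = min(horizon, max_t)
    h0 = breslow_cumulative_hazard(fit, params, horizon)
    pct = percentile_table["percentile"].to_numpy(float)
    scores = percentile_table["score"].to_numpy(float)
    hb = rcs_basis(scores, fit.hefi_knots)
    eb = rcs_basis(np.full(len(scores), float(energy_ref)), fit.energy_knots)
    lp = np.column_stack([hb, eb]) @ params
    risks = 1.0 - np.exp(-h0 * np.exp(lp))
    ref_mask = pct == reference_percentile
    ref_risk = float(risks[ref_mask][0])
    ref_score = float(scores[ref_mask][0])
    table = pd.DataFrame(
        {
            "percentile": pct,
            "score": scores,
            "change": scores - ref_score,
            "risk": risks,
            "rd": (risks - ref_risk) * 100.0,
            "rr": risks / ref_risk,
        }
    )
    table.loc[ref_mask, ["rd", "rr"]] = [0.0, 1.0]
    return table.sort_values("percentile", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# pooled logistic (discrete-time) analogue

def _person_period(
    outcomes: pd.DataFrame, period_months: float, horizon: float
) -> pd.DataFrame:
    time = np.minimum(outcomes["time_months"].to_numpy(float), horizon)
    event = (outcomes["event"].to_numpy() == "cvd") & (
        outcomes["time_months"].to_numpy(float) <= horizon
    )
    n_periods = np.maximum(np.ceil(time / period_months).astype(int), 1)
    idx = np.repeat(np.arange(len(time)), n_periods)
    period = np.concatenate([np.arange(1, k + 1) for k in n_periods])
    last = np.concatenate([np.arange(1, k + 1) == k for k in n_periods])
    return pd.DataFrame(
        {
            "row": idx,
            "t": period * period_months,
            "event": (last & event[idx]).astype(float),
        }
    )


def pooled_logistic_risks(
    outcomes: pd.DataFrame,
    score,
    energy,
    weights=None,
    percentile_table: pd.DataFrame | None = None,
    period_months: float = 1.0,
    horizon: float = DEFAULT_HORIZON_MONTHS,
    time_knot_percentiles: Sequence[float] = (5.0, 27.5, 50.0, 72.5, 95.0),
    hefi_knots=None,
    energy_ref: float | None = None,
    reference_percentile: float = 50.0,
    rng: np.random.Generator | None = None,
    n_sim_se: int = 200,
):
    """Discrete-time (pooled logistic) risks at prespecified percentiles.

    Person-time is split into periods of ``period_months``; the per-period
    CVD hazard is modeled with an RCS in time (5 knots), an RCS in the usual
    HEFI score, a score-by-time interaction and energy intake, with each
    person-period carrying the person's IP weight. Risks at the horizon are
    products of conditional survival probabilities; contrasts are taken
    against the reference (median) percentile. In the rare-event, fine-grid
    limit this reproduces the Cox-based risks.

    Returns ``(risk_table, se_log_rr)`` where the standard errors of log RR
    come from simulating the fitted coefficients' asymptotic normal
    distribution (used for between-stratum Wald tests).
    """
    score = np.asarray(score, dtype=float)
    energy = np.asarray(energy, dtype=float)
    w = np.ones(len(score)) if weights is None else np.asarray(weights, dtype=float)
    if percentile_table is None:
        values = np.percentile(score, list(DEFAULT_PERCENTILES))
        percentile_table = pd.DataFrame(
            {"percentile": list(DEFAULT_PERCENTILES), "score": values}
        )
    if hefi_knots is None:
        hefi_knots = knots_from_percentiles(score)
    if energy_ref is None:
        energy_ref = float(np.average(energy, weights=w))

    pp = _person_period(outcomes, period_months, horizon)
    time_knots = knots_from_percentiles(pp["t"].to_numpy(), time_knot_percentiles)
    rows = pp["row"].to_numpy()
    s_center, e_center = float(score.mean()), float(energy.mean())
    e_scale = float(energy.std()) or 1.0

    def build_X(t_vals, score_vals, energy_vals):
        tb = rcs_basis(t_vals / 12.0, time_knots / 12.0)
        hb = rcs_basis(score_vals, hefi_knots)
        # centered/scaled score-by-time interaction keeps the GLM well conditioned
        inter = (((score_vals - s_center) / 10.0) * (t_vals / 12.0))[:, None]
        energy_std = ((np.asarray(energy_vals) - e_center) / e_scale)[:, None]
        return np.column_stack([np.ones(len(t_vals)), tb, hb, inter, energy_std])

    X = build_X(pp["t"].to_numpy(), score[rows], energy[rows])
    y = pp["event"].to_numpy()
    glm = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w[rows]).fit()

    periods = np.arange(1, int(np.ceil(horizon / period_months)) + 1) * period_months

    def risks_for(params):
        out = np.empty(len(percentile_table))
        for i, s in enumerate(percentile_table["score"].to_numpy(float)):
            Xg = build_X(
                periods, np.full(len(periods), s), np.full(len(periods), energy_ref)
            )
            h = 1.0 / (1.0 + np.exp(-(Xg @ params)))
            out[i] = 1.0 - np.prod(1.0 - h)
        return out

    risks = risks_for(glm.params)
    pct = percentile_table["percentile"].to_numpy(float)
    ref_mask = pct == reference_percentile
    if not ref_mask.any():
        raise ValueError("reference percentile missing from percentile table")
    ref_risk = float(risks[ref_mask][0])
    ref_score = float(percentile_table["score"].to_numpy(float)[ref_mask][0])
    table = pd.DataFrame(
        {
            "percentile": pct,
            "score": percentile_table["score"].to_numpy(float),
            "change": percentile_table["score"].to_numpy(float) - ref_score,
            "risk": risks,
            "rd": (risks - ref_risk) * 100.0,
            "rr": risks / ref_risk,
        }
    )
    table.loc[ref_mask, ["rd", "rr"]] = [0.0, 1.0]

    if rng is None:
        rng = np.random.default_rng(0)
    draws = rng.multivariate_normal(glm.params, glm.cov_params(), size=n_sim_se)
    log_rr = np.empty((n_sim_se, len(percentile_table)))
    for b in range(n_sim_se):
        r = risks_for(draws[b])
        log_rr[b] = np.log(np.clip(r / r[ref_mask][0], 1e-12, None))
    se_log_rr = log_rr.std(axis=0, ddof=1)
    table["se_log_rr"] = se_log_rr
    return table.sort_values("percentile", ascending=False).reset_index(drop=True)


def compare_stratum_rr(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Wald tests that the RR at each percentile is equal in two strata.

    Uses the simulated ``se_log_rr`` columns; the reference rows (RR = 1 in
    both strata) get no test.
    """
    merged = table_a.merge(table_b, on="percentile", suffixes=("_a", "_b"))
    diff = np.log(merged["rr_a"]) - np.log(merged["rr_b"])
    se = np.sqrt(merged["se_log_rr_a"] ** 2 + merged["se_log_rr_b"] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(np.abs(diff) < 1e-15, 0.0, diff / np.where(se > 0, se, np.nan))
    p = 2.0 * (1.0 - norm.cdf(np.abs(z)))
    out = merged[["percentile"]].copy()
    out["log_rr_diff"] = diff
    out["p_interaction"] = np.where(
        (merged["rr_a"] == 1.0) & (merged["rr_b"] == 1.0), np.nan, p
    )
    return out


# ---------------------------------------------------------------------------
# E-value and proportional hazards diagnostics

def evalue(rr: float, ci: tuple[float, float] | None = None):
    """E-value for an observed risk ratio (and optionally its 95% CI bound).

    Protective ratios are inverted first; E = RR* + sqrt(RR* (RR* - 1)).
    The CI E-value uses the bound closer to the null and is 1 when the CI
    crosses 1.
    """
    if rr <= 0:
        raise ValueError("rr must be > 0")

    def _e(r: float) -> float:
        r = 1.0 / r if r < 1.0 else r
        if r <= 1.0:
            return 1.0
        return r + np.sqrt(r * (r - 1.0))

    point = _e(rr)
    if ci is None:
        return {"point": point, "ci": None}
    lo, hi = ci
    if lo <= 1.0 <= hi:
        return {"point": point, "ci": 1.0}
    bound = hi if rr < 1.0 else lo
    return {"point": point, "ci": _e(bound)}


def ph_check(
    outcomes: pd.DataFrame,
    score,
    energy,
    weights=None,
    windows: Sequence[float] = (36.0, 60.0, 96.0, 132.0),
    contrast: tuple[float, float] | None = None,
    min_events: int = 10,
) -> dict:
    """Proportional-hazards diagnostics.

    Re-fits the weighted Cox model on nested follow-up windows and reports
    the HR for a fixed score contrast (default: 90th vs 50th percentile) in
    each window; windows with too few events are skipped with a note. Also
    runs a Schoenfeld-residual slope test on the full-window fit.
    """
    score = np.asarray(score, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if contrast is None:
        contrast = (float(np.percentile(score, 90)), float(np.percentile(score, 50)))
    rows, skipped = [], []
    full_fit = None
    for wdw in sorted(windows):
        out_w = outcomes.copy()
        over = out_w["time_months"].to_numpy(float) > wdw
        out_w.loc[over, "time_months"] = wdw
        out_w.loc[over, "event"] = "censor"
        n_ev = int((out_w["event"] == "cvd").sum())
        if n_ev < min_events:
            skipped.append({"window_months": wdw, "events": n_ev})
            continue
        fit = fit_weighted_cox(out_w, score, energy, weights, min_events=min_events)
        if wdw == max(windows):
            full_fit = fit
        b_hi = rcs_basis(np.array([contrast[0]]), fit.hefi_knots)
        b_lo = rcs_basis(np.array([contrast[1]]), fit.hefi_knots)
        diff = (b_hi - b_lo)[0]
        hr = float(np.exp(diff @ fit.hefi_coefs))
        cov_h = fit.model.variance_matrix_.loc[fit.hefi_cols, fit.hefi_cols].to_numpy()
        se = float(np.sqrt(diff @ cov_h @ diff))
        rows.append(
            {
                "window_months": wdw,
                "events": n_ev,
                "hr": hr,
                "hr_lo": float(hr * np.exp(-1.96 * se)),
                "hr_hi": float(hr * np.exp(1.96 * se)),
            }
        )
    slope_p = None
    if full_fit is not None:
        try:
            from lifelines.statistics import proportional_hazard_test

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = proportional_hazard_test(
                    full_fit.model, full_fit.train_df, time_transform="rank"
                )
            slope_p = float(res.summary["p"].min())
        except Exception:  # diagnostic only; never fail the analysis
            slope_p = None
    return {
        "windows": pd.DataFrame(rows),
        "skipped": skipped,
        "schoenfeld_min_p": slope_p,
        "contrast": contrast,
    }
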