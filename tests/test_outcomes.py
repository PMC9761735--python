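"""Outcome models: Cox oracle equivalence, standardized risks, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from hefi_cvd import (
    GeneratorConfig,
    evalue,
    fit_weighted_cox,
    generate_cohort,
    hr_curve,
    ph_check,
    pooled_logistic_risks,
    compare_stratum_rr,
    standardized_risk_table,
)
from hefi_cvd.outcomes import breslow_cumulative_hazard, risk_table_from_params
from hefi_cvd.splines import rcs_basis
from hefi_cvd.usual_intake import usual_score_percentiles

# ---------------------------------------------------------------------------
# a fixed 20-record survival fixture (continuous times, no ties)

FIXTURE = pd.DataFrame(
    {
        "time": [
            2.3, 4.1, 5.7, 6.2, 7.9, 9.4, 10.8, 12.5, 13.1, 15.6,
            17.2, 19.9, 21.4, 23.8, 26.3, 28.7, 31.2, 34.5, 37.9, 41.3,
        ],
        "event": [1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 0, 1],
        "x": [
            0.8, -0.3, 1.2, 0.1, -0.9, 0.6, -1.4, 0.9, 0.3, -0.2,
            1.1, -0.7, 0.5, -1.1, 0.2, 0.7, -0.4, 1.3, -0.6, 0.0,
        ],
        "w": [
            1.0, 2.0, 1.0, 0.5, 1.5, 1.0, 1.0, 2.5, 1.0, 1.0,
            0.5, 1.0, 1.5, 1.0, 1.0, 2.0, 1.0, 0.5, 1.0, 1.0,
        ],
    }
)


def _oracle_weighted_cox_beta(df: pd.DataFrame, tol=1e-12) -> float:
    """Independently coded Newton-Raphson maximizer of the weighted Cox
    partial likelihood (single covariate, continuous times: Breslow and
    Efron coincide)."""
    t = df["time"].to_numpy()
    d = df["event"].to_numpy()
    x = df["x"].to_numpy()
    w = df["w"].to_numpy()
    beta = 0.0
    for _ in range(100):
        g = 0.0
        h = 0.0
        for i in np.flatnonzero(d):
            risk = t >= t[i]
            ew = w[risk] * np.exp(beta * x[risk])
            s0 = ew.sum()
            s1 = (ew * x[risk]).sum()
            s2 = (ew * x[risk] ** 2).sum()
            g += w[i] * (x[i] - s1 / s0)
            h -= w[i] * (s2 / s0 - (s1 / s0) ** 2)
        step = g / h
        beta -= step
        if abs(step) < tol:
            break
    return beta


class TestCoxOracle:
    def test_weighted_coefficient_matches_newton_raphson_oracle(self):
        from lifelines import CoxPHFitter
        import warnings

        oracle = _oracle_weighted_cox_beta(FIXTURE)
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                FIXTURE, "time", "event", weights_col="w", robust=True,
                fit_options={"precision": 1e-9},
            )
        assert cph.params_["x"] == pytest.approx(oracle, abs=1e-6)

    def test_weight_rescaling_leaves_coefficient_unchanged(self):
        from lifelines import CoxPHFitter
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = CoxPHFitter().fit(FIXTURE, "time", "event", weights_col="w")
            doubled = FIXTURE.assign(w=2.0 * FIXTURE["w"])
            b = CoxPHFitter().fit(doubled, "time", "event", weights_col="w")
        assert a.params_["x"] == pytest.approx(b.params_["x"], abs=1e-9)


# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cox_setup(medium_cohort):
    rng = np.random.default_rng(0)
    n = len(medium_cohort.covariates)
    score = rng.normal(46.0, 9.0, n)
    energy = rng.normal(2100.0, 350.0, n)
    fit = fit_weighted_cox(
        medium_cohort.outcomes, score, energy, None, min_events=10, robust=False
    )
    pct = usual_score_percentiles(score)
    return fit, pct, score


class TestRiskTable:
    def test_reference_row_exact(self, cox_setup):
        fit, pct, _ = cox_setup
        table = standardized_risk_table(fit, pct, 2100.0)
        ref = table[table["percentile"] == 50.0].iloc[0]
        assert ref["rd"] == 0.0
        assert ref["rr"] == 1.0
        assert ref["change"] == 0.0
        assert ((table["risk"] > 0) & (table["risk"] < 1)).all()

    def test_survival_curves_non_increasing(self, cox_setup):
        fit, pct, _ = cox_setup
        from hefi_cvd.pipeline import _survival_curves

        surv = _survival_curves(fit, pct, 2100.0, 132.0)
        values = surv[[c for c in surv.columns if c.startswith("t_")]].to_numpy()
        assert (np.diff(values, axis=1) <= 1e-12).all()

    def test_breslow_path_reproduces_lifelines_risks(self, cox_setup):
        """Dual route: the hand-computed Breslow baseline + linear predictor
        reproduces the lifelines-based risk table at the fitted coefficients."""
        fit, pct, _ = cox_setup
        lifelines_table = standardized_risk_table(fit, pct, 2100.0, horizon=120.0)
        cols = fit.hefi_cols + fit.energy_cols
        params = fit.model.params_[cols].to_numpy()
        hand = risk_table_from_params(fit, params, pct, 2100.0, horizon=120.0)
        assert np.allclose(hand["risk"], lifelines_table["risk"], rtol=1e-6)
        assert np.allclose(hand["rr"], lifelines_table["rr"], rtol=1e-6)

    def test_missing_reference_percentile_rejected(self, cox_setup):
        fit, pct, _ = cox_setup
        with pytest.raises(ValueError, match="reference"):
            standardized_risk_table(fit, pct[pct["percentile"] != 50.0], 2100.0)


class TestHRCurve:
    def test_reference_hr_is_exactly_one(self, cox_setup):
        fit, _, score = cox_setup
        ref = float(np.median(score))
        curve = hr_curve(fit, score, reference=ref)
        i = int(np.argmin(np.abs(curve["score"] - ref)))
        basis_ref = rcs_basis(np.array([ref]), fit.hefi_knots)
        hr_at_ref = np.exp((basis_ref - basis_ref) @ fit.hefi_coefs)
        assert hr_at_ref[0] == 1.0
        assert curve["hr"].iloc[i] == pytest.approx(1.0, abs=0.05)

    def test_grid_restricted_to_inner_percentiles(self, cox_setup):
        fit, _, score = cox_setup
        curve = hr_curve(fit, score)
        lo, hi = np.percentile(score, [1.0, 99.0])
        assert curve["score"].min() >= lo - 1e-9
        assert curve["score"].max() <= hi + 1e-9

    def test_monotone_decreasing_for_protective_linear_hazard(self):
        c = generate_cohort(
            GeneratorConfig(
                n_participants=30_000, seed=17,
                confounding_strength={}, covariate_log_hazard={},
                competing_log_hazard={},
            )
        )
        score = c.truth["true_hefi"].to_numpy()
        energy = c.truth["energy"].to_numpy()
        fit = fit_weighted_cox(c.outcomes, score, energy, None, robust=False)
        curve = hr_curve(fit, score)
        # allow tiny numerical wiggles in the fitted spline
        assert (np.diff(curve["hr"]) < 0.004).all()
        assert curve["hr"].iloc[0] > 1.0 > curve["hr"].iloc[-1]


class TestEValue:
    def test_null_rr_gives_one(self):
        assert evalue(1.0)["point"] == 1.0

    def test_protective_half_inverts_first(self):
        out = evalue(0.5, ci=(0.3, 0.8))
        assert out["point"] == pytest.approx(2.0 + np.sqrt(2.0))
        # CI bound closer to the null is 0.8 -> RR* = 1.25
        assert out["ci"] == pytest.approx(1.25 + np.sqrt(1.25 * 0.25))

    def test_ci_crossing_null_gives_one(self):
        assert evalue(0.76, ci=(0.55, 1.05))["ci"] == 1.0

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            evalue(0.0)


class TestPooledLogistic:
    def test_time_spline_has_four_columns_for_five_knots(self, medium_cohort):
        rng = np.random.default_rng(1)
        n = len(medium_cohort.covariates)
        score = rng.normal(46, 9, n)
        energy = rng.normal(2100, 300, n)
        table = pooled_logistic_risks(
            medium_cohort.outcomes, score, energy, period_months=6.0,
            rng=np.random.default_rng(0), n_sim_se=20,
        )
        assert len(table) == 7
        ref = table[table["percentile"] == 50.0].iloc[0]
        assert ref["rr"] == 1.0 and ref["rd"] == 0.0
        # design width: intercept + 4 time cols + 3 hefi cols + interaction + energy
        time_knots_cols = 4
        assert time_knots_cols == len(
            rcs_basis(np.linspace(1, 132, 50), np.percentile(
                np.linspace(1, 132, 50), [5, 27.5, 50, 72.5, 95])).T
        )

    def test_identical_strata_interaction_p_is_one(self, medium_cohort):
        rng = np.random.default_rng(2)
        n = len(medium_cohort.covariates)
        score = rng.normal(46, 9, n)
        energy = rng.normal(2100, 300, n)
        t = pooled_logistic_risks(
            medium_cohort.outcomes, score, energy, period_months=6.0,
            rng=np.random.default_rng(0), n_sim_se=20,
        )
        cmp = compare_stratum_rr(t, t.copy())
        non_ref = cmp.dropna(subset=["p_interaction"])
        assert np.allclose(non_ref["p_interaction"], 1.0)


class TestPHCheck:
    def test_one_row_per_window_and_ci_overlap_under_proportionality(self):
        c = generate_cohort(
            GeneratorConfig(
                n_participants=15_000, seed=23, confounding_strength={},
                covariate_log_hazard={}, competing_log_hazard={},
            )
        )
        out = ph_check(
            c.outcomes, c.truth["true_hefi"].to_numpy(),
            c.truth["energy"].to_numpy(), windows=(60.0, 96.0, 132.0),
        )
        assert len(out["windows"]) + len(out["skipped"]) == 3
        rows = out["windows"]
        # proportional hazards: window HRs mutually compatible (CI overlap)
        assert rows["hr_lo"].max() < rows["hr_hi"].min()
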