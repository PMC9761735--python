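"""Measurement-error model: parameter recovery, conditional draws, percentiles."""

import numpy as np
import pandas as pd
import pytest

from hefi_cvd import (
    GeneratorConfig,
    generate_cohort,
    usual_score_percentiles,
)
from hefi_cvd.synthetic import ComponentSpec
from hefi_cvd.usual_intake import (
    draw_usual_intakes,
    fit_measurement_error_model,
    fit_probit_random_intercept,
    fit_random_intercept_lmm,
)


def _sim_lmm(n=1500, sd_b=1.0, sd_w=1.5, beta=(2.0, 0.7), seed=0, p_two=0.62):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    Xp = np.column_stack([np.ones(n), x])
    counts = np.where(rng.random(n) < p_two, rng.integers(2, 5, n), 1)
    person = np.repeat(np.arange(n), counts)
    u = rng.normal(0, sd_b, n)
    mu = Xp @ np.asarray(beta) + u
    y = mu[person] + rng.normal(0, sd_w, len(person))
    return y, person, Xp


class TestRandomInterceptLMM:
    def test_matches_statsmodels_mixedlm_oracle(self):
        """Dual route: the profiled exact-ML fitter agrees with statsmodels'
        general mixed-model machinery on the same data."""
        import statsmodels.api as sm

        y, person, Xp = _sim_lmm(n=400, seed=3)
        fit = fit_random_intercept_lmm(y, person, Xp)
        md = sm.MixedLM(y, Xp[person], groups=person).fit(reml=False)
        assert np.allclose(fit.beta, md.fe_params, atol=1e-4)
        assert fit.sigma_e == pytest.approx(np.sqrt(md.scale), abs=1e-3)
        assert fit.sigma_u == pytest.approx(
            np.sqrt(float(np.asarray(md.cov_re)[0, 0])), abs=1e-3
        )
        assert fit.loglik == pytest.approx(md.llf, abs=1e-4)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_between_and_within_sds_within_10pct(self, seed):
        y, person, Xp = _sim_lmm(n=2000, sd_b=1.0, sd_w=1.5, seed=seed)
        fit = fit_random_intercept_lmm(y, person, Xp)
        assert fit.sigma_u == pytest.approx(1.0, rel=0.10)
        assert fit.sigma_e == pytest.approx(1.5, rel=0.10)

    def test_zero_within_noise_degenerates_to_person_mean(self):
        y, person, Xp = _sim_lmm(n=500, sd_w=1e-6, seed=1)
        fit = fit_random_intercept_lmm(y, person, Xp)
        assert fit.sigma_e < 0.01
        assert fit.sigma_u == pytest.approx(1.0, rel=0.15)

    def test_no_repeats_aborts(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 50)
        with pytest.raises(ValueError, match="repeated"):
            fit_random_intercept_lmm(y, np.arange(50), np.ones((50, 1)))


class TestProbitRandomIntercept:
    def test_recovers_half_consumption_probability(self):
        rng = np.random.default_rng(8)
        n = 2000
        counts = rng.integers(1, 6, n)
        person = np.repeat(np.arange(n), counts)
        u = rng.normal(0, 0.8, n)
        from scipy.special import ndtr

        y = (rng.random(len(person)) < ndtr(0.0 + u[person])).astype(float)
        fit = fit_probit_random_intercept(y, person, np.ones((n, 1)))
        assert abs(fit.gamma[0]) < 0.1
        assert fit.sigma_u == pytest.approx(0.8, rel=0.25)


def _recovery_cohort(seed, n=2000):
    """Default cohort with three components overridden to known, covariate-free
    laws (the targets of the recovery assertions)."""
    overrides = {
        # log scale keeps the back-transform strictly positive, so the large
        # generating SDs (1.0 between / 1.5 within) cannot truncate at zero
        "vegetables": ComponentSpec("vegetables", "RA", 2.0, 0.0, 1.0, 1.5, 0.0, 0.0),
        "energy": ComponentSpec("energy", "kcal", 2000.0, 0.0, 0.2, 0.25, 0.0, 0.0),
        "sugary_drinks": ComponentSpec(
            "sugary_drinks", "g", 250.0, 0.0, 0.5, 0.5, 0.0, 0.0,
            episodic=True, prob_base=0.0, prob_load_q=0.0, prob_sd_between=0.8,
        ),
    }
    from hefi_cvd.synthetic import default_components

    comps = [overrides.get(c.name, c) for c in default_components()]
    return generate_cohort(
        GeneratorConfig(n_participants=n, seed=seed, components=comps,
                        confounding_strength={}, q_residual_sd=1.0)
    )


class TestMeasurementErrorModel:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_generator_sds_within_10pct(self, seed):
        """Between/within SDs of a non-episodic component (generated with
        sigma_b = 1.0, sigma_w = 1.5 on the transformed scale) are recovered."""
        c = _recovery_cohort(seed)
        X = np.ones((len(c.covariates), 1))
        fit = fit_measurement_error_model(
            c.recalls, X, c.covariates["person_id"].to_numpy(),
            components=["vegetables"], lambda_grid=(0.0,), episodic=[],
        )
        veg = fit.models["vegetables"].amount
        assert veg.sigma_u == pytest.approx(1.0, rel=0.10)
        assert veg.sigma_e == pytest.approx(1.5, rel=0.10)

    def test_probit_intercept_recovered_for_half_probability(self):
        c = _recovery_cohort(4, n=3000)
        X = np.ones((len(c.covariates), 1))
        fit = fit_measurement_error_model(
            c.recalls, X, c.covariates["person_id"].to_numpy(),
            components=["sugary_drinks"], lambda_grid=(0.0,),
            episodic=["sugary_drinks"],
        )
        prob = fit.models["sugary_drinks"].prob
        assert abs(prob.gamma[0]) < 0.1

    def test_lambda_profile_prefers_generating_transform(self):
        c = _recovery_cohort(5)
        X = np.ones((len(c.covariates), 1))
        fit = fit_measurement_error_model(
            c.recalls, X, c.covariates["person_id"].to_numpy(),
            components=["fruits", "energy"],
            lambda_grid=(0.0, 0.5, 1.0), episodic=[],
        )
        assert fit.models["fruits"].lam == 0.5  # generated on sqrt scale
        assert fit.models["energy"].lam == 0.0  # generated on log scale

    def test_all_zero_component_rejected(self):
        c = _recovery_cohort(6, n=300)
        recalls = c.recalls.copy()
        recalls["vegetables"] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            fit_measurement_error_model(
                recalls, np.ones((300, 1)), c.covariates["person_id"].to_numpy(),
                components=["vegetables"], lambda_grid=(0.5,),
            )


class TestDraws:
    @pytest.fixture(scope="class")
    def fitted(self):
        c = _recovery_cohort(7)
        X = np.ones((len(c.covariates), 1))
        fit = fit_measurement_error_model(
            c.recalls, X, c.covariates["person_id"].to_numpy(),
            components=["energy", "sugary_drinks"], lambda_grid=(0.0, 0.5),
            episodic=["sugary_drinks"],
        )
        return c, fit

    def test_same_seed_identical_draws(self, fitted):
        c, fit = fitted
        d1 = draw_usual_intakes(fit, c.recalls, M=20, seed=42)
        d2 = draw_usual_intakes(fit, c.recalls, M=20, seed=42)
        for name in d1.amounts:
            assert np.array_equal(d1.amounts[name], d2.amounts[name])

    def test_seed_required(self, fitted):
        c, fit = fitted
        with pytest.raises(ValueError, match="seed"):
            draw_usual_intakes(fit, c.recalls, M=10)

    def test_mean_usual_energy_tracks_truth(self, fitted):
        c, fit = fitted
        d = draw_usual_intakes(fit, c.recalls, M=100, seed=1)
        est = d.amounts["energy"].mean(axis=1)
        true = c.truth["energy"].to_numpy()
        r = np.corrcoef(est, true)[0, 1]
        assert r > 0.7
        assert est.mean() == pytest.approx(true.mean(), rel=0.03)

    def test_monte_carlo_se_shrinks_with_M(self, fitted):
        c, fit = fitted
        from hefi_cvd.usual_intake import usual_hefi_from_draws

        # single-component proxy: SD across draws of usual energy per person
        d_small = draw_usual_intakes(fit, c.recalls, M=25, seed=2)
        d_large = draw_usual_intakes(fit, c.recalls, M=200, seed=2)
        se_small = d_small.amounts["energy"].std(axis=1).mean() / np.sqrt(25)
        se_large = d_large.amounts["energy"].std(axis=1).mean() / np.sqrt(200)
        assert se_large < se_small

    def test_json_roundtrip_preserves_draws(self, fitted, tmp_path):
        from hefi_cvd.usual_intake import MeasurementErrorFit

        c, fit = fitted
        fit.to_json(tmp_path / "fit.json")
        back = MeasurementErrorFit.from_json(tmp_path / "fit.json")
        d1 = draw_usual_intakes(fit, c.recalls, M=10, seed=5)
        d2 = draw_usual_intakes(back, c.recalls, M=10, seed=5)
        for name in d1.amounts:
            assert np.allclose(d1.amounts[name], d2.amounts[name])

    def test_conditional_draws_shrink_toward_observed(self, fitted):
        """Persons' conditional usual intakes correlate more strongly with
        their own recall means than marginal (covariate-only) draws do."""
        c, fit = fitted
        rec_mean = c.recalls.groupby("person_id")["energy"].mean().to_numpy()
        cond = draw_usual_intakes(fit, c.recalls, M=50, seed=3, conditional=True)
        marg = draw_usual_intakes(fit, c.recalls, M=50, seed=3, conditional=False)
        r_cond = np.corrcoef(cond.amounts["energy"].mean(axis=1), rec_mean)[0, 1]
        r_marg = abs(np.corrcoef(marg.amounts["energy"].mean(axis=1), rec_mean)[0, 1])
        assert r_cond > 0.8
        assert r_cond > r_marg + 0.3


class TestAttenuation:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_measurement_error_correction_deattenuates(self, seed):
        """Single recalls overstate the spread of usual intake (within-person
        noise adds to between-person variance); the modeled usual intakes
        land closer to the true spread, and the modeled usual score tracks
        the true score better than any single recall does."""
        from hefi_cvd import PipelineConfig, run_pipeline
        from hefi_cvd.derivations import predict_sodium_24h
        from hefi_cvd.scoring import score_hefi
        from hefi_cvd.synthetic import hefi_inputs_from_amounts

        c = generate_cohort(GeneratorConfig(n_participants=1200, seed=seed))
        res = run_pipeline(
            c.observed(),
            PipelineConfig(M=25, seed=seed, lambda_grid=(0.0, 0.5), min_events=5),
        )
        # intake-level attenuation correction, on an unbounded component
        first = c.recalls.groupby("person_id").head(1).reset_index(drop=True)
        var_true = c.truth["energy"].var()
        var_single = first["energy"].var()
        var_usual = res.usual_summary["energy"].var()
        assert var_single > var_true
        assert abs(var_usual - var_true) < abs(var_single - var_true)
        # score-level: corrected scores track the true score more closely
        sodium = predict_sodium_24h(c.urine)["sodium_mg"].to_numpy()
        single_score = score_hefi(hefi_inputs_from_amounts(first, sodium))["total"]
        r_single = np.corrcoef(single_score, c.truth["true_hefi"])[0, 1]
        r_usual = np.corrcoef(
            res.usual_summary["usual_hefi"], c.truth["true_hefi"]
        )[0, 1]
        assert r_usual > r_single


class TestPercentiles:
    def test_constant_scores_all_percentiles_equal(self):
        out = usual_score_percentiles(np.full(200, 41.0))
        assert (out["score"] == 41.0).all()

    def test_default_has_seven_rows(self):
        out = usual_score_percentiles(np.random.default_rng(0).uniform(0, 80, 500))
        assert len(out) == 7
        assert list(out["percentile"]) == [5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0]

    def test_uniform_median_closed_form(self):
        rng = np.random.default_rng(1)
        out = usual_score_percentiles(rng.uniform(0, 80, 100_000))
        med = out.loc[out["percentile"] == 50.0, "score"].iloc[0]
        assert med == pytest.approx(40.0, abs=0.5)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            usual_score_percentiles(np.arange(50))
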