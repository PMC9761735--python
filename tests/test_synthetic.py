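"""Synthetic cohort generator: determinism, configured rates, noise structure."""

import numpy as np
import pandas as pd
import pytest

from hefi_cvd import ComponentSpec, GeneratorConfig, generate_cohort
from hefi_cvd.synthetic import (
    _person_effects,
    _true_usual_amounts,
    generate_recalls,
    simulate_outcomes,
)


class TestConfigValidation:
    def test_bad_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="probabilit"):
            GeneratorConfig(recall_count_distribution=(0.5, 0.5, 0.5, 0.0, 0.0))

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GeneratorConfig(n_participants=0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(baseline_hazard=-0.1)

    def test_component_spec_validation(self):
        with pytest.raises(ValueError):
            ComponentSpec("x", "RA", -1.0, 0.5, 0.3, 0.3)
        with pytest.raises(ValueError):
            ComponentSpec("x", "RA", 1.0, 0.5, 0.0, 0.3)


class TestDeterminism:
    def test_same_config_and_seed_byte_identical(self):
        cfg = GeneratorConfig(n_participants=300, seed=9)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for name in ("recalls", "urine", "covariates", "outcomes", "truth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seed_differs(self):
        a = generate_cohort(GeneratorConfig(n_participants=300, seed=9))
        b = generate_cohort(GeneratorConfig(n_participants=300, seed=10))
        assert not a.recalls.equals(b.recalls)


class TestCohortInvariants:
    def test_every_person_has_recall_with_energy_floor(self, small_cohort):
        gmax = small_cohort.recalls.groupby("person_id")["energy"].max()
        assert len(gmax) == len(small_cohort.covariates)
        assert (gmax >= 100.0).all()

    def test_event_times_in_bounds_and_single_event_type(self, small_cohort):
        out = small_cohort.outcomes
        assert ((out["time_months"] > 0) & (out["time_months"] <= 132.0)).all()
        assert out["person_id"].is_unique
        assert set(out["event"]) <= {"cvd", "death", "loss", "censor"}

    def test_recall_count_distribution_matches_config(self, medium_cohort):
        counts = medium_cohort.recalls.groupby("person_id").size()
        assert counts.mean() == pytest.approx(2.25, abs=0.1)
        assert (counts >= 2).mean() == pytest.approx(0.62, abs=0.03)
        assert counts.between(1, 5).all()

    def test_realized_event_rates_near_targets(self):
        """Configured vs realized 11-y proportions agree within 3 binomial SEs."""
        n = 60_000
        c = generate_cohort(GeneratorConfig(n_participants=n, seed=3))
        for event, target in (("cvd", 0.021), ("death", 0.026), ("loss", 0.003)):
            realized = (c.outcomes["event"] == event).mean()
            se = np.sqrt(target * (1 - target) / n)
            assert abs(realized - target) < 3 * se, (event, realized)


class TestRecallNoise:
    def _effects(self, cfg, n=400, seed=0):
        rng = np.random.default_rng(seed)
        q = rng.normal(0, 1, n)
        v = rng.normal(0, 1, n)
        eff = _person_effects(cfg, q, v, rng)
        return eff, rng

    def test_zero_within_noise_reproduces_usual_intake(self):
        comp = [
            ComponentSpec("vegetables", "RA", 2.0, 0.5, 0.4, 0.0),
            ComponentSpec("energy", "kcal", 2000.0, 0.0, 0.2, 0.0),
        ]
        cfg = GeneratorConfig(n_participants=400, components=comp)
        eff, rng = self._effects(cfg)
        recalls = generate_recalls(eff, cfg, rng)
        truth = _true_usual_amounts(cfg, eff)
        merged = recalls.merge(truth, on="person_id", suffixes=("", "_true"))
        assert np.allclose(merged["vegetables"], merged["vegetables_true"])
        assert np.allclose(
            np.maximum(merged["energy_true"], 100.0), merged["energy"]
        )

    def test_episodic_probability_one_never_zero(self):
        comp = [
            ComponentSpec(
                "sugary_drinks", "g", 250.0, 0.0, 0.4, 0.4, episodic=True,
                prob_base=8.0, prob_load_q=0.0, prob_sd_between=0.01,
            ),
            ComponentSpec("energy", "kcal", 2000.0, 0.0, 0.2, 0.2),
        ]
        cfg = GeneratorConfig(n_participants=500, components=comp)
        eff, rng = self._effects(cfg)
        recalls = generate_recalls(eff, cfg, rng)
        assert (recalls["sugary_drinks"] > 0).all()

    def test_log_component_recall_mean_matches_person_value(self):
        """CLT check: with many recalls, the log-scale sample mean sits within
        3 SEs of the person's latent value."""
        comp = [ComponentSpec("energy", "kcal", 2000.0, 0.0, 0.2, 0.3)]
        cfg = GeneratorConfig(
            n_participants=1, components=comp,
            recall_count_distribution=(0, 0, 0, 0, 1),
        )
        rng = np.random.default_rng(4)
        eff = _person_effects(cfg, np.zeros(1), np.zeros(1), rng)
        reps = [generate_recalls(eff, cfg, rng)["energy"] for _ in range(2000)]
        logs = np.log(np.concatenate(reps))  # 10 000 recalls
        se = 0.3 / np.sqrt(len(logs))
        assert abs(logs.mean() - eff["mu_energy"].iloc[0]) < 3 * se


class TestOutcomes:
    def _cov(self, n, seed=0):
        from hefi_cvd.synthetic import _generate_covariates

        return _generate_covariates(n, np.random.default_rng(seed))

    def test_all_hazards_zero_everyone_admin_censored(self):
        cfg = GeneratorConfig(
            baseline_hazard=0.0, competing_mortality_rate=0.0, loss_rate=0.0,
            covariate_log_hazard={}, competing_log_hazard={},
        )
        cov = self._cov(200)
        out = simulate_outcomes(
            np.full(200, 46.0), cov, cfg, np.random.default_rng(1)
        )
        assert (out["event"] == "censor").all()
        assert (out["time_months"] == 132.0).all()

    def test_exponential_incidence_matches_closed_form(self):
        lam = 0.0002
        cfg = GeneratorConfig(
            baseline_hazard=lam, competing_mortality_rate=0.0, loss_rate=0.0,
            covariate_log_hazard={}, competing_log_hazard={},
            log_hazard_per_10pts=0.0,
        )
        n = 40_000
        cov = self._cov(n)
        out = simulate_outcomes(np.full(n, 46.0), cov, cfg, np.random.default_rng(2))
        expected = 1.0 - np.exp(-lam * 132.0)
        realized = (out["event"] == "cvd").mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(realized - expected) < 3 * se

    def test_doubling_log_hazard_raises_incidence(self):
        n = 20_000
        cov = self._cov(n)
        rng_scores = np.random.default_rng(3)
        scores = rng_scores.normal(46.0, 10.0, n)
        rates = []
        for beta in (0.0, 0.3, 0.6):
            cfg = GeneratorConfig(
                baseline_hazard=0.00015, competing_mortality_rate=0.0,
                loss_rate=0.0, covariate_log_hazard={}, competing_log_hazard={},
                log_hazard_per_10pts=beta,
            )
            out = simulate_outcomes(scores + 10.0, cov, cfg, np.random.default_rng(4))
            # +10 points above centering -> higher beta raises hazard
            rates.append((out["event"] == "cvd").mean())
        assert rates[0] < rates[1] < rates[2]

    def test_null_effect_gives_no_score_event_association(self):
        cfg = GeneratorConfig(
            n_participants=50_000, seed=5, log_hazard_per_10pts=0.0,
            covariate_log_hazard={}, competing_log_hazard={},
        )
        c = generate_cohort(cfg)
        ev = (c.outcomes["event"] == "cvd").astype(float)
        r = np.corrcoef(c.truth["true_hefi"], ev)[0, 1]
        assert abs(r) < 0.01


class TestTruthSeparation:
    def test_observed_view_has_no_truth(self, small_cohort):
        obs = small_cohort.observed()
        assert not hasattr(obs, "truth")
        for name in ("recalls", "urine", "covariates", "outcomes"):
            cols = getattr(obs, name).columns
            assert not any(c.startswith("true_") for c in cols)

    def test_csv_roundtrip(self, small_cohort, tmp_path):
        small_cohort.to_csv(tmp_path)
        assert (tmp_path / "realized_config.json").exists()
        back = pd.read_csv(tmp_path / "recalls.csv")
        pd.testing.assert_frame_equal(
            back, small_cohort.recalls, check_exact=False, atol=1e-12
        )
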