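"""Synthetic cohort generator with the statistical structure the analysis assumes.

The generator emulates a UK-Biobank-like prospective cohort: baseline
covariates, repeated 24-h dietary recalls whose amounts carry within-person
random error around a latent usual intake (episodic categories are
zero-inflated), a casual urine assay generated by inverting the spot-urine
sodium prediction equation from true sodium, and survival outcomes with a
CVD event, competing non-CVD mortality, loss to follow-up and administrative
censoring at 132 months (11 y).

Design targets baked into the defaults (the conditions downstream stages are
tested under): ~2.2 +/- 1.2 recalls per person with 62% completing at least
two; ~2.1% 11-y CVD incidence; ~2.6% competing mortality; ~0.3% loss to
follow-up; diet quality confounded by health-conscious covariates; a
protective exposure effect of hazard ratio 0.8 per +10 HEFI points.

The truth table (latent usual intakes, true HEFI score) is kept separate and
is only for parameter-recovery tests: the analysis pipeline consumes the
:class:`ObservedCohort` view, which does not contain it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .boxcox import boxcox, inverse_boxcox, inverse_boxcox_corrected
from .derivations import (
    SodiumPredictionCoefficients,
    estimate_free_sugars,
    invert_sodium_equation,
    load_intersalt_coefficients,
)
from .scoring import score_hefi

__all__ = [
    "ComponentSpec",
    "GeneratorConfig",
    "SyntheticCohort",
    "ObservedCohort",
    "generate_cohort",
    "generate_recalls",
    "simulate_outcomes",
    "default_components",
    "hefi_inputs_from_amounts",
    "DEFAULT_NATURAL_SUGAR_FACTORS",
]

MONTHS_PER_YEAR = 12.0

#: g of natural sugar per unit amount of each sugar-bearing category.
DEFAULT_NATURAL_SUGAR_FACTORS: Mapping[str, float] = {
    "vegetables": 2.0,   # per RA
    "fruits": 9.0,       # per RA
    "dairy": 0.05,       # per g unsweetened milk
    "legumes": 2.0,      # per RA plant-based protein food
}


@dataclass(frozen=True)
class ComponentSpec:
    """Generating law for one dietary component.

    Recall amounts are Gaussian on the Box-Cox(``lam``) scale around a
    person-level mean ``boxcox(median, lam) + load_q*q + load_v*v + u`` with
    between-person SD ``sd_between`` and within-person (recall-to-recall) SD
    ``sd_within``. Episodic components are consumed on a given recall with
    person-specific probability ``Phi(prob_base + prob_load_q*q + w)``.
    ``q`` is the latent diet-quality factor (confounded by covariates) and
    ``v`` a latent intake-volume factor shared with energy.
    """

    name: str
    unit: str
    median: float
    lam: float
    sd_between: float
    sd_within: float
    load_q: float = 0.0
    load_v: float = 0.0
    episodic: bool = False
    prob_base: float = 0.0        # probit scale; ignored unless episodic
    prob_load_q: float = 0.0
    prob_sd_between: float = 0.8
    observed_in_recalls: bool = True

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError(f"{self.name}: median must be > 0")
        if self.sd_between <= 0 or self.sd_within < 0:
            raise ValueError(f"{self.name}: SDs must be positive")

    @property
    def mean_t(self) -> float:
        return float(boxcox(self.median, self.lam))


def default_components() -> list[ComponentSpec]:
    """Default component laws: 7 food categories (RA/d), 3 beverages (g/d),
    energy and nutrient totals. Two episodic categories (legumes/plant
    protein and sugary drinks)."""
    return [
        ComponentSpec("vegetables", "RA", 2.2, 0.5, 0.35, 0.60, 0.30, 0.15),
        ComponentSpec("fruits", "RA", 1.6, 0.5, 0.35, 0.60, 0.30, 0.10),
        ComponentSpec("whole_grain_foods", "RA", 1.0, 0.5, 0.30, 0.55, 0.25, 0.15),
        ComponentSpec("refined_grain_foods", "RA", 2.2, 0.5, 0.30, 0.55, -0.20, 0.20),
        ComponentSpec("animal_protein_foods", "RA", 1.8, 0.5, 0.25, 0.50, -0.05, 0.20),
        ComponentSpec(
            "plant_protein_foods", "RA", 1.0, 0.0, 0.35, 0.50, 0.20, 0.05,
            episodic=True, prob_base=float(ndtri(0.35)), prob_load_q=0.35,
            prob_sd_between=0.8,
        ),
        ComponentSpec("other_foods", "RA", 2.0, 0.5, 0.30, 0.60, -0.25, 0.25),
        ComponentSpec("water_unsweetened", "g", 1200.0, 0.0, 0.35, 0.45, 0.15, 0.0),
        ComponentSpec("milk_unsweetened", "g", 180.0, 0.0, 0.50, 0.60, 0.0, 0.0),
        ComponentSpec(
            "sugary_drinks", "g", 300.0, 0.0, 0.50, 0.60, -0.25, 0.0,
            episodic=True, prob_base=float(ndtri(0.45)), prob_load_q=-0.40,
            prob_sd_between=0.9,
        ),
        ComponentSpec("energy", "kcal", 2050.0, 0.0, 0.16, 0.22, 0.0, 0.18),
        ComponentSpec("sfa", "g", 25.0, 0.0, 0.22, 0.30, -0.12, 0.18),
        ComponentSpec("mufa", "g", 29.0, 0.0, 0.20, 0.30, 0.0, 0.18),
        ComponentSpec("pufa", "g", 13.0, 0.0, 0.22, 0.32, 0.10, 0.15),
        ComponentSpec("total_sugars", "g", 95.0, 0.0, 0.25, 0.30, 0.05, 0.18),
        # median near UK-typical intake; must sit above the spot-urine
        # equation's covariate-driven base level so the inversion that
        # generates assay values stays inside the physical domain
        ComponentSpec(
            "sodium", "mg", 3400.0, 0.0, 0.18, 0.0, -0.10, 0.12,
            observed_in_recalls=False,
        ),
    ]


#: Standardized-covariate loadings on the latent diet-quality factor q.
DEFAULT_CONFOUNDING: Mapping[str, float] = {
    "female": 0.35,
    "age": 0.20,
    "education": 0.25,
    "smoking": -0.45,
    "physical_activity": 0.30,
    "bmi": -0.25,
    "sedentary_time": -0.15,
    "townsend": -0.15,
    "supplement_use": 0.20,
    "family_history": 0.05,
    "risk_factor": -0.05,
}

#: Standardized-covariate log-hazard effects on CVD.
DEFAULT_COVARIATE_LOG_HAZARD: Mapping[str, float] = {
    "female": -0.35,
    "age": 0.55,
    "smoking": 0.30,
    "bmi": 0.20,
    "physical_activity": -0.12,
    "family_history": 0.18,
    "risk_factor": 0.25,
    "townsend": 0.08,
}

#: Standardized-covariate log-hazard effects on competing (non-CVD) death.
DEFAULT_COMPETING_LOG_HAZARD: Mapping[str, float] = {
    "age": 0.65,
    "smoking": 0.40,
    "female": -0.15,
    "bmi": 0.10,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of the synthetic cohort law.

    ``baseline_hazard``, ``competing_mortality_rate`` and ``loss_rate`` are
    per-month exponential rates; leave them ``None`` to calibrate by
    root-finding so the realized 11-y proportions hit ``target_cvd``,
    ``target_competing`` and ``target_loss``.
    """

    n_participants: int = 5000
    recall_count_distribution: Sequence[float] = (0.38, 0.25, 0.18, 0.12, 0.07)
    components: Sequence[ComponentSpec] = field(default_factory=default_components)
    confounding_strength: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDING)
    )
    q_residual_sd: float | None = None  # None: chosen so var(q) = 1
    log_hazard_per_10pts: float = float(np.log(0.8))
    covariate_log_hazard: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LOG_HAZARD)
    )
    competing_log_hazard: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPETING_LOG_HAZARD)
    )
    baseline_hazard: float | None = None
    competing_mortality_rate: float | None = None
    loss_rate: float | None = None
    target_cvd: float = 0.021
    target_competing: float = 0.026
    target_loss: float = 0.003
    admin_censor_months: float = 132.0
    urine_noise_sd_mg: float = 300.0
    natural_sugar_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NATURAL_SUGAR_FACTORS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.recall_count_distribution, dtype=float)
        if len(p) != 5 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(
                "recall_count_distribution must be 5 non-negative probabilities summing to 1"
            )
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be positive")
        for rate in (self.baseline_hazard, self.competing_mortality_rate, self.loss_rate):
            if rate is not None and rate < 0:
                raise ValueError("hazard rates must be non-negative")


@dataclass(frozen=True)
class ObservedCohort:
    """The tables the analysis pipeline is allowed to see (no truth)."""

    recalls: pd.DataFrame
    urine: pd.DataFrame
    covariates: pd.DataFrame
    outcomes: pd.DataFrame


@dataclass(frozen=True)
class SyntheticCohort:
    recalls: pd.DataFrame
    urine: pd.DataFrame
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame
    realized: dict

    def observed(self) -> ObservedCohort:
        return ObservedCohort(self.recalls, self.urine, self.covariates, self.outcomes)

    def to_csv(self, outdir) -> None:
        """Write the five tables plus a JSON sidecar of the realized config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("recalls", "urine", "covariates", "outcomes", "truth"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "realized_config.json", "w") as fh:
            json.dump(self.realized, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# covariates and latents

def _generate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    female = rng.random(n) < 0.553
    cov = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "female": female.astype(int),
            "age": np.clip(rng.normal(57.2, 8.0, n), 40.0, 75.0),
            "bmi": np.clip(rng.normal(26.5, 4.3, n), 16.0, 55.0),
            "townsend": np.clip(rng.normal(-1.3, 2.8, n), -6.5, 10.0),
            "education": (rng.random(n) < 0.504).astype(int),
            "employment": rng.choice(3, size=n, p=[0.55, 0.35, 0.10]),
            "family_history": (rng.random(n) < 0.25).astype(int),
            "smoking": (rng.random(n) < 0.10).astype(int),
            "physical_activity": rng.choice(3, size=n, p=[0.20, 0.45, 0.35]),
            "alcohol": (rng.random(n) < 0.92).astype(int),
            "sedentary_time": np.clip(rng.normal(4.6, 2.3, n), 0.0, 16.0),
            "supplement_use": (rng.random(n) < 0.35).astype(int),
            "medication_use": (rng.random(n) < 0.20).astype(int),
            "risk_factor": (rng.random(n) < 0.30).astype(int),
        }
    )
    cov["menopausal"] = np.where(female, (rng.random(n) < 0.60).astype(int), 0)
    cov["hormone_therapy"] = np.where(female, (rng.random(n) < 0.20).astype(int), 0)
    return cov


def _standardize(cov: pd.DataFrame, names) -> pd.DataFrame:
    z = {}
    for name in names:
        x = cov[name].to_numpy(float)
        sd = x.std()
        z[name] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    return pd.DataFrame(z, index=cov.index)


def _latent_quality(
    cov: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    loads = config.confounding_strength
    z = _standardize(cov, loads.keys())
    systematic = sum(w * z[name].to_numpy() for name, w in loads.items())
    load_var = float(sum(w**2 for w in loads.values()))
    if config.q_residual_sd is not None:
        resid_sd = config.q_residual_sd
    else:
        resid_sd = np.sqrt(max(1.0 - load_var, 0.05))
    return systematic + rng.normal(0.0, resid_sd, len(cov))


# ---------------------------------------------------------------------------
# dietary truth and recalls

def _person_effects(
    config: GeneratorConfig, q: np.ndarray, v: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Person-level means on the transformed scale (and probit scores for
    episodic components)."""
    n = len(q)
    eff = {"person_id": np.arange(n)}
    for spec in config.components:
        mu = spec.mean_t + spec.load_q * q + spec.load_v * v
        eff[f"mu_{spec.name}"] = mu + rng.normal(0.0, spec.sd_between, n)
        if spec.episodic:
            pi = spec.prob_base + spec.prob_load_q * q
            eff[f"pi_{spec.name}"] = pi + rng.normal(0.0, spec.prob_sd_between, n)
    return pd.DataFrame(eff)


def _true_usual_amounts(config: GeneratorConfig, effects: pd.DataFrame) -> pd.DataFrame:
    out = {"person_id": effects["person_id"].to_numpy()}
    for spec in config.components:
        mu = effects[f"mu_{spec.name}"].to_numpy()
        amount = inverse_boxcox_corrected(mu, spec.lam, spec.sd_within**2)
        if spec.episodic:
            amount = ndtr(effects[f"pi_{spec.name}"].to_numpy()) * amount
        out[spec.name] = amount
    return pd.DataFrame(out)


def hefi_inputs_from_amounts(
    amounts: pd.DataFrame,
    sodium_mg: np.ndarray,
    natural_sugar_factors: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Map generator/estimated component amounts to HEFI scoring inputs.

    ``amounts`` uses the generator's component names; sodium is supplied
    separately (truth, or the urine-predicted value in the observed
    pipeline). Free sugars are derived from total sugars and the natural
    sugars in vegetables, fruits, dairy (unsweetened milk) and legumes
    (plant-based protein foods).
    """
    if natural_sugar_factors is None:
        natural_sugar_factors = DEFAULT_NATURAL_SUGAR_FACTORS
    free_sugars = estimate_free_sugars(
        amounts["total_sugars"].to_numpy(float),
        {
            "vegetables": amounts["vegetables"].to_numpy(float),
            "fruits": amounts["fruits"].to_numpy(float),
            "dairy": amounts["milk_unsweetened"].to_numpy(float),
            "legumes": amounts["plant_protein_foods"].to_numpy(float),
        },
        natural_sugar_factors,
    )
    protein = (
        amounts["animal_protein_foods"].to_numpy(float)
        + amounts["plant_protein_foods"].to_numpy(float)
    )
    return pd.DataFrame(
        {
            "vf_ra": amounts["vegetables"].to_numpy(float)
            + amounts["fruits"].to_numpy(float),
            "whole_grain_ra": amounts["whole_grain_foods"].to_numpy(float),
            "refined_grain_ra": amounts["refined_grain_foods"].to_numpy(float),
            "protein_ra": protein,
            "plant_protein_ra": amounts["plant_protein_foods"].to_numpy(float),
            "other_food_ra": amounts["other_foods"].to_numpy(float),
            "rec_bev_g": amounts["water_unsweetened"].to_numpy(float)
            + amounts["milk_unsweetened"].to_numpy(float),
            "other_bev_g": amounts["sugary_drinks"].to_numpy(float),
            "energy_kcal": amounts["energy"].to_numpy(float),
            "sfa_g": amounts["sfa"].to_numpy(float),
            "mufa_g": amounts["mufa"].to_numpy(float),
            "pufa_g": amounts["pufa"].to_numpy(float),
            "free_sugars_g": free_sugars,
            "sodium_mg": np.asarray(sodium_mg, dtype=float),
        },
        index=amounts.index,
    )


def generate_recalls(
    effects: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate the repeated 24-h recalls given person-level effects.

    Each recall draws within-person Gaussian noise on the transform scale
    (back-transformed to amounts); episodic components are zero on
    non-consumption days (Bernoulli with the person's probit probability).
    Recall-level energy is floored at 100 kcal, mirroring the eligibility
    floor of the emulated instrument.
    """
    n = len(effects)
    counts = rng.choice(
        np.arange(1, 6), size=n, p=np.asarray(config.recall_count_distribution, float)
    )
    person_rows = np.repeat(np.arange(n), counts)
    recall_no = np.concatenate([np.arange(1, c + 1) for c in counts])
    rows = {
        "person_id": effects["person_id"].to_numpy()[person_rows],
        "recall_no": recall_no,
    }
    total = len(person_rows)
    for spec in config.components:
        if not spec.observed_in_recalls:
            continue
        mu = effects[f"mu_{spec.name}"].to_numpy()[person_rows]
        amount = inverse_boxcox(mu + rng.normal(0.0, spec.sd_within, total), spec.lam)
        if spec.episodic:
            p = ndtr(effects[f"pi_{spec.name}"].to_numpy()[person_rows])
            amount = np.where(rng.random(total) < p, amount, 0.0)
        if spec.name == "energy":
            amount = np.maximum(amount, 100.0)
        rows[spec.name] = amount
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# urine assay

def _generate_urine(
    cov: pd.DataFrame,
    true_sodium_mg: np.ndarray,
    config: GeneratorConfig,
    coeffs: SodiumPredictionCoefficients,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(cov)
    urine = pd.DataFrame(
        {
            "person_id": cov["person_id"].to_numpy(),
            "urine_k": np.exp(rng.normal(np.log(60.0), 0.30, n)),
            "urine_cr": np.exp(rng.normal(np.log(9.0), 0.35, n)),
            "female": cov["female"].to_numpy(bool),
            "age": cov["age"].to_numpy(float),
            "bmi": cov["bmi"].to_numpy(float),
        }
    )
    target = true_sodium_mg + rng.normal(0.0, config.urine_noise_sd_mg, n)
    na = invert_sodium_equation(target, urine, coeffs)
    urine.insert(1, "urine_na", np.clip(na, 1.0, None))
    return urine[["person_id", "urine_na", "urine_k", "urine_cr", "female", "age", "bmi"]]


# ---------------------------------------------------------------------------
# outcomes

def _event_probability(rates: np.ndarray, total: np.ndarray, horizon: float) -> np.ndarray:
    """P(this exponential clock rings first and before the horizon)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = rates / total * (1.0 - np.exp(-total * horizon))
    return np.where(total > 0, p, 0.0)


def _calibrate_rates(
    lp_cvd: np.ndarray, lp_death: np.ndarray, config: GeneratorConfig
) -> tuple[float, float, float]:
    """Root-find baseline rates so marginal 11-y event proportions hit the
    configured targets (closed form under competing exponential clocks)."""
    C = config.admin_censor_months
    e_cvd, e_death = np.exp(lp_cvd), np.exp(lp_death)
    lam0 = config.baseline_hazard
    del0 = config.competing_mortality_rate
    rho = config.loss_rate

    # crude starting points ignoring competition
    lam = lam0 if lam0 is not None else -np.log(1 - config.target_cvd) / C / e_cvd.mean()
    dl = del0 if del0 is not None else -np.log(1 - config.target_competing) / C / e_death.mean()
    rh = rho if rho is not None else -np.log(1 - max(config.target_loss, 1e-9)) / C

    for _ in range(4):  # fixed-point over the three coupled calibrations
        total = lambda l, d, r: l * e_cvd + d * e_death + r
        if lam0 is None and config.target_cvd > 0:
            f = lambda l: _event_probability(l * e_cvd, total(l, dl, rh), C).mean() - config.target_cvd
            lam = brentq(f, 1e-12, 1.0)
        if del0 is None and config.target_competing > 0:
            f = lambda d: _event_probability(d * e_death, total(lam, d, rh), C).mean() - config.target_competing
            dl = brentq(f, 1e-12, 1.0)
        if rho is None and config.target_loss > 0:
            f = lambda r: _event_probability(
                np.full_like(e_cvd, r), total(lam, dl, r), C
            ).mean() - config.target_loss
            rh = brentq(f, 1e-12, 1.0)
    if lam0 is None and config.target_cvd == 0:
        lam = 0.0
    if del0 is None and config.target_competing == 0:
        dl = 0.0
    if rho is None and config.target_loss == 0:
        rh = 0.0
    return float(lam), float(dl), float(rh)


def simulate_outcomes(
    true_hefi: np.ndarray,
    covariates: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
    return_rates: bool = False,
):
    """Simulate event times under competing exponential clocks.

    The CVD log-hazard is ``log(baseline) + log_hazard_per_10pts *
    (HEFI - mean)/10 + covariate terms``; competing death and loss have their
    own clocks; everyone still at risk at ``admin_censor_months`` is
    administratively censored. Event type is one of ``cvd``, ``death``,
    ``loss``, ``censor``.
    """
    n = len(true_hefi)
    z = _standardize(covariates, set(config.covariate_log_hazard) | set(config.competing_log_hazard))
    hefi_c = (np.asarray(true_hefi, float) - np.mean(true_hefi)) / 10.0
    lp_cvd = config.log_hazard_per_10pts * hefi_c + sum(
        b * z[name].to_numpy() for name, b in config.covariate_log_hazard.items()
    )
    lp_death = sum(
        b * z[name].to_numpy() for name, b in config.competing_log_hazard.items()
    )
    lp_death = lp_death if isinstance(lp_death, np.ndarray) else np.zeros(n)
    lam, dl, rh = _calibrate_rates(lp_cvd, lp_death, config)

    def draw_exp(rates):
        with np.errstate(divide="ignore"):
            t = rng.exponential(1.0, n) / np.where(rates > 0, rates, np.nan)
        return np.where(np.isnan(t), np.inf, t)

    t_cvd = draw_exp(lam * np.exp(lp_cvd))
    t_death = draw_exp(dl * np.exp(lp_death))
    t_loss = draw_exp(np.full(n, rh))
    C = config.admin_censor_months
    stacked = np.column_stack([t_cvd, t_death, t_loss, np.full(n, C)])
    which = np.argmin(stacked, axis=1)
    time = stacked[np.arange(n), which]
    event = np.array(["cvd", "death", "loss", "censor"])[which]
    outcomes = pd.DataFrame(
        {
            "person_id": covariates["person_id"].to_numpy(),
            "time_months": time,
            "event": event,
        }
    )
    if return_rates:
        return outcomes, {"baseline_hazard": lam, "competing_rate": dl, "loss_rate": rh}
    return outcomes


# ---------------------------------------------------------------------------
# top level

def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (deterministic under config + seed)."""
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    coeffs = load_intersalt_coefficients()

    covariates = _generate_covariates(config.n_participants, rng)
    q = _latent_quality(covariates, config, rng)
    v = rng.normal(0.0, 1.0, config.n_participants) - 0.3 * _standardize(
        covariates, ["female"]
    )["female"].to_numpy()
    effects = _person_effects(config, q, v, rng)
    truth_amounts = _true_usual_amounts(config, effects)

    true_inputs = hefi_inputs_from_amounts(
        truth_amounts,
        truth_amounts["sodium"].to_numpy(),
        config.natural_sugar_factors,
    )
    true_scores = score_hefi(true_inputs)
    truth = truth_amounts.copy()
    truth["true_hefi"] = true_scores["total"].to_numpy()

    recalls = generate_recalls(effects, config, rng)
    urine = _generate_urine(covariates, truth_amounts["sodium"].to_numpy(), config, coeffs, rng)
    outcomes, rates = simulate_outcomes(
        truth["true_hefi"].to_numpy(), covariates, config, rng, return_rates=True
    )

    realized = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "log_hazard_per_10pts": config.log_hazard_per_10pts,
        "admin_censor_months": config.admin_censor_months,
        "recall_count_distribution": list(config.recall_count_distribution),
        **rates,
        "realized_cvd_incidence": float((outcomes["event"] == "cvd").mean()),
        "realized_competing": float((outcomes["event"] == "death").mean()),
        "realized_loss": float((outcomes["event"] == "loss").mean()),
        "mean_recalls": float(recalls.groupby("person_id").size().mean()),
        "mean_true_hefi": float(truth["true_hefi"].mean()),
        "sd_true_hefi": float(truth["true_hefi"].std()),
    }
    return SyntheticCohort(recalls, urine, covariates, outcomes, truth, realized)
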