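"""Derived HEFI-2019 inputs the recall instrument does not report directly.

Three derivations:

* 24-h sodium intake predicted from a casual (spot) urine assay with the
  INTERSALT sex-specific equations (sodium, potassium, creatinine
  concentrations plus BMI and age; the female equation has an age^2 term),
* free sugars as total sugars minus the natural-sugar contribution of
  vegetables, fruits, dairy and legumes,
* classification of energy reporting plausibility from the ratio of reported
  energy intake to a predicted energy requirement (plausible within
  0.74-1.26, bounds inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SodiumPredictionCoefficients",
    "load_intersalt_coefficients",
    "predict_sodium_24h",
    "NATURAL_SUGAR_CATEGORIES",
    "estimate_free_sugars",
    "PlausibilityCutoffs",
    "predicted_energy_requirement",
    "classify_energy_reporting",
]

_TERMS = ("intercept", "urine_na", "urine_k", "urine_cr", "bmi", "age", "age2")

#: Category keys accepted by :func:`estimate_free_sugars`.
NATURAL_SUGAR_CATEGORIES = ("vegetables", "fruits", "dairy", "legumes")


@dataclass(frozen=True)
class SodiumPredictionCoefficients:
    """Per-sex linear coefficients mapping a spot urine assay to mmol Na/24 h.

    ``male`` and ``female`` map term names (see ``_TERMS``) to coefficients;
    the linear predictor is in mmol/24 h and is converted to mg/24 h with
    ``mg_per_mmol``.
    """

    male: Mapping[str, float]
    female: Mapping[str, float]
    mg_per_mmol: float = 23.0
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for sex, coefs in (("male", self.male), ("female", self.female)):
            unknown = set(coefs) - set(_TERMS)
            if unknown:
                raise ValueError(f"{sex}: unknown coefficient terms {sorted(unknown)}")
            if not all(np.isfinite(list(coefs.values()))):
                raise ValueError(f"{sex}: non-finite coefficient")

    def for_sex(self, female: bool) -> Mapping[str, float]:
        return self.female if female else self.male


def load_intersalt_coefficients(path=None) -> SodiumPredictionCoefficients:
    """Load the packaged (or a user-supplied) INTERSALT coefficient file."""
    if path is None:
        ref = resources.files("hefi_cvd.data") / "intersalt.yaml"
        with resources.as_file(ref) as p:
            raw = yaml.safe_load(open(p))
    else:
        raw = yaml.safe_load(open(path))
    return SodiumPredictionCoefficients(
        male=raw["male"],
        female=raw["female"],
        mg_per_mmol=float(raw.get("mg_per_mmol", 23.0)),
        version=str(raw.get("version", "unversioned")),
    )


def _sodium_linear_predictor(urine: pd.DataFrame, coeffs: SodiumPredictionCoefficients) -> np.ndarray:
    female = urine["female"].to_numpy(bool)
    age = urine["age"].to_numpy(float)
    cols = {
        "intercept": np.ones(len(urine)),
        "urine_na": urine["urine_na"].to_numpy(float),
        "urine_k": urine["urine_k"].to_numpy(float),
        "urine_cr": urine["urine_cr"].to_numpy(float),
        "bmi": urine["bmi"].to_numpy(float),
        "age": age,
        "age2": age**2,
    }
    lp = np.zeros(len(urine))
    for sex_female in (False, True):
        coefs = coeffs.for_sex(sex_female)
        mask = female == sex_female
        lp[mask] = sum(coefs.get(t, 0.0) * cols[t][mask] for t in _TERMS)
    return lp


def predict_sodium_24h(
    urine: pd.DataFrame, coeffs: SodiumPredictionCoefficients | None = None
) -> pd.DataFrame:
    """Predict 24-h sodium intake (mg) from casual urine concentrations.

    ``urine`` needs columns ``urine_na``, ``urine_k``, ``urine_cr`` (mmol/L,
    all > 0), ``female`` (bool), ``age`` (y) and ``bmi`` (kg/m^2). Returns a
    DataFrame with ``sodium_mg`` (floored at 0) and ``floored`` flagging the
    rare negative linear predictors.
    """
    if coeffs is None:
        coeffs = load_intersalt_coefficients()
    required = ["urine_na", "urine_k", "urine_cr", "female", "age", "bmi"]
    missing = [c for c in required if c not in urine.columns]
    if missing:
        raise ValueError(f"urine table missing columns: {missing}")
    conc = urine[["urine_na", "urine_k", "urine_cr"]].to_numpy(float)
    if not (conc > 0).all():
        raise ValueError("urine concentrations must be strictly positive")
    mmol = _sodium_linear_predictor(urine, coeffs)
    mg = mmol * coeffs.mg_per_mmol
    floored = mg < 0
    return pd.DataFrame(
        {"sodium_mg": np.where(floored, 0.0, mg), "floored": floored}, index=urine.index
    )


def invert_sodium_equation(
    sodium_mg: np.ndarray, urine_no_na: pd.DataFrame, coeffs: SodiumPredictionCoefficients
) -> np.ndarray:
    """Solve the prediction equation for the spot sodium concentration.

    Given target 24-h sodium (mg) and the other assay/anthropometry columns,
    return the ``urine_na`` (mmol/L) that reproduces it exactly. Used by the
    synthetic cohort generator so that the derivation has a recoverable
    signal.
    """
    tmp = urine_no_na.copy()
    tmp["urine_na"] = 0.0
    base = _sodium_linear_predictor(tmp, coeffs)
    female = urine_no_na["female"].to_numpy(bool)
    b_na = np.where(
        female, coeffs.for_sex(True)["urine_na"], coeffs.for_sex(False)["urine_na"]
    )
    return (np.asarray(sodium_mg, float) / coeffs.mg_per_mmol - base) / b_na


def estimate_free_sugars(
    total_sugars_g,
    category_amounts: Mapping[str, np.ndarray],
    factors: Mapping[str, float],
) -> np.ndarray:
    """Free sugars (g/d) = total sugars minus natural sugars, floored at 0.

    ``category_amounts`` maps a subset of :data:`NATURAL_SUGAR_CATEGORIES` to
    daily amounts; ``factors`` gives each category's natural-sugar content
    per unit amount (g sugar per RA or per g). Unknown keys are rejected.
    """
    for mapping, label in ((category_amounts, "category_amounts"), (factors, "factors")):
        unknown = set(mapping) - set(NATURAL_SUGAR_CATEGORIES)
        if unknown:
            raise ValueError(f"{label}: unknown categories {sorted(unknown)}")
    if any(f < 0 for f in factors.values()):
        raise ValueError("natural-sugar factors must be >= 0")
    total = np.asarray(total_sugars_g, dtype=float)
    natural = np.zeros_like(total)
    for cat, amounts in category_amounts.items():
        natural = natural + factors.get(cat, 0.0) * np.asarray(amounts, dtype=float)
    return np.maximum(0.0, total - natural)


@dataclass(frozen=True)
class PlausibilityCutoffs:
    """Reported/predicted energy ratio bounds for plausible reporting."""

    lower: float = 0.74
    upper: float = 1.26

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError("need 0 < lower < upper")


# Sex-typical stature (m) used to recover weight from BMI when only BMI is
# recorded; feeds the Mifflin-St-Jeor-type resting energy expenditure below.
_STATURE_M = {False: 1.76, True: 1.63}
_PAL = np.array([1.4, 1.6, 1.8])  # low / moderate / high physical activity


def predicted_energy_requirement(female, age, bmi, activity_level) -> np.ndarray:
    """Predicted daily energy requirement (kcal) from sex, age, BMI, activity.

    Resting energy expenditure from a Mifflin-St-Jeor-type equation evaluated
    at sex-typical stature (weight recovered as BMI x height^2), multiplied by
    an activity-dependent physical activity level (1.4/1.6/1.8 for
    low/moderate/high). A documented, swappable convention.
    """
    female = np.asarray(female, dtype=bool)
    age = np.asarray(age, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    act = np.asarray(activity_level, dtype=int)
    h = np.where(female, _STATURE_M[True], _STATURE_M[False])
    weight = bmi * h**2
    ree = 10.0 * weight + 625.0 * h - 5.0 * age + np.where(female, -161.0, 5.0)
    return ree * _PAL[np.clip(act, 0, 2)]


def classify_energy_reporting(
    reported_energy, predicted_requirement, cutoffs: PlausibilityCutoffs | None = None
) -> np.ndarray:
    """Label each person's energy reporting as under / plausible / over.

    The plausible band is the closed interval [lower, upper] on the ratio of
    reported intake to predicted requirement ("within 0.74-1.26").
    """
    if cutoffs is None:
        cutoffs = PlausibilityCutoffs()
    reported = np.asarray(reported_energy, dtype=float)
    predicted = np.asarray(predicted_requirement, dtype=float)
    if (predicted <= 0).any():
        raise ValueError("predicted energy requirement must be > 0")
    if (reported <= 0).any():
        raise ValueError("reported energy must be > 0")
    ratio = reported / predicted
    out = np.where(ratio < cutoffs.lower, "under", "plausible")
    out = np.where(ratio > cutoffs.upper, "over", out)
    return out
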