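"""HEFI-2019 scoring engine.

The Healthy Eating Food Index 2019 measures adherence to Canada's Food Guide
2019 recommendations on healthy food choices. It has 10 components — 5 on
foods, 1 on beverages and 4 on nutrients — worth 80 points in total. Each
component converts a ratio or density (e.g. the share of total food intake,
in reference amounts, coming from vegetables and fruits; mg of sodium per
kcal) into points allocated proportionally between a zero-credit and a
full-credit cutoff.

The engine is cutoff-agnostic: the component definitions (ratio name,
direction, cutoffs, maximum points) live in a standards file, with a default
shipped in :mod:`hefi_cvd.data`. Inputs are daily intakes, either for one
profile (a mapping) or for many (a DataFrame), using the canonical columns in
:data:`HEFI_INPUT_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ComponentStandard",
    "HEFI_INPUT_COLUMNS",
    "load_standards",
    "default_standards",
    "compute_ratios",
    "score_component",
    "score_hefi",
    "full_credit_profile",
]

#: Canonical per-day input columns for the scoring engine.
#: RA = reference amounts/day, g = grams/day, mg = mg/day, kcal = kcal/day.
HEFI_INPUT_COLUMNS = (
    "vf_ra",             # vegetables & fruits
    "whole_grain_ra",
    "refined_grain_ra",
    "protein_ra",        # all protein foods (includes plant-based)
    "plant_protein_ra",
    "other_food_ra",
    "rec_bev_g",         # water and other recommended (unsweetened) beverages
    "other_bev_g",
    "energy_kcal",
    "sfa_g",
    "mufa_g",
    "pufa_g",
    "free_sugars_g",
    "sodium_mg",
)

KCAL_PER_G_FAT = 9.0
KCAL_PER_G_SUGAR = 4.0


@dataclass(frozen=True)
class ComponentStandard:
    """Scoring standard for one HEFI-2019 component.

    ``direction`` is "higher" when larger ratios earn more points and "lower"
    for the moderation components (saturated fat, free sugars, sodium).
    """

    name: str
    ratio: str
    max_points: float
    direction: str
    zero_cutoff: float
    full_cutoff: float

    def __post_init__(self) -> None:
        if self.max_points <= 0:
            raise ValueError(f"{self.name}: max_points must be > 0")
        if self.direction not in ("higher", "lower"):
            raise ValueError(f"{self.name}: direction must be 'higher' or 'lower'")
        if self.zero_cutoff == self.full_cutoff:
            raise ValueError(f"{self.name}: cutoffs must be distinct")
        if self.direction == "higher" and not self.full_cutoff > self.zero_cutoff:
            raise ValueError(f"{self.name}: higher-better needs full > zero cutoff")
        if self.direction == "lower" and not self.full_cutoff < self.zero_cutoff:
            raise ValueError(f"{self.name}: lower-better needs full < zero cutoff")


def load_standards(path) -> list[ComponentStandard]:
    """Load component standards from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [ComponentStandard(**block) for block in raw["components"]]


def default_standards() -> list[ComponentStandard]:
    """The packaged default HEFI-2019 standards (10 components, 80 points)."""
    ref = resources.files("hefi_cvd.data") / "hefi2019_standards.yaml"
    with resources.as_file(ref) as path:
        return load_standards(path)


def _as_frame(inputs) -> pd.DataFrame:
    if isinstance(inputs, pd.DataFrame):
        df = inputs
    else:
        df = pd.DataFrame({k: np.atleast_1d(v) for k, v in dict(inputs).items()})
    missing = [c for c in HEFI_INPUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing HEFI input columns: {missing}")
    return df


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Element-wise num/den with NaN (not an error) where den == 0."""
    out = np.full(np.broadcast(num, den).shape, np.nan, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def compute_ratios(inputs) -> pd.DataFrame:
    """Compute the 10 HEFI-2019 ratios/densities for one or many profiles.

    Undefined ratios (zero denominator, e.g. no food reported at all) come
    back as NaN; :func:`score_hefi` turns them into zero points plus a flag
    rather than an error.
    """
    df = _as_frame(inputs)
    vf = df["vf_ra"].to_numpy(float)
    whole = df["whole_grain_ra"].to_numpy(float)
    refined = df["refined_grain_ra"].to_numpy(float)
    protein = df["protein_ra"].to_numpy(float)
    plant = df["plant_protein_ra"].to_numpy(float)
    other = df["other_food_ra"].to_numpy(float)
    total_food = vf + whole + refined + protein + other
    rec_bev = df["rec_bev_g"].to_numpy(float)
    other_bev = df["other_bev_g"].to_numpy(float)
    energy = df["energy_kcal"].to_numpy(float)
    sfa = df["sfa_g"].to_numpy(float)

    ratios = pd.DataFrame(
        {
            "vf_share": _safe_ratio(vf, total_food),
            "whole_grain_share": _safe_ratio(whole, total_food),
            "grain_ratio": _safe_ratio(whole, whole + refined),
            "protein_share": _safe_ratio(protein, total_food),
            "plant_protein_ratio": _safe_ratio(plant, protein),
            "recommended_bev_ratio": _safe_ratio(rec_bev, rec_bev + other_bev),
            "unsat_sat_ratio": _safe_ratio(
                df["mufa_g"].to_numpy(float) + df["pufa_g"].to_numpy(float), sfa
            ),
            "sfa_pct_energy": _safe_ratio(sfa * KCAL_PER_G_FAT, energy) * 100.0,
            "free_sugars_pct_energy": _safe_ratio(
                df["free_sugars_g"].to_numpy(float) * KCAL_PER_G_SUGAR, energy
            )
            * 100.0,
            "sodium_density": _safe_ratio(df["sodium_mg"].to_numpy(float), energy),
        },
        index=df.index,
    )
    return ratios


def score_component(ratio, standard: ComponentStandard) -> np.ndarray:
    """Points for one component: proportional allocation between cutoffs.

    NaN ratios (undefined denominator) score 0 points — the conservative
    convention; callers can detect them via the flags in :func:`score_hefi`.
    """
    r = np.asarray(ratio, dtype=float)
    if standard.direction == "higher":
        frac = (r - standard.zero_cutoff) / (standard.full_cutoff - standard.zero_cutoff)
    else:
        frac = (standard.zero_cutoff - r) / (standard.zero_cutoff - standard.full_cutoff)
    with np.errstate(invalid="ignore"):
        pts = standard.max_points * np.clip(frac, 0.0, 1.0)
    return np.where(np.isnan(r), 0.0, pts)


def score_hefi(inputs, standards: Sequence[ComponentStandard] | None = None) -> pd.DataFrame:
    """Score one or many dietary profiles.

    Returns a DataFrame with one points column per component, ``total``
    (out of the sum of max points, 80 under the defaults), the underlying
    ratio values (``ratio_<name>``), and ``flag_<name>`` booleans marking
    components whose ratio was undefined.
    """
    if standards is None:
        standards = default_standards()
    if len(standards) != 10:
        raise ValueError(f"expected 10 component standards, got {len(standards)}")
    ratios = compute_ratios(inputs)
    out = pd.DataFrame(index=ratios.index)
    total = np.zeros(len(ratios))
    for st in standards:
        r = ratios[st.ratio].to_numpy()
        pts = score_component(r, st)
        out[st.name] = pts
        out[f"ratio_{st.name}"] = r
        out[f"flag_{st.name}"] = np.isnan(r)
        total = total + pts
    out["total"] = total
    return out


def full_credit_profile() -> dict[str, float]:
    """A dietary profile meeting every full-credit standard under the defaults.

    Used in tests and worked examples: half of food intake from vegetables
    and fruits, all grains whole, a quarter of intake from protein foods with
    more than half plant-based, only water as beverage, a favourable fat mix,
    and low free sugars and sodium.
    """
    return {
        "vf_ra": 5.0,
        "whole_grain_ra": 2.5,
        "refined_grain_ra": 0.0,
        "protein_ra": 2.5,
        "plant_protein_ra": 1.5,
        "other_food_ra": 0.0,
        "rec_bev_g": 1500.0,
        "other_bev_g": 0.0,
        "energy_kcal": 2000.0,
        "sfa_g": 15.0,
        "mufa_g": 25.0,
        "pufa_g": 15.0,
        "free_sugars_g": 40.0,
        "sodium_mg": 1500.0,
    }
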