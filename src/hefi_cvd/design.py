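"""Covariate design matrices shared by the measurement-error and weighting models."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .splines import DEFAULT_KNOT_PERCENTILES, knots_from_percentiles, rcs_basis

__all__ = ["covariate_design", "CONTINUOUS_COVARIATES"]

CONTINUOUS_COVARIATES = ("age", "bmi", "townsend", "sedentary_time")


def covariate_design(
    covariates: pd.DataFrame,
    spline_continuous: bool = True,
    extra: Mapping[str, np.ndarray] | None = None,
    include_intercept: bool = True,
    columns: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build a design matrix from a baseline covariate table.

    Continuous covariates are expanded as restricted cubic splines with 4
    knots at percentiles 5/35/65/95 (the a-priori transformation used for
    confounder adjustment) when ``spline_continuous`` is set, otherwise
    entered linearly; everything is standardized to mean 0 / SD 1 for
    numerical stability. ``extra`` adds person-level columns (e.g. the
    urine-predicted sodium intake in the measurement-error model).
    """
    if columns is None:
        columns = [c for c in covariates.columns if c != "person_id"]
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if include_intercept:
        blocks.append(np.ones((len(covariates), 1)))
        names.append("intercept")

    def add(name: str, x: np.ndarray) -> None:
        x = np.asarray(x, dtype=float)
        if name in CONTINUOUS_COVARIATES and spline_continuous and np.unique(x).size > 10:
            knots = knots_from_percentiles(x, DEFAULT_KNOT_PERCENTILES)
            basis = rcs_basis(x, knots)
            for j in range(basis.shape[1]):
                col = basis[:, j]
                sd = col.std()
                blocks.append(((col - col.mean()) / (sd if sd > 0 else 1.0))[:, None])
                names.append(f"{name}_rcs{j}")
        else:
            sd = x.std()
            blocks.append(((x - x.mean()) / (sd if sd > 0 else 1.0))[:, None])
            names.append(name)

    for name in columns:
        add(name, covariates[name].to_numpy())
    if extra:
        for name, x in extra.items():
            add(name, np.asarray(x))
    return np.hstack(blocks), names
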