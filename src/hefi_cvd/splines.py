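"""Restricted cubic spline (natural spline) basis, Harrell parameterization.

With k knots the basis has k-1 columns: the identity plus k-2 nonlinear
terms built from truncated cubic powers, constrained so the fitted function
is linear beyond the boundary knots. Continuous covariates in both the
exposure (IPTW) model and the outcome models are expanded this way; the
dose-response analyses use 4 knots at percentiles 5/35/65/95.
"""

from __future__ import annotations

import numpy as np

__all__ = ["knots_from_percentiles", "rcs_basis", "DEFAULT_KNOT_PERCENTILES"]

DEFAULT_KNOT_PERCENTILES = (5.0, 35.0, 65.0, 95.0)


def knots_from_percentiles(x, percentiles=DEFAULT_KNOT_PERCENTILES) -> np.ndarray:
    """Knot locations at the given percentiles of ``x`` (must be distinct)."""
    knots = np.percentile(np.asarray(x, dtype=float), percentiles)
    if np.unique(knots).size != len(knots):
        raise ValueError("knot percentiles yield duplicate knots")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis matrix, shape (n, k-1).

    Column 0 is x itself; columns j = 1..k-2 are

        [(x - t_j)_+^3 - (x - t_{k-1})_+^3 (t_k - t_j)/(t_k - t_{k-1})
                       + (x - t_k)_+^3 (t_{k-1} - t_j)/(t_k - t_{k-1})]
        / (t_k - t_1)^2

    which vanish into linearity outside [t_1, t_k]. Deterministic in x and
    knots; duplicate knots are rejected.
    """
    x = np.asarray(x, dtype=float)
    t = np.sort(np.asarray(knots, dtype=float))
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    if np.unique(t).size != k:
        raise ValueError("duplicate knots")
    scale = (t[-1] - t[0]) ** 2

    def cube(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    denom = t[-1] - t[-2]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / denom
            + cube(x - t[-1]) * (t[-2] - t[j]) / denom
        )
        cols.append(term / scale)
    return np.column_stack(cols)
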