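"""Box-Cox transformation machinery for intake amounts.

g(x; lam) = (x^lam - 1)/lam for lam != 0, log(x) for lam = 0. The inverse
with second-order bias correction, g^{-1}(m) + 0.5 g^{-1}''(m) s2, converts a
person's mean m and within-person variance s2 on the transformed scale into
an (approximately unbiased) mean on the original scale — the back-
transformation step of usual-intake estimation. Values whose inverse would
leave the transformation's domain (1 + lam*m <= 0) map to 0 intake.
"""

from __future__ import annotations

import numpy as np

__all__ = ["boxcox", "inverse_boxcox", "inverse_boxcox_corrected"]


def boxcox(x, lam: float):
    """Box-Cox transform; requires x > 0 when lam <= 0."""
    x = np.asarray(x, dtype=float)
    if lam <= 0 and np.any(x <= 0):
        raise ValueError("x must be > 0 for lam <= 0")
    if lam == 0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def inverse_boxcox(m, lam: float):
    """Plain inverse transform, floored at 0 outside the domain."""
    m = np.asarray(m, dtype=float)
    if lam == 0:
        return np.exp(m)
    base = 1.0 + lam * m
    with np.errstate(invalid="ignore"):
        out = np.power(np.clip(base, 0.0, None), 1.0 / lam)
    return np.where(base > 0, out, 0.0)


def inverse_boxcox_corrected(m, lam: float, sigma2):
    """Second-order bias-corrected inverse: g^{-1}(m) + 0.5 g^{-1}''(m) sigma2.

    For lam = 1 (affine identity) the correction vanishes exactly; for
    lam = 0 it gives exp(m) (1 + sigma2/2), the second-order expansion of the
    lognormal mean exp(m + sigma2/2).
    """
    if np.any(np.asarray(sigma2) < 0):
        raise ValueError("sigma2 must be >= 0")
    m = np.asarray(m, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if lam == 0:
        return np.exp(m) * (1.0 + sigma2 / 2.0)
    base = 1.0 + lam * m
    with np.errstate(invalid="ignore"):
        g_inv = np.power(np.clip(base, 0.0, None), 1.0 / lam)
        second = (1.0 - lam) * np.power(np.clip(base, 1e-300, None), 1.0 / lam - 2.0)
    out = g_inv + 0.5 * second * sigma2
    return np.where(base > 0, out, 0.0)
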