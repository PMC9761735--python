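"""Stabilized inverse-probability weights for a continuous diet-quality exposure.

IPTW for the continuous HEFI-2019 score uses the "standard normal" density
approach: the score is regressed on confounders (spline-expanded continuous
terms), the conditional density of each person's observed score under that
linear-Gaussian model forms the weight denominator, and the marginal normal
density of the score the stabilizing numerator. IPCW handles informative
censoring (competing non-CVD death or loss to follow-up) with a logistic
model for remaining uncensored. Each factor is rescaled to mean 1
("stabilized to the sample size") before being multiplied together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "WeightSet",
    "BalanceReport",
    "estimate_iptw",
    "estimate_ipcw",
    "combine_weights",
    "balance_report",
]


@dataclass
class WeightSet:
    """Per-person stabilized weights: treatment, censoring and their product."""

    table: pd.DataFrame  # person_id, iptw, ipcw, weight, truncated
    truncation_percentile: float | None = None

    @property
    def weight(self) -> np.ndarray:
        return self.table["weight"].to_numpy()


def _rescale(w: np.ndarray) -> np.ndarray:
    return w / w.mean()


def estimate_iptw(score, X, person_id=None, rng=None) -> pd.DataFrame:
    """Stabilized treatment weights for the continuous score.

    ``X`` is the confounder design matrix (with intercept; energy intake must
    not be among the columns — it belongs to the outcome model only). Returns
    a DataFrame with the raw numerator/denominator densities and the
    mean-one rescaled weight.

    ``rng``: when given, the exposure-model coefficients are redrawn from
    their asymptotic normal distribution before the densities are evaluated
    (parametric-bootstrap propagation of weight-estimation uncertainty).
    """
    a = np.asarray(score, dtype=float)
    X = np.asarray(X, dtype=float)
    ols = sm.OLS(a, X).fit()
    sigma2 = float(ols.scale)
    if not np.isfinite(sigma2) or sigma2 <= 1e-12 * float(np.var(a)):
        raise ValueError("degenerate exposure model: residual variance is 0")
    fitted = np.asarray(ols.fittedvalues)
    if rng is not None:
        beta_star = rng.multivariate_normal(ols.params, ols.cov_params())
        fitted = X @ beta_star
        # residual-variance draw from its large-sample chi-square law
        sigma2 = sigma2 * ols.df_resid / rng.chisquare(ols.df_resid)
    dens_cond = norm.pdf(a, loc=fitted, scale=np.sqrt(sigma2))
    dens_marg = norm.pdf(a, loc=a.mean(), scale=a.std(ddof=1))
    w = _rescale(dens_marg / dens_cond)
    out = pd.DataFrame(
        {
            "iptw": w,
            "numerator": dens_marg,
            "denominator": dens_cond,
        }
    )
    if person_id is not None:
        out.insert(0, "person_id", np.asarray(person_id))
    return out


def estimate_ipcw(outcomes: pd.DataFrame, X, person_id=None, rng=None) -> pd.DataFrame:
    """Stabilized censoring weights from a logistic model.

    A person is "censored" when follow-up ended by competing death or loss
    (events ``death``/``loss``); administrative end-of-study censoring is
    non-informative and does not count. The weight is
    P(uncensored)/P(uncensored | X), rescaled to mean 1. ``rng`` optionally
    redraws the logistic coefficients from their asymptotic normal law
    (parametric bootstrap).
    """
    uncensored = (~outcomes["event"].isin(["death", "loss"])).to_numpy(float)
    X = np.asarray(X, dtype=float)
    if uncensored.all():
        w = np.ones(len(uncensored))
        p_cond = np.ones(len(uncensored))
    else:
        glm = sm.GLM(uncensored, X, family=sm.families.Binomial()).fit()
        if rng is not None:
            # parametric-bootstrap draw; clip rather than abort, since a
            # near-separated fit has a wide asymptotic law whose tail draws
            # are legitimate replicates
            gamma_star = rng.multivariate_normal(glm.params, glm.cov_params())
            p_cond = np.clip(1.0 / (1.0 + np.exp(-(X @ gamma_star))), 1e-4, 1.0)
        else:
            p_cond = np.asarray(glm.fittedvalues)
            # Fitted probabilities hitting 0 blow the weights up (separation);
            # probabilities near 1 are benign under rare censoring.
            if np.any(p_cond <= 1e-8):
                raise ValueError(
                    "separation in the censoring model (fitted probabilities "
                    "of remaining uncensored reach 0)"
                )
        w = _rescale(uncensored.mean() / p_cond)
    out = pd.DataFrame({"ipcw": w, "p_uncensored": p_cond})
    if person_id is not None:
        out.insert(0, "person_id", np.asarray(person_id))
    return out


def combine_weights(
    iptw: pd.DataFrame,
    ipcw: pd.DataFrame,
    truncation_percentile: float | None = None,
) -> WeightSet:
    """Combine the two mean-one factors; optional symmetric truncation.

    ``truncation_percentile`` p caps weights at the p-th and (100-p)-th
    percentiles (off by default); the combined weight is rescaled to mean 1
    afterwards either way.
    """
    if "person_id" in iptw.columns and "person_id" in ipcw.columns:
        if not np.array_equal(iptw["person_id"].to_numpy(), ipcw["person_id"].to_numpy()):
            raise ValueError("IPTW and IPCW person ids do not match")
    w = _rescale(iptw["iptw"].to_numpy()) * _rescale(ipcw["ipcw"].to_numpy())
    truncated = np.zeros(len(w), dtype=bool)
    if truncation_percentile is not None:
        lo, hi = np.percentile(w, [truncation_percentile, 100.0 - truncation_percentile])
        truncated = (w < lo) | (w > hi)
        w = np.clip(w, lo, hi)
    w = _rescale(w)
    table = pd.DataFrame(
        {
            "iptw": iptw["iptw"].to_numpy(),
            "ipcw": ipcw["ipcw"].to_numpy(),
            "weight": w,
            "truncated": truncated,
        }
    )
    if "person_id" in iptw.columns:
        table.insert(0, "person_id", iptw["person_id"].to_numpy())
    return WeightSet(table=table, truncation_percentile=truncation_percentile)


@dataclass
class BalanceReport:
    table: pd.DataFrame  # covariate, unweighted_corr, weighted_corr
    max_weighted_abs: float


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx, vy = np.sum(w * (x - mx) ** 2), np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def balance_report(score, covariates: pd.DataFrame, weights=None) -> BalanceReport:
    """Exposure-covariate correlations before and after weighting.

    One row per covariate column (``person_id`` excluded); the weighted
    column uses the combined stabilized weights.
    """
    a = np.asarray(score, dtype=float)
    w = np.ones(len(a)) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for name in covariates.columns:
        if name == "person_id":
            continue
        x = covariates[name].to_numpy(float)
        rows.append(
            {
                "covariate": name,
                "unweighted_corr": _weighted_corr(x, a, np.ones(len(a))),
                "weighted_corr": _weighted_corr(x, a, w),
            }
        )
    table = pd.DataFrame(rows)
    return BalanceReport(
        table=table, max_weighted_abs=float(table["weighted_corr"].abs().max())
    )
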