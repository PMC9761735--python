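"""Measurement-error-corrected usual intakes from repeated 24-h recalls.

Single 24-h recalls are noisy snapshots of a person's long-term average
("usual") intake; using them directly attenuates diet-outcome associations
and inflates the apparent spread of diet-quality scores. This module
implements an NCI-multivariate-style correction at desk scale:

* each dietary component gets a two-part model — a random-intercept probit
  for the probability of consumption on a given day (episodic components
  only) and a random-intercept linear model for the Box-Cox-transformed
  positive amounts, with person-level covariates as fixed effects;
* the Box-Cox exponent of each amount part is chosen by profile likelihood
  on a small grid;
* the random effects of all parts are tied together through a covariance
  matrix assembled from empirical-Bayes predictions with a
  shrinkage-inflation correction, which is the multivariate ingredient that
  lets episodic and daily components correlate;
* per-person usual intakes are then simulated by Monte Carlo: random-effect
  vectors are drawn from each person's conditional (posterior) distribution
  given their observed recalls, converted to usual intakes via the
  bias-corrected inverse transform, scored with the HEFI-2019 engine, and
  averaged across draws.

The Gaussian amount part is fit by exact maximum likelihood with the fixed
effects and residual structure profiled out (covariates are person-level, so
the person mean and the within-person sum of squares are sufficient); the
probit part by Gauss-Hermite quadrature. statsmodels' general mixed-model
machinery is deliberately not on this path so that it can serve as an
independent cross-check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from .boxcox import boxcox, inverse_boxcox_corrected
from .scoring import score_hefi
from .synthetic import hefi_inputs_from_amounts

__all__ = [
    "LMMFit",
    "ProbitFit",
    "TwoPartComponentModel",
    "MeasurementErrorFit",
    "UsualIntakeDraws",
    "fit_random_intercept_lmm",
    "fit_probit_random_intercept",
    "fit_measurement_error_model",
    "draw_usual_intakes",
    "usual_hefi_from_draws",
    "usual_score_percentiles",
    "DEFAULT_PERCENTILES",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_PERCENTILES = (5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0)
DEFAULT_LAMBDA_GRID = (0.0, 0.25, 1.0 / 3.0, 0.5, 1.0)


# ---------------------------------------------------------------------------
# Gaussian amount part

@dataclass
class LMMFit:
    """ML fit of y_ij = x_i beta + u_i + e_ij with person-level covariates."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_u: float
    sigma_e: float
    loglik: float
    converged: bool
    n_obs: int
    n_persons: int


def _person_stats(y: np.ndarray, person: np.ndarray, n_persons: int):
    n_i = np.bincount(person, minlength=n_persons).astype(float)
    present = n_i > 0
    ybar = np.zeros(n_persons)
    np.divide(
        np.bincount(person, weights=y, minlength=n_persons), n_i,
        out=ybar, where=present,
    )
    ssw = float(np.sum((y - ybar[person]) ** 2))
    return n_i, ybar, ssw, present


def fit_random_intercept_lmm(y, person, X_person) -> LMMFit:
    """Exact ML for the random-intercept LMM with person-level fixed effects.

    ``person`` maps each observation to a row of ``X_person``. Profiles beta
    out by weighted least squares for each variance pair and optimizes the
    2-parameter profile likelihood. Requires at least some persons with >= 2
    observations for the within/between decomposition to be identified.
    """
    y = np.asarray(y, dtype=float)
    person = np.asarray(person, dtype=int)
    Xp = np.asarray(X_person, dtype=float)
    G = Xp.shape[0]
    n_i, ybar, ssw, present = _person_stats(y, person, G)
    df_within = float(np.sum(np.maximum(n_i - 1.0, 0.0)))
    if df_within == 0:
        raise ValueError("no repeated recalls: within-person variance not identifiable")
    N = len(y)
    n_obs_i = n_i[present]
    Xo, yo = Xp[present], ybar[present]

    def profile(se2: float, su2: float):
        var_i = se2 / n_obs_i + su2
        w = 1.0 / var_i
        XtW = Xo.T * w
        beta = np.linalg.solve(XtW @ Xo, XtW @ yo)
        resid = yo - Xo @ beta
        m2ll = (
            df_within * np.log(se2)
            + ssw / se2
            + np.sum(np.log(n_obs_i * var_i))
            + np.sum(resid**2 / var_i)
            + N * np.log(2.0 * np.pi)
        )
        return m2ll, beta, XtW

    se2_0 = max(ssw / df_within, 1e-8)
    resid0 = yo - Xo @ np.linalg.lstsq(Xo, yo, rcond=None)[0]
    su2_0 = max(float(np.var(resid0)) - se2_0 / float(n_obs_i.mean()), 1e-4)

    def nll(params):
        se2, su2 = np.exp(2.0 * params)
        return 0.5 * profile(se2, su2)[0]

    res = minimize(
        nll,
        x0=0.5 * np.log([se2_0, su2_0]),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 600},
    )
    se2, su2 = np.exp(2.0 * res.x)
    m2ll, beta, XtW = profile(se2, su2)
    cov_beta = np.linalg.inv(XtW @ Xo)
    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma_u=float(np.sqrt(su2)),
        sigma_e=float(np.sqrt(se2)),
        loglik=float(-0.5 * m2ll),
        converged=bool(res.success),
        n_obs=N,
        n_persons=int(present.sum()),
    )


# ---------------------------------------------------------------------------
# probit consumption part

@dataclass
class ProbitFit:
    """ML fit (Gauss-Hermite) of P(consume) = Phi(x_i gamma + u_i)."""

    gamma: np.ndarray
    cov_gamma: np.ndarray
    sigma_u: float
    loglik: float
    converged: bool
    n_obs: int


def _gh_nodes(n_quad: int):
    t, w = np.polynomial.hermite_e.hermegauss(n_quad)
    return t, w / np.sqrt(2.0 * np.pi)


def fit_probit_random_intercept(y, person, X_person, n_quad: int = 21) -> ProbitFit:
    """Random-intercept probit by marginal ML over Gauss-Hermite nodes.

    With person-level covariates, each person contributes through the
    sufficient pair (number of recalls, number with consumption).
    """
    y = np.asarray(y, dtype=float)
    person = np.asarray(person, dtype=int)
    Xp = np.asarray(X_person, dtype=float)
    G = Xp.shape[0]
    n_i = np.bincount(person, minlength=G).astype(float)
    k_i = np.bincount(person, weights=y, minlength=G)
    present = n_i > 0
    Xo, n_o, k_o = Xp[present], n_i[present], k_i[present]
    t, w = _gh_nodes(n_quad)

    def nll(params):
        gamma, log_s = params[:-1], params[-1]
        s = np.exp(log_s)
        eta = Xo @ gamma
        z = eta[:, None] + s * t[None, :]
        p = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)
        logl = k_o[:, None] * np.log(p) + (n_o - k_o)[:, None] * np.log1p(-p)
        m = logl.max(axis=1, keepdims=True)
        lik = np.exp(logl - m) @ w
        return -float(np.sum(np.log(lik) + m[:, 0]))

    p_marg = float(np.clip(k_o.sum() / n_o.sum(), 1e-4, 1 - 1e-4))
    x0 = np.zeros(Xp.shape[1] + 1)
    x0[0] = norm.ppf(p_marg)
    x0[-1] = np.log(0.8)
    res = minimize(nll, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 300})
    cov = np.asarray(res.hess_inv)
    return ProbitFit(
        gamma=res.x[:-1],
        cov_gamma=cov[:-1, :-1],
        sigma_u=float(np.exp(res.x[-1])),
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_obs=int(n_o.sum()),
    )


# ---------------------------------------------------------------------------
# full measurement-error model

@dataclass
class TwoPartComponentModel:
    name: str
    episodic: bool
    lam: float
    amount: LMMFit
    prob: ProbitFit | None = None


@dataclass
class MeasurementErrorFit:
    """Fitted two-part models plus the cross-part random-effect covariance.

    ``part_names`` orders the random-effect vector: one "amount" entry per
    component and one "prob" entry per episodic component. ``X_person`` is
    the person-level covariate design shared by all parts, aligned with
    ``person_id``.
    """

    models: dict[str, TwoPartComponentModel]
    Sigma_u: np.ndarray
    part_names: list[tuple[str, str]]
    X_person: np.ndarray
    design_names: list[str]
    person_id: np.ndarray
    report: dict = field(default_factory=dict)

    @property
    def components(self) -> list[str]:
        return list(self.models)

    def to_json(self, path) -> None:
        """Serialize the fit (parameters, covariance structure, design)."""
        import json

        def lmm(f: LMMFit) -> dict:
            return {
                "beta": f.beta.tolist(),
                "cov_beta": f.cov_beta.tolist(),
                "sigma_u": f.sigma_u,
                "sigma_e": f.sigma_e,
                "loglik": f.loglik,
                "converged": f.converged,
                "n_obs": f.n_obs,
                "n_persons": f.n_persons,
            }

        payload = {
            "models": {
                name: {
                    "episodic": m.episodic,
                    "lam": m.lam,
                    "amount": lmm(m.amount),
                    "prob": None
                    if m.prob is None
                    else {
                        "gamma": m.prob.gamma.tolist(),
                        "cov_gamma": np.asarray(m.prob.cov_gamma).tolist(),
                        "sigma_u": m.prob.sigma_u,
                        "loglik": m.prob.loglik,
                        "converged": m.prob.converged,
                        "n_obs": m.prob.n_obs,
                    },
                }
                for name, m in self.models.items()
            },
            "Sigma_u": self.Sigma_u.tolist(),
            "part_names": [list(p) for p in self.part_names],
            "X_person": self.X_person.tolist(),
            "design_names": self.design_names,
            "person_id": np.asarray(self.person_id).tolist(),
            "report": self.report,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MeasurementErrorFit":
        import json

        with open(path) as fh:
            raw = json.load(fh)

        def lmm(d: dict) -> LMMFit:
            return LMMFit(
                beta=np.asarray(d["beta"]),
                cov_beta=np.asarray(d["cov_beta"]),
                sigma_u=d["sigma_u"],
                sigma_e=d["sigma_e"],
                loglik=d["loglik"],
                converged=d["converged"],
                n_obs=d["n_obs"],
                n_persons=d["n_persons"],
            )

        models = {}
        for name, m in raw["models"].items():
            prob = None
            if m["prob"] is not None:
                p = m["prob"]
                prob = ProbitFit(
                    gamma=np.asarray(p["gamma"]),
                    cov_gamma=np.asarray(p["cov_gamma"]),
                    sigma_u=p["sigma_u"],
                    loglik=p["loglik"],
                    converged=p["converged"],
                    n_obs=p["n_obs"],
                )
            models[name] = TwoPartComponentModel(
                name, m["episodic"], m["lam"], lmm(m["amount"]), prob
            )
        return cls(
            models=models,
            Sigma_u=np.asarray(raw["Sigma_u"]),
            part_names=[tuple(p) for p in raw["part_names"]],
            X_person=np.asarray(raw["X_person"]),
            design_names=raw["design_names"],
            person_id=np.asarray(raw["person_id"]),
            report=raw["report"],
        )


def _pick_lambda(y_pos, person, Xp, lambda_grid) -> tuple[float, LMMFit]:
    """Profile likelihood over the Box-Cox grid (Jacobian-adjusted)."""
    best = None
    log_jac = float(np.sum(np.log(y_pos)))
    for lam in lambda_grid:
        fit = fit_random_intercept_lmm(boxcox(y_pos, lam), person, Xp)
        score = fit.loglik + (lam - 1.0) * log_jac
        # ties broken toward 1/3
        key = (round(score, 8), -abs(lam - 1.0 / 3.0))
        if best is None or key > best[0]:
            best = (key, lam, fit)
    return best[1], best[2]


def fit_measurement_error_model(
    recalls: pd.DataFrame,
    X_person: np.ndarray,
    person_id: np.ndarray,
    design_names: Sequence[str] | None = None,
    components: Sequence[str] | None = None,
    episodic: Sequence[str] | None = None,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    n_quad: int = 21,
) -> MeasurementErrorFit:
    """Fit the multivariate measurement-error model to a recall table.

    ``X_person`` is the person-level covariate design (one row per person in
    ``person_id`` order; typically from :func:`hefi_cvd.design.covariate_design`
    including the urine-predicted sodium). Components default to every recall
    column except identifiers; a component is treated as episodic when it has
    zero-valued recalls (override with ``episodic``).
    """
    person_id = np.asarray(person_id)
    pos = pd.Series(np.arange(len(person_id)), index=person_id)
    person = pos.loc[recalls["person_id"]].to_numpy()
    if components is None:
        components = [c for c in recalls.columns if c not in ("person_id", "recall_no")]
    models: dict[str, TwoPartComponentModel] = {}
    blups: list[np.ndarray] = []
    sigmas: list[float] = []
    part_names: list[tuple[str, str]] = []
    G = X_person.shape[0]

    for name in components:
        y = recalls[name].to_numpy(float)
        consumed = y > 0
        if not consumed.any():
            raise ValueError(f"component {name!r} is all-zero")
        is_episodic = (name in episodic) if episodic is not None else bool(
            (~consumed).mean() > 0.01
        )
        prob_fit = None
        if is_episodic:
            prob_fit = fit_probit_random_intercept(
                consumed.astype(float), person, X_person, n_quad=n_quad
            )
            part_names.append((name, "prob"))
            sigmas.append(prob_fit.sigma_u)
            blups.append(
                _probit_posterior_mean(
                    consumed.astype(float), person, X_person, prob_fit, n_quad
                )
            )
        lam, amount_fit = _pick_lambda(
            y[consumed], person[consumed], X_person, lambda_grid
        )
        part_names.append((name, "amount"))
        sigmas.append(amount_fit.sigma_u)
        blups.append(
            _amount_blup(
                boxcox(y[consumed], lam), person[consumed], X_person, amount_fit, G
            )
        )
        models[name] = TwoPartComponentModel(name, is_episodic, lam, amount_fit, prob_fit)

    B = np.column_stack(blups)
    Sigma_u = _assemble_sigma(B, np.asarray(sigmas))
    report = {
        "converged": all(
            m.amount.converged and (m.prob is None or m.prob.converged)
            for m in models.values()
        ),
        "n_parts": len(part_names),
    }
    return MeasurementErrorFit(
        models=models,
        Sigma_u=Sigma_u,
        part_names=part_names,
        X_person=np.asarray(X_person, float),
        design_names=list(design_names) if design_names is not None else [],
        person_id=person_id,
        report=report,
    )


def _amount_blup(t, person, Xp, fit: LMMFit, G: int) -> np.ndarray:
    n_i, tbar, _, present = _person_stats(t, person, G)
    resid = np.where(present, tbar - Xp @ fit.beta, 0.0)
    shrink = fit.sigma_u**2 / (fit.sigma_u**2 + fit.sigma_e**2 / np.maximum(n_i, 1.0))
    return np.where(present, shrink * resid, 0.0)


def _probit_posterior_mean(y, person, Xp, fit: ProbitFit, n_quad: int) -> np.ndarray:
    G = Xp.shape[0]
    n_i = np.bincount(person, minlength=G).astype(float)
    k_i = np.bincount(person, weights=y, minlength=G)
    t, w = _gh_nodes(n_quad)
    eta = Xp @ fit.gamma
    z = eta[:, None] + fit.sigma_u * t[None, :]
    p = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)
    logl = k_i[:, None] * np.log(p) + (n_i - k_i)[:, None] * np.log1p(-p)
    m = logl.max(axis=1, keepdims=True)
    lik = np.exp(logl - m)
    num = (lik * t[None, :]) @ w
    den = lik @ w
    out = fit.sigma_u * num / den
    return np.where(n_i > 0, out, 0.0)


def _assemble_sigma(B: np.ndarray, model_sds: np.ndarray) -> np.ndarray:
    """Cross-part covariance: correlation of the empirical-Bayes predictions,
    rescaled so each part's SD matches its model estimate (the
    shrinkage-inflation correction), projected to positive semi-definite."""
    K = B.shape[1]
    sds = B.std(axis=0)
    C = np.cov(B.T) if K > 1 else np.array([[sds[0] ** 2]])
    C = np.atleast_2d(C)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = C / np.outer(sds, sds)
    R[~np.isfinite(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    R = vecs @ np.diag(np.clip(vals, 1e-6, None)) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    return np.outer(model_sds, model_sds) * R


# ---------------------------------------------------------------------------
# conditional Monte Carlo draws

@dataclass
class UsualIntakeDraws:
    """M Monte-Carlo draws of usual intake per person and component."""

    person_id: np.ndarray
    amounts: dict[str, np.ndarray]  # component -> (n_persons, M)
    M: int
    seed: int | None

    def mean_amounts(self) -> pd.DataFrame:
        out = {"person_id": self.person_id}
        out.update({name: a.mean(axis=1) for name, a in self.amounts.items()})
        return pd.DataFrame(out)


def _conditional_moments(
    fit: MeasurementErrorFit, recalls: pd.DataFrame, conditional: bool
):
    """Per-person Gaussian pseudo-observations (m, tau) for each random-effect
    part: exact conjugate form for amount parts, Laplace approximation for the
    probit parts. tau = 0 marks an uninformative part (or marginal draws)."""
    G = len(fit.person_id)
    K = len(fit.part_names)
    m = np.zeros((G, K))
    tau = np.zeros((G, K))
    if not conditional:
        return m, tau
    pos = pd.Series(np.arange(G), index=fit.person_id)
    person = pos.loc[recalls["person_id"]].to_numpy()
    for k, (name, part) in enumerate(fit.part_names):
        model = fit.models[name]
        y = recalls[name].to_numpy(float)
        if part == "amount":
            consumed = y > 0
            t = boxcox(y[consumed], model.lam)
            n_i, tbar, _, present = _person_stats(t, person[consumed], G)
            resid = np.where(present, tbar - fit.X_person @ model.amount.beta, 0.0)
            m[:, k] = resid
            tau[:, k] = n_i / max(model.amount.sigma_e**2, 1e-10)
        else:
            consumed = (y > 0).astype(float)
            n_i = np.bincount(person, minlength=G).astype(float)
            k_i = np.bincount(person, weights=consumed, minlength=G)
            eta = fit.X_person @ model.prob.gamma
            s2 = model.prob.sigma_u**2
            u = np.zeros(G)
            for _ in range(25):  # Newton on the per-person posterior mode
                z = eta + u
                pdf, cdf = norm.pdf(z), np.clip(ndtr(z), 1e-12, 1 - 1e-12)
                r1, r0 = pdf / cdf, pdf / (1.0 - cdf)
                grad = k_i * r1 - (n_i - k_i) * r0 - u / s2
                hess = -k_i * r1 * (z + r1) - (n_i - k_i) * r0 * (r0 - z) - 1.0 / s2
                hess = np.minimum(hess, -1e-6)
                step = np.clip(grad / -hess, -2.0, 2.0)
                u = u + step
                if np.max(np.abs(step)) < 1e-9:
                    break
            post_prec = -hess
            tk = np.maximum(post_prec - 1.0 / s2, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                mk = np.where(tk > 1e-8, u * post_prec / np.maximum(tk, 1e-8), 0.0)
            m[:, k] = mk
            tau[:, k] = np.where(tk > 1e-8, tk, 0.0)
            tau[n_i == 0, k] = 0.0
    return m, tau


def draw_usual_intakes(
    fit: MeasurementErrorFit,
    recalls: pd.DataFrame,
    M: int = 1000,
    seed: int | None = None,
    conditional: bool = True,
) -> UsualIntakeDraws:
    """Monte-Carlo draws of usual intakes for every person.

    Random-effect vectors are drawn from each person's conditional
    distribution given their recalls (``conditional=False`` draws from the
    covariate-only marginal instead). Per draw, usual intake is the
    consumption probability (episodic parts) times the bias-corrected
    back-transformed amount.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible draws")
    rng = np.random.default_rng(seed)
    G = len(fit.person_id)
    K = len(fit.part_names)
    m, tau = _conditional_moments(fit, recalls, conditional)

    prec_prior = np.linalg.inv(
        fit.Sigma_u + 1e-10 * np.eye(K) * np.trace(fit.Sigma_u) / K
    )
    A = np.broadcast_to(prec_prior, (G, K, K)).copy()
    A[:, np.arange(K), np.arange(K)] += tau
    cov = np.linalg.inv(A)
    mu = np.einsum("nij,nj->ni", cov, tau * m)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(K))
    z = rng.standard_normal((G, M, K))
    u = mu[:, None, :] + np.einsum("nkj,nmj->nmk", L, z)

    k_of = {pn: k for k, pn in enumerate(fit.part_names)}
    amounts: dict[str, np.ndarray] = {}
    for name, model in fit.models.items():
        xb = fit.X_person @ model.amount.beta
        t_star = xb[:, None] + u[:, :, k_of[(name, "amount")]]
        a = inverse_boxcox_corrected(t_star, model.lam, model.amount.sigma_e**2)
        if model.episodic:
            eta = fit.X_person @ model.prob.gamma
            p = ndtr(eta[:, None] + u[:, :, k_of[(name, "prob")]])
            a = p * a
        amounts[name] = a
    return UsualIntakeDraws(person_id=fit.person_id, amounts=amounts, M=M, seed=seed)


def usual_hefi_from_draws(
    draws: UsualIntakeDraws,
    sodium_mg: np.ndarray,
    natural_sugar_factors: Mapping[str, float] | None = None,
    standards=None,
) -> pd.DataFrame:
    """Score the HEFI-2019 on every usual-intake draw and average per person.

    ``sodium_mg`` is the per-person urine-predicted sodium (error-free
    covariate, constant across draws). Returns one row per person with the
    mean usual component amounts, mean usual HEFI component scores and the
    mean usual total (``usual_hefi``) averaged across simulations.
    """
    G, M = len(draws.person_id), draws.M
    sodium = np.asarray(sodium_mg, dtype=float)
    totals = np.zeros((G, M))
    comp_sums: dict[str, np.ndarray] = {}
    for mdx in range(M):
        profile = pd.DataFrame(
            {name: a[:, mdx] for name, a in draws.amounts.items()}
        )
        inputs = hefi_inputs_from_amounts(profile, sodium, natural_sugar_factors)
        scored = score_hefi(inputs, standards)
        totals[:, mdx] = scored["total"].to_numpy()
        for st_name in scored.columns:
            if st_name.startswith(("ratio_", "flag_")) or st_name == "total":
                continue
            comp_sums[st_name] = comp_sums.get(st_name, 0.0) + scored[st_name].to_numpy()
    out = {"person_id": draws.person_id}
    out.update({name: a.mean(axis=1) for name, a in draws.amounts.items()})
    out.update({f"score_{k}": v / M for k, v in comp_sums.items()})
    out["usual_hefi"] = totals.mean(axis=1)
    out["usual_hefi_mc_se"] = totals.std(axis=1, ddof=1) / np.sqrt(M)
    return pd.DataFrame(out)


def usual_score_percentiles(
    scores, percentiles: Sequence[float] = DEFAULT_PERCENTILES
) -> pd.DataFrame:
    """Empirical percentiles of the mean usual HEFI score distribution."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores provided")
    if scores.size < 100:
        raise ValueError("need at least 100 persons for stable percentiles")
    values = np.percentile(scores, list(percentiles))
    return pd.DataFrame({"percentile": list(percentiles), "score": values})
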