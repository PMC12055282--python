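"""Maximum-likelihood fitting of the duration-adjusted occurrence model.

The free parameters are the fixed effects beta, the random-intercept SD
sigma, and the per-second baseline probability B that enters through the
duration offset.  B is a likelihood-level parameter, not a GLMM coefficient:
the canonical estimator profiles it in an outer one-dimensional search
(``profile_B``), refitting (beta, sigma) at each candidate B.  For the
likelihood-ratio test, where only maximized log-likelihoods matter, full and
reduced models are maximized jointly over (beta, log sigma, logit B), which
reaches the same maximum as the profile at a fraction of the cost.

sigma is parameterized internally as log(sigma); the sigma = 0 boundary is
handled by an explicit boundary fit (a plain offset logistic regression) and
wins whenever the interior optimum does not beat it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .data import Dataset, FittedModel, ModelParams, ModelSpec
from .model import ModelMatrix, _bernoulli_loglik, _marginal_core, build_matrix, offset_term

__all__ = ["fit_inner", "profile_B", "lrt_activity", "collapse_periods", "LRTResult"]

_LOG_SIGMA_LO = np.log(1e-3)
_LOG_SIGMA_HI = np.log(10.0)
_SEPARATION_THRESHOLD = 15.0


# ---------------------------------------------------------------------------
# sigma = 0 boundary: plain logistic regression with offset
# ---------------------------------------------------------------------------


def _logistic_offset_fit(X, y, off, max_iter=100, tol=1e-12):
    """Newton-Raphson logistic regression with a fixed offset.

    Returns (beta, loglik, cov, separated).  A tiny ridge keeps the Hessian
    invertible; runaway coefficients (|beta| > threshold) mark separation.
    """
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    separated = False
    for _ in range(max_iter):
        eta = X @ beta + off
        mu = expit(eta)
        w = mu * (1.0 - mu)
        g = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X + 1e-10 * np.eye(p_dim)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(beta)) > 2 * _SEPARATION_THRESHOLD:
            separated = True
            break
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta + off
    ll = float(np.sum(_bernoulli_loglik(eta, y)))
    mu = expit(eta)
    H = (X * (mu * (1 - mu))[:, None]).T @ X + 1e-10 * np.eye(p_dim)
    cov = np.linalg.inv(H)
    return beta, ll, cov, separated


# ---------------------------------------------------------------------------
# internal optimizer on arrays
# ---------------------------------------------------------------------------


@dataclass
class _ArrayFit:
    beta: np.ndarray
    sigma: float
    B: float
    loglik: float
    converged: bool
    boundary_sigma: bool
    grad_norm: float
    se_beta: np.ndarray | None = None
    messages: list = field(default_factory=list)


def _minimize(fun, x0, bounds, loose: bool = False):
    # loose mode is for replicate refits (bootstrap, leave-one-out) where
    # percentile/range summaries do not need the strict optimum used by the
    # nesting and profile-consistency guarantees
    options = (
        {"ftol": 2.2e-9, "gtol": 1e-5, "maxiter": 200}
        if loose
        else {"ftol": 1e-12, "gtol": 1e-7, "maxiter": 300}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return optimize.minimize(
            fun, x0, jac=True, method="L-BFGS-B", bounds=bounds, options=options
        )


def _fit_arrays(
    mat: ModelMatrix,
    B: float,
    nodes: int = 30,
    start: tuple | None = None,
    se: bool = False,
    loose: bool = False,
) -> _ArrayFit:
    """Maximize the marginal log-likelihood over (beta, log sigma) at fixed B."""
    p_dim = mat.X.shape[1]
    off = offset_term(B, mat.T)

    # boundary fit (sigma = 0): offset logistic regression
    beta0, ll0, cov0, separated0 = _logistic_offset_fit(mat.X, mat.y, off)

    mode_state: dict = {}

    def objective(theta):
        beta, log_sigma = theta[:p_dim], theta[p_dim]
        ll, dbeta, dlogsigma, _ = _marginal_core(
            beta, float(np.exp(log_sigma)), B, mat, nodes, want_grad=True,
            state=mode_state,
        )
        return -ll, -np.concatenate([dbeta, [dlogsigma]])

    if start is not None:
        beta_s = np.asarray(start[0], dtype=float)
        sigma_s = max(float(start[1]), 2e-3)
        starts = [np.concatenate([beta_s, [np.log(sigma_s)]])]
    else:
        bs = np.clip(beta0, -_SEPARATION_THRESHOLD, _SEPARATION_THRESHOLD)
        starts = [
            np.concatenate([bs, [np.log(0.1)]]),
            np.concatenate([bs, [np.log(1.0)]]),
        ]

    bounds = [(None, None)] * p_dim + [(_LOG_SIGMA_LO, _LOG_SIGMA_HI)]
    best = None
    for x0 in starts:
        res = _minimize(objective, x0, bounds, loose=loose)
        cand = (res.fun, np.exp(res.x[p_dim]), res)
        if best is None or cand[0] < best[0] - 1e-10 or (
            abs(cand[0] - best[0]) <= 1e-10 and cand[1] < best[1]
        ):
            best = cand
    res = best[2]
    beta_hat = res.x[:p_dim]
    sigma_hat = float(np.exp(res.x[p_dim]))
    ll_hat = -float(res.fun)
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm < 1e-4
    boundary = False
    messages: list = []

    # boundary comparison: plain logistic wins if it matches or beats the
    # interior optimum (sigma indistinguishable from 0)
    if ll0 >= ll_hat - 1e-8 or sigma_hat <= np.exp(_LOG_SIGMA_LO) * 1.0001:
        if ll0 >= ll_hat - 1e-8:
            beta_hat, ll_hat = beta0, ll0
        sigma_hat = 0.0
        boundary = True
        converged = True and not separated0 if ll0 >= ll_hat - 1e-8 else converged
        messages.append("sigma at boundary (0): variance not distinguishable from zero")

    if mat.n_individuals < 2:
        boundary = True
        converged = False
        messages.append("single individual: random-intercept SD not identifiable")

    fit = _ArrayFit(
        beta=beta_hat,
        sigma=sigma_hat,
        B=B,
        loglik=ll_hat,
        converged=converged,
        boundary_sigma=boundary,
        grad_norm=grad_norm,
        messages=messages,
    )
    if se:
        fit.se_beta = _se_beta(fit, mat, nodes, cov0)
    return fit


def _se_beta(
    fit: _ArrayFit, mat: ModelMatrix, nodes: int, cov0: np.ndarray, free_B: bool = False
) -> np.ndarray:
    """Standard errors from the observed information at the optimum.

    With ``free_B=True`` (B was estimated, not held fixed) the information is
    taken over (beta, sigma, B) jointly, so the reported SEs propagate the
    uncertainty in B — without this the intercept SE is badly optimistic,
    because B and the intercept are strongly correlated.
    """
    p_dim = mat.X.shape[1]
    if fit.boundary_sigma or fit.sigma <= 0:
        if not free_B:
            return np.sqrt(np.clip(np.diag(cov0), 0, np.inf))
        theta = np.concatenate([fit.beta, [fit.B]])

        def nll(t):
            B = float(np.clip(t[p_dim], 1e-6, 1 - 1e-6))
            return -_marginal_core(t[:p_dim], 0.0, B, mat, nodes)

    elif free_B:
        theta = np.concatenate([fit.beta, [fit.sigma, fit.B]])

        def nll(t):
            sigma = max(float(t[p_dim]), 1e-8)
            B = float(np.clip(t[p_dim + 1], 1e-6, 1 - 1e-6))
            return -_marginal_core(t[:p_dim], sigma, B, mat, nodes)

    else:
        theta = np.concatenate([fit.beta, [fit.sigma]])

        def nll(t):
            sigma = max(float(t[p_dim]), 1e-8)
            return -_marginal_core(t[:p_dim], sigma, fit.B, mat, nodes)

    from statsmodels.tools.numdiff import approx_hess1

    H = approx_hess1(theta, nll)
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov)[:p_dim])
            if np.all(np.isfinite(se)):
                return se
        except np.linalg.LinAlgError:
            pass
    # fall back to beta-only information at fixed sigma
    Hb = approx_hess1(fit.beta, lambda b: -_marginal_core(b, fit.sigma, fit.B, mat, nodes))
    return np.sqrt(np.clip(np.diag(np.linalg.inv(Hb)), 0, np.inf))


def _joint_fit(
    mat: ModelMatrix,
    nodes: int = 30,
    B_bounds: tuple = (1e-3, 0.999),
    starts: list | None = None,
) -> _ArrayFit:
    """Maximize over (beta, log sigma, logit B) jointly.

    Reaches the same maximum as the outer profile over B; used where only
    the maximized log-likelihood is needed (likelihood-ratio tests).
    """
    p_dim = mat.X.shape[1]
    lb, ub = logit(B_bounds[0]), logit(B_bounds[1])

    rate = float(np.clip(np.mean(mat.y), 1.0 / (mat.n_obs + 1), 1 - 1.0 / (mat.n_obs + 1)))
    B0 = float(np.clip(1.0 - (1.0 - rate) ** (1.0 / np.mean(mat.T)), *B_bounds))
    beta0, _, _, _ = _logistic_offset_fit(mat.X, mat.y, offset_term(B0, mat.T))
    beta0 = np.clip(beta0, -_SEPARATION_THRESHOLD, _SEPARATION_THRESHOLD)

    mode_state: dict = {}

    def objective(theta):
        beta, log_sigma, lB = theta[:p_dim], theta[p_dim], theta[p_dim + 1]
        B = float(expit(lB))
        ll, dbeta, dlogsigma, dlogitB = _marginal_core(
            beta, float(np.exp(log_sigma)), B, mat, nodes, want_grad=True,
            state=mode_state,
        )
        return -ll, -np.concatenate([dbeta, [dlogsigma, dlogitB]])

    default_starts = [
        np.concatenate([beta0, [np.log(0.5), logit(B0)]]),
        np.concatenate([beta0, [np.log(1.0), logit(np.clip(B0 * 2.5, *B_bounds))]]),
    ]
    if starts:
        default_starts = [np.asarray(s, float) for s in starts] + default_starts
    bounds = [(None, None)] * p_dim + [(_LOG_SIGMA_LO, _LOG_SIGMA_HI), (lb, ub)]

    best = None
    for x0 in default_starts:
        res = _minimize(objective, x0, bounds)
        if best is None or res.fun < best.fun:
            best = res
    res = best
    B_hat = float(expit(res.x[p_dim + 1]))
    sigma_hat = float(np.exp(res.x[p_dim]))
    ll = -float(res.fun)

    # the sigma = 0 boundary must be checked at the profiled-out B too
    inner0 = _fit_arrays(mat, B_hat, nodes)
    if inner0.loglik > ll:
        return inner0
    grad_norm = float(np.max(np.abs(res.jac)))
    return _ArrayFit(
        beta=res.x[:p_dim],
        sigma=sigma_hat if sigma_hat > np.exp(_LOG_SIGMA_LO) * 1.0001 else 0.0,
        B=B_hat,
        loglik=ll,
        converged=bool(res.success) or grad_norm < 1e-4,
        boundary_sigma=sigma_hat <= np.exp(_LOG_SIGMA_LO) * 1.0001,
        grad_norm=grad_norm,
    )


def _as_fitted(fit: _ArrayFit, mat: ModelMatrix, spec: ModelSpec, B_fixed: bool) -> FittedModel:
    separation = bool(np.any(np.abs(fit.beta) > _SEPARATION_THRESHOLD))
    if separation:
        fit.messages.append("possible separation: |beta| exceeds 15 on the logit scale")
    se = fit.se_beta if fit.se_beta is not None else np.full(fit.beta.size, np.nan)
    return FittedModel(
        params=ModelParams(beta=tuple(fit.beta), sigma=fit.sigma, B=fit.B),
        se_beta=np.asarray(se, dtype=float),
        loglik=fit.loglik,
        converged=fit.converged,
        boundary_sigma=fit.boundary_sigma,
        B_fixed=B_fixed,
        n_obs=mat.n_obs,
        n_individuals=mat.n_individuals,
        model_spec=spec,
        separation=separation,
        messages=list(fit.messages),
    )


def _degenerate_fit(mat: ModelMatrix, spec: ModelSpec, B: float, B_fixed: bool) -> FittedModel:
    """All-zero or all-one responses: no interior MLE exists."""
    n = mat.n_obs
    rate = (mat.y.sum() + 0.5) / (n + 1.0)
    beta = np.zeros(mat.X.shape[1])
    beta[0] = logit(rate) - float(np.mean(offset_term(B, mat.T)))
    eta = mat.X @ beta + offset_term(B, mat.T)
    ll = float(np.sum(_bernoulli_loglik(eta, mat.y)))
    return FittedModel(
        params=ModelParams(beta=tuple(beta), sigma=0.0, B=B),
        se_beta=np.full(beta.size, np.nan),
        loglik=ll,
        converged=False,
        boundary_sigma=True,
        B_fixed=B_fixed,
        n_obs=n,
        n_individuals=mat.n_individuals,
        model_spec=spec,
        separation=True,
        messages=["degenerate responses (all 0 or all 1): boundary pseudo-fit returned"],
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def fit_inner(
    data: Dataset,
    spec: ModelSpec,
    B: float,
    *,
    nodes: int = 30,
    start: tuple | None = None,
    se: bool = True,
) -> FittedModel:
    """Fit (beta, sigma) by maximum marginal likelihood at a fixed B.

    Quasi-Newton (L-BFGS-B) from multiple starts: beta from an offset
    logistic regression without random effect, sigma from {0.1, 1}; ties
    broken by highest log-likelihood then smallest sigma.  Standard errors
    come from the observed information (inverse negative Hessian).
    """
    if not (0.0 < B < 1.0):
        raise ValueError(f"B must lie strictly inside (0, 1), got {B}")
    mat = build_matrix(data, spec)
    if mat.y.min() == mat.y.max():
        return _degenerate_fit(mat, spec, B, B_fixed=True)
    fit = _fit_arrays(mat, B, nodes=nodes, start=start, se=se)
    return _as_fitted(fit, mat, spec, B_fixed=True)


def profile_B(
    data: Dataset,
    spec: ModelSpec,
    bounds: tuple = (0.001, 0.999),
    *,
    nodes: int = 30,
    n_grid: int = 9,
    se: bool = True,
    return_trace: bool = False,
):
    """Estimate B by maximizing the profile log-likelihood L*(B).

    L*(B) = max over (beta, sigma) of the marginal log-likelihood with the
    offset computed at B.  A coarse grid on the logit(B) scale (``n_grid``
    points, at least 9) brackets the maximum; Brent-style bounded
    minimization then refines it.  Inner fits are warm-started along the
    search path.  Returns ``(B_hat, FittedModel)``; with
    ``return_trace=True`` also the list of (B, L*(B)) pairs visited.
    """
    lo, hi = bounds
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"need 0 < lo < hi < 1, got {bounds}")
    n_grid = max(int(n_grid), 9)
    mat = build_matrix(data, spec)
    if mat.y.min() == mat.y.max():
        fitted = _degenerate_fit(mat, spec, float(np.sqrt(lo * hi)), B_fixed=False)
        return (fitted.params.B, fitted, []) if return_trace else (fitted.params.B, fitted)

    trace: list = []
    state = {"start": None}

    def profile_ll(lB: float) -> float:
        B = float(expit(lB))
        fit = _fit_arrays(mat, B, nodes=nodes, start=state["start"])
        state["start"] = (fit.beta, max(fit.sigma, 0.05))
        trace.append((B, fit.loglik))
        return fit.loglik

    grid = np.linspace(logit(lo), logit(hi), n_grid)
    grid_ll = np.array([profile_ll(lB) for lB in grid])
    k = int(np.argmax(grid_ll))

    flat = bool(grid_ll.max() - grid_ll.min() < 1e-6) or bool(np.ptp(mat.T) == 0)
    messages = []
    if flat:
        messages.append(
            "flat profile: B and the intercept are jointly unidentified "
            "(constant durations make the offset a constant)"
        )
    lo_k = grid[max(k - 1, 0)]
    hi_k = grid[min(k + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda lB: -profile_ll(lB),
        bounds=(lo_k, hi_k),
        method="bounded",
        options={"xatol": 1e-3},
    )
    lB_hat = float(res.x) if -res.fun >= grid_ll[k] else float(grid[k])
    B_hat = float(expit(lB_hat))

    fit = _fit_arrays(mat, B_hat, nodes=nodes, start=state["start"])
    if fit.loglik < grid_ll[k] - 1e-8:  # refinement must not lose to the grid
        B_hat = float(expit(grid[k]))
        fit = _fit_arrays(mat, B_hat, nodes=nodes, start=state["start"])
    if se:
        _, _, cov0, _ = _logistic_offset_fit(mat.X, mat.y, offset_term(B_hat, mat.T))
        fit.se_beta = _se_beta(fit, mat, nodes, cov0, free_B=not flat)
    fit.messages.extend(messages)
    if B_hat <= lo * 1.02 or B_hat >= hi * 0.98:
        fit.messages.append(
            "profile maximum at the search boundary: B may be confounded with the intercept"
        )
    fitted = _as_fitted(fit, mat, spec, B_fixed=False)
    return (B_hat, fitted, trace) if return_trace else (B_hat, fitted)


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float
    full: FittedModel
    reduced: FittedModel

    def __iter__(self):
        return iter((self.chi2, self.df, self.p))


def lrt_activity(
    data: Dataset,
    spec: ModelSpec,
    *,
    nodes: int = 30,
    refit_B: bool = True,
    B: float | None = None,
) -> LRTResult:
    """Likelihood-ratio test for the overall activity-type effect.

    Compares the full model against the reduced model with activity dropped.
    By default B is re-optimized in both models, so the test compares true
    profile maxima; pass ``refit_B=False`` with an explicit ``B`` to hold
    the offset fixed in both fits (sensitivity variant).  df = 2 (two
    activity contrasts), asserted against the design-matrix rank.
    """
    full_spec = ModelSpec(spec.behaviour, spec.period, include_activity=True)
    mat_full = build_matrix(data, full_spec)
    levels = np.unique(mat_full.X[:, 1] + 2 * mat_full.X[:, 2]).size
    if levels == 1:
        fit = (
            _joint_fit(mat_full, nodes=nodes)
            if refit_B and B is None
            else _fit_arrays(mat_full, B, nodes=nodes)
        )
        fitted = _as_fitted(fit, mat_full, full_spec, B_fixed=not refit_B)
        return LRTResult(chi2=0.0, df=2, p=1.0, full=fitted, reduced=fitted)

    rank_full = np.linalg.matrix_rank(mat_full.X)
    df = rank_full - 1
    assert df == 2, (
        f"activity design has rank {rank_full}; the three-level factor must "
        "contribute exactly 2 contrasts"
    )
    mat_red = build_matrix(data, full_spec.reduced())
    if mat_full.y.min() == mat_full.y.max():
        raise ValueError("degenerate responses (all 0 or all 1): LRT refused")

    if refit_B and B is None:
        red = _joint_fit(mat_red, nodes=nodes)
        # nest the reduced optimum into the full model's start list
        seed_start = np.concatenate(
            [[red.beta[0]], np.zeros(2), [np.log(max(red.sigma, 0.05)), logit(red.B)]]
        )
        full = _joint_fit(mat_full, nodes=nodes, starts=[seed_start])
        B_fixed = False
    else:
        if B is None:
            raise ValueError("refit_B=False requires an explicit B")
        red = _fit_arrays(mat_red, B, nodes=nodes)
        full = _fit_arrays(
            mat_full, B, nodes=nodes, start=(np.concatenate([[red.beta[0]], np.zeros(2)]), max(red.sigma, 0.05))
        )
        fallback = _fit_arrays(mat_full, B, nodes=nodes)
        if fallback.loglik > full.loglik:
            full = fallback
        B_fixed = True

    if not (full.converged and red.converged):
        raise RuntimeError("LRT refused: full or reduced model did not converge")
    chi2 = 2.0 * (full.loglik - red.loglik)
    if chi2 < 0.0:
        if chi2 < -1e-6:
            raise RuntimeError(
                f"nesting violated beyond tolerance (chi2 = {chi2:.3g}): optimizer failure"
            )
        chi2 = 0.0
    p = float(stats.chi2.sf(chi2, df))
    return LRTResult(
        chi2=float(chi2),
        df=int(df),
        p=p,
        full=_as_fitted(full, mat_full, full_spec, B_fixed=B_fixed),
        reduced=_as_fitted(red, mat_red, full_spec.reduced(), B_fixed=B_fixed),
    )


def collapse_periods(data: Dataset) -> Dataset:
    """Merge before/after windows of each event into one combined window.

    The combined response is the logical OR of the two windows and the
    combined duration their sum.  Events observed in a single window only
    are kept with that window (and counted in ``metadata['unpaired']``).
    Pairing requires an ``event_id`` column.
    """
    df = data.df
    if "event_id" not in df.columns:
        raise ValueError("collapse_periods requires an 'event_id' column to pair windows")
    if (df["period"] == "combined").any():
        raise ValueError("data already contain combined-period records")

    grouped = df.groupby(["event_id", "behaviour"], sort=True)
    rows = []
    unpaired = 0
    for (event_id, behaviour), g in grouped:
        if len(set(g["period"])) < len(g):
            raise ValueError(f"duplicate period rows for event {event_id!r}/{behaviour!r}")
        if len(g) == 1:
            unpaired += 1
        first = g.iloc[0]
        rows.append(
            {
                "individual_id": first["individual_id"],
                "site": first["site"],
                "activity": first["activity"],
                "period": "combined",
                "duration_s": g["duration_s"].sum(),
                "behaviour": behaviour,
                "occurred": int(g["occurred"].max()),
                "event_id": event_id,
            }
        )
    meta = dict(data.metadata)
    meta["unpaired"] = unpaired
    return Dataset(pd.DataFrame(rows), metadata=meta)
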