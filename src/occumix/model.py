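"""Probability machinery for the duration-adjusted occurrence model.

The model for a binary response y (did the behaviour occur at least once
while the individual was visible for T seconds?) is

    y ~ Bernoulli(p),   logit(p) = x'beta + u_i + logit(O(B, T)),

where u_i ~ Normal(0, sigma^2) is an individual random intercept and
O(B, T) = 1 - (1 - B)^T is the probability that a behaviour with constant
per-second occurrence probability B happens at least once in a window of T
seconds.  The offset logit(O) makes windows of different length comparable:
with beta = 0 and u = 0 the model probability is exactly O(B, T).

B is not known a priori; it is profiled by the fitting layer.  This module
only evaluates probabilities and (marginal) log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit, logsumexp, roots_hermite

from .data import Dataset, ModelParams, ModelSpec

__all__ = [
    "occurrence_offset_probability",
    "offset_term",
    "conditional_loglik",
    "marginal_loglik",
    "brute_force_marginal_loglik",
]

_LOG_SQRT_2 = 0.5 * np.log(2.0)


def _check_B(B) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    if np.any(B <= 0.0) or np.any(B >= 1.0):
        raise ValueError(f"B must lie strictly inside (0, 1), got {B}")
    return B


def occurrence_offset_probability(B, T, *, formula: str = "at_least_one"):
    """Probability O that the behaviour occurs at least once in T seconds.

    Parameters
    ----------
    B : float or array
        Per-second baseline occurrence probability, strictly in (0, 1).
    T : float or array
        Window duration in seconds, >= 0.  Integer in the study data; the
        closed form extends continuously to non-integer durations.
    formula : {"at_least_one", "printed"}
        "at_least_one" (default) evaluates ``O = 1 - (1 - B)**T``, the
        at-least-one-event probability under a per-second Bernoulli(B)
        process.  "printed" evaluates the literal expression ``B**T`` for
        auditing; it *decreases* with duration and cannot represent exposure.
    """
    B = _check_B(B)
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError(f"duration T must be >= 0, got {T}")
    if formula == "at_least_one":
        out = -np.expm1(T * np.log1p(-B))
    elif formula == "printed":
        out = np.exp(T * np.log(B))
    else:
        raise ValueError(f"unknown offset formula {formula!r}")
    return out if out.ndim else float(out)


def offset_term(B, T, *, formula: str = "at_least_one"):
    """Logit-scale duration offset, log(O / (1 - O)).

    Requires T >= 1 (an empty window gives O = 0 and an infinite offset).
    Evaluated in log space so it is finite for extreme B and T.
    """
    B = _check_B(B)
    T = np.asarray(T, dtype=float)
    if np.any(T < 1):
        raise ValueError(
            f"offset_term requires T >= 1 (O must be inside (0,1)); got T={T}"
        )
    if formula == "at_least_one":
        # 1-O = (1-B)^T; logit(O) = log(-expm1(T*log1p(-B))) - T*log1p(-B)
        log_1mO = T * np.log1p(-B)
        out = np.log(-np.expm1(log_1mO)) - log_1mO
    elif formula == "printed":
        log_O = T * np.log(B)
        out = log_O - np.log(-np.expm1(log_O))
    else:
        raise ValueError(f"unknown offset formula {formula!r}")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# internal array representation used by all likelihood code
# ---------------------------------------------------------------------------


@dataclass
class ModelMatrix:
    """Arrays for one (behaviour, period) model, sorted by individual."""

    X: np.ndarray           # (n, p) fixed-effect design
    y: np.ndarray           # (n,) 0/1 responses
    T: np.ndarray           # (n,) durations in seconds
    ind: np.ndarray         # (n,) individual codes 0..m-1, non-decreasing
    individual_ids: list    # length m, code -> original ID
    bounds: np.ndarray      # (m+1,) reduceat offsets per individual

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def group_sum(self, values: np.ndarray) -> np.ndarray:
        """Sum record-level values (n, ...) within individuals -> (m, ...)."""
        return np.add.reduceat(values, self.bounds[:-1], axis=0)


def replace_responses(mat: ModelMatrix, y: np.ndarray) -> ModelMatrix:
    """A copy of ``mat`` with new responses at the same design points."""
    return ModelMatrix(
        X=mat.X, y=np.asarray(y, dtype=float), T=mat.T, ind=mat.ind,
        individual_ids=mat.individual_ids, bounds=mat.bounds,
    )


def build_matrix(data: Dataset, spec: ModelSpec | None = None) -> ModelMatrix:
    """Build the design arrays for one model from a tidy dataset.

    If ``spec`` selects a (behaviour, period), only matching rows are used;
    with ``spec=None`` all rows enter (callers must pass homogeneous data).
    Activity is dummy coded with drumming as the reference level.
    """
    df = data.df
    include_activity = True
    if spec is not None:
        df = df[(df["behaviour"] == spec.behaviour) & (df["period"] == spec.period)]
        if df.empty:
            raise ValueError(f"no records match {spec}")
        include_activity = spec.include_activity
    ids = df["individual_id"].astype(str).to_numpy()
    uniq = sorted(set(ids))
    code = {v: i for i, v in enumerate(uniq)}
    ind = np.array([code[v] for v in ids])
    order = np.argsort(ind, kind="stable")

    activity = df["activity"].to_numpy()[order]
    n = len(df)
    if include_activity:
        X = np.column_stack(
            [
                np.ones(n),
                (activity == "stone_and_drum").astype(float),
                (activity == "stone").astype(float),
            ]
        )
    else:
        X = np.ones((n, 1))
    y = df["occurred"].to_numpy(dtype=float)[order]
    T = df["duration_s"].to_numpy(dtype=float)[order]
    ind = ind[order]
    bounds = np.searchsorted(ind, np.arange(len(uniq) + 1))
    return ModelMatrix(X=X, y=y, T=T, ind=ind, individual_ids=uniq, bounds=bounds)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Elementwise log P(y | p=expit(eta)), numerically stable."""
    # y*log p + (1-y)*log(1-p) = log_expit(eta) for y=1, log_expit(-eta) for y=0
    return log_expit((2.0 * y - 1.0) * eta)


def _conditional_mode(
    eta0: np.ndarray,
    mat: ModelMatrix,
    sigma: float,
    tol: float = 1e-9,
    u0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual mode and curvature of the conditional log-joint in u.

    Newton iterations, vectorized across individuals.  Returns (mode,
    negative second derivative at the mode).  The log-joint in u is concave,
    so undamped Newton converges; a step-halving safeguard handles the first
    few iterations from u=0.
    """
    m = mat.n_individuals
    u = np.zeros(m) if u0 is None else u0.copy()
    inv_s2 = 1.0 / (sigma * sigma)

    def grad_hess(u):
        eta = eta0 + u[mat.ind]
        p = expit(eta)
        g = mat.group_sum(mat.y - p) - u * inv_s2
        h = mat.group_sum(p * (1.0 - p)) + inv_s2  # = -d2/du2
        return g, h

    for _ in range(50):
        g, h = grad_hess(u)
        step = g / h
        u_new = u + step
        if np.max(np.abs(step)) < tol:
            u = u_new
            break
        u = u_new
    g, h = grad_hess(u)
    return u, h


_HERMITE_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _hermite(nodes: int) -> tuple[np.ndarray, np.ndarray]:
    if nodes not in _HERMITE_CACHE:
        t, w = roots_hermite(nodes)
        _HERMITE_CACHE[nodes] = (t, np.log(w))
    return _HERMITE_CACHE[nodes]


def _marginal_core(
    beta: np.ndarray,
    sigma: float,
    B: float,
    mat: ModelMatrix,
    nodes: int,
    *,
    formula: str = "at_least_one",
    want_grad: bool = False,
    state: dict | None = None,
):
    """Marginal log-likelihood (and optionally its gradient) on arrays.

    Integrates the random intercept out with adaptive Gauss-Hermite
    quadrature centred at each individual's conditional mode and scaled by
    the conditional curvature.  Gradients use the posterior-expectation
    identity evaluated on the same nodes: d/dbeta is the posterior-weighted
    score X'(y - p), d/dlog(sigma) is E[(u/sigma)^2 - 1], and
    d/dlogit(B) is sum_j r_j * T_j * B / O_j where r_j is the
    posterior-weighted residual of record j.
    """
    off = offset_term(B, mat.T, formula=formula)
    eta0 = mat.X @ beta + off

    if sigma == 0.0:
        ll = float(np.sum(_bernoulli_loglik(eta0, mat.y)))
        if not want_grad:
            return ll
        p = expit(eta0)
        r = mat.y - p
        dbeta = mat.X.T @ r
        O = occurrence_offset_probability(B, mat.T, formula=formula)
        dlogitB = float(np.sum(r * mat.T * B / O))
        return ll, dbeta, 0.0, dlogitB

    u_start = state.get("u") if state is not None else None
    if u_start is not None and u_start.size != mat.n_individuals:
        u_start = None
    u_mode, h = _conditional_mode(eta0, mat, sigma, u0=u_start)
    if state is not None:
        state["u"] = u_mode
    s = 1.0 / np.sqrt(h)                     # (m,) adaptive scale
    t, log_w = _hermite(nodes)               # (K,)
    U = u_mode[:, None] + np.sqrt(2.0) * s[:, None] * t[None, :]   # (m, K)

    eta = eta0[:, None] + U[mat.ind, :]      # (n, K)
    lf = mat.group_sum(_bernoulli_loglik(eta, mat.y[:, None]))     # (m, K)
    log_phi = -0.5 * (U / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    la = log_w[None, :] + t[None, :] ** 2 + _LOG_SQRT_2 + np.log(s)[:, None] + log_phi + lf
    # inline logsumexp: the (m, K) arrays are small and call overhead matters
    la_max = la.max(axis=1)
    ll_i = la_max + np.log(np.exp(la - la_max[:, None]).sum(axis=1))   # (m,)
    ll = float(np.sum(ll_i))
    if not np.isfinite(ll):
        raise FloatingPointError(
            "non-finite marginal log-likelihood (parameters at the edge of the "
            f"feasible region: beta={beta}, sigma={sigma}, B={B})"
        )
    if not want_grad:
        return ll

    omega = np.exp(la - ll_i[:, None])       # (m, K) posterior node weights
    p = expit(eta)                           # (n, K)
    r = np.sum(omega[mat.ind, :] * (mat.y[:, None] - p), axis=1)   # (n,)
    dbeta = mat.X.T @ r
    dlogsigma = float(np.sum(omega * ((U / sigma) ** 2 - 1.0)))
    O = occurrence_offset_probability(B, mat.T, formula=formula)
    dlogitB = float(np.sum(r * mat.T * B / O))
    return ll, dbeta, dlogsigma, dlogitB


# ---------------------------------------------------------------------------
# public likelihood API on Dataset / ModelParams
# ---------------------------------------------------------------------------


def conditional_loglik(params: ModelParams, u: dict, data: Dataset) -> float:
    """Log-likelihood of the responses given the random intercepts.

    ``u`` maps individual ID to its intercept.  Every individual present in
    the data must have an entry.
    """
    mat = build_matrix(data)
    missing = [i for i in mat.individual_ids if i not in u]
    if missing:
        raise KeyError(f"no random intercept supplied for individual(s): {missing}")
    u_vec = np.array([float(u[i]) for i in mat.individual_ids])
    off = offset_term(params.B, mat.T)
    eta = mat.X @ params.beta_array + u_vec[mat.ind] + off
    return float(np.sum(_bernoulli_loglik(eta, mat.y)))


def marginal_loglik(params: ModelParams, data: Dataset, quadrature_nodes: int = 30) -> float:
    """Marginal log-likelihood, random intercepts integrated out.

    Uses adaptive Gauss-Hermite quadrature with ``quadrature_nodes`` nodes
    per individual.  At sigma = 0 this reduces exactly to the conditional
    log-likelihood with all intercepts zero.
    """
    if quadrature_nodes < 1:
        raise ValueError("quadrature_nodes must be >= 1")
    mat = build_matrix(data)
    return _marginal_core(params.beta_array, params.sigma, params.B, mat, quadrature_nodes)


def brute_force_marginal_loglik(
    params: ModelParams, data: Dataset, n_grid: int = 20001, width: float = 10.0
) -> float:
    """Dense-trapezoid evaluation of the same marginal likelihood.

    Verification oracle for the quadrature: integrates each individual's
    likelihood contribution over u in [-width*sigma, width*sigma] on an
    ``n_grid``-point grid.  Only intended for small datasets.
    """
    mat = build_matrix(data)
    sigma = params.sigma
    if sigma == 0.0:
        return _marginal_core(params.beta_array, 0.0, params.B, mat, 1)
    if mat.n_individuals > 50:
        raise ValueError("brute-force integration is restricted to small datasets")
    off = offset_term(params.B, mat.T)
    eta0 = mat.X @ params.beta_array + off
    u = np.linspace(-width * sigma, width * sigma, n_grid)
    du = u[1] - u[0]
    eta = eta0[:, None] + u[None, :]                       # (n, G)
    lf = mat.group_sum(_bernoulli_loglik(eta, mat.y[:, None]))  # (m, G)
    log_phi = -0.5 * (u / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    integrand = lf + log_phi[None, :]
    # trapezoid rule in log space: interior points weight du, ends du/2
    log_wts = np.full(n_grid, np.log(du))
    log_wts[[0, -1]] -= np.log(2.0)
    ll_i = logsumexp(integrand + log_wts[None, :], axis=1)
    return float(np.sum(ll_i))
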