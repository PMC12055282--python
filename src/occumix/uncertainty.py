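"""Bootstrap confidence limits and leave-one-individual-out stability.

Both procedures hold the profiled per-second rate B fixed at its full-data
point estimate: the offset is then a known covariate and each refit is an
ordinary mixed-model fit.  Confidence limits are percentile (2.5/97.5)
limits of the bootstrap replicate estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, FittedModel
from .fitting import LRTResult, _fit_arrays, profile_B
from .model import build_matrix, replace_responses
from .simulate import _draw_responses, simulate_from_fit

__all__ = ["parametric_bootstrap", "loo_stability", "summarize", "BootstrapResult", "StabilityResult", "FitSummary"]


@dataclass
class BootstrapResult:
    """Replicate fixed-effect estimates from a parametric bootstrap."""

    n_boot: int
    replicate_estimates: np.ndarray  # (n_ok, p)
    n_failed: int
    seed: int
    term_names: tuple

    def __post_init__(self) -> None:
        assert self.n_failed + self.replicate_estimates.shape[0] == self.n_boot

    @property
    def unreliable(self) -> bool:
        return self.n_failed > 0.1 * self.n_boot

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Percentile confidence limits for each fixed-effect term."""
        if self.replicate_estimates.shape[0] == 0:
            raise RuntimeError(
                f"no successful bootstrap replicates ({self.n_failed}/{self.n_boot} failed)"
            )
        alpha = 100.0 * (1.0 - level) / 2.0
        lo = np.percentile(self.replicate_estimates, alpha, axis=0)
        hi = np.percentile(self.replicate_estimates, 100.0 - alpha, axis=0)
        return lo, hi


@dataclass
class StabilityResult:
    """Componentwise range of estimates over leave-one-individual-out refits."""

    estimates: pd.DataFrame  # one row per dropped individual
    min: np.ndarray
    max: np.ndarray
    n_failed: int
    term_names: tuple


def parametric_bootstrap(
    fitted: FittedModel,
    data: Dataset,
    n_boot: int,
    seed: int,
    *,
    nodes: int = 30,
    refit_B: bool = False,
) -> BootstrapResult:
    """Parametric bootstrap of the fixed effects.

    Each replicate simulates new responses from the fitted model at the
    original design points and refits (beta, sigma) with B held at the point
    estimate (``refit_B=True`` re-profiles B per replicate instead; roughly
    an order of magnitude slower).  Replicates whose refit does not converge
    are dropped and counted, never imputed.
    """
    if not fitted.converged:
        raise ValueError("refusing to bootstrap a non-converged fit")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    spec = fitted.model_spec
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_boot)

    mat = build_matrix(data, spec)
    start = (fitted.params.beta_array, max(fitted.params.sigma, 0.05))
    rows = []
    n_failed = 0
    params = fitted.params
    for s in child_seeds:
        if refit_B:
            rep = simulate_from_fit(fitted, data, int(s))
            try:
                _, refit = profile_B(rep, spec, se=False)
            except (RuntimeError, ValueError):
                n_failed += 1
                continue
            ok, beta = refit.converged and not refit.separation, refit.params.beta_array
        else:
            # array fast path: same draws as simulate_from_fit for this seed
            y = _draw_responses(mat, params.beta_array, params.sigma, params.B, int(s))
            if y.min() == y.max():
                n_failed += 1
                continue
            mat_rep = replace_responses(mat, y)
            f = _fit_arrays(mat_rep, params.B, nodes=nodes, start=start, loose=True)
            ok, beta = f.converged and np.max(np.abs(f.beta)) < 15.0, f.beta
        if ok:
            rows.append(beta)
        else:
            n_failed += 1

    estimates = np.asarray(rows, dtype=float).reshape(len(rows), mat.X.shape[1])
    return BootstrapResult(
        n_boot=n_boot,
        replicate_estimates=estimates,
        n_failed=n_failed,
        seed=seed,
        term_names=fitted.term_names,
    )


def loo_stability(fitted: FittedModel, data: Dataset, *, nodes: int = 30) -> StabilityResult:
    """Refit after dropping each individual in turn; report estimate ranges.

    B is kept constant at the full-data estimate throughout.  Subsets whose
    refit fails are excluded and counted; if every subset fails, an error is
    raised.
    """
    spec = fitted.model_spec
    df = data.df
    df = df[(df["behaviour"] == spec.behaviour) & (df["period"] == spec.period)]
    individuals = sorted(set(df["individual_id"].astype(str)))
    if len(individuals) < 3:
        raise ValueError("leave-one-out stability needs at least 3 individuals")

    start = (fitted.params.beta_array, max(fitted.params.sigma, 0.05))
    rows = []
    n_failed = 0
    for ind in individuals:
        sub = Dataset(df[df["individual_id"].astype(str) != ind].copy())
        mat = build_matrix(sub, spec)
        if mat.y.min() == mat.y.max():
            n_failed += 1
            continue
        f = _fit_arrays(mat, fitted.params.B, nodes=nodes, start=start, loose=True)
        if f.converged:
            rows.append({"dropped": ind, **dict(zip(fitted.term_names, f.beta))})
        else:
            n_failed += 1
    if not rows:
        raise RuntimeError("all leave-one-out subsets failed to fit")
    est = pd.DataFrame(rows)
    values = est[list(fitted.term_names)].to_numpy()
    return StabilityResult(
        estimates=est,
        min=values.min(axis=0),
        max=values.max(axis=0),
        n_failed=n_failed,
        term_names=fitted.term_names,
    )


@dataclass
class FitSummary:
    """One Table-shaped block: per-term estimates with uncertainty and range.

    Columns mirror the reporting convention for these models: Est., SE,
    CI_lower, CI_upper (parametric bootstrap percentiles), the activity-type
    likelihood-ratio test (chi2, d.f., P), and per-term min/max over
    leave-one-individual-out refits.
    """

    model: str
    table: pd.DataFrame
    chi2: float
    df: int
    p: float
    B: float
    n_obs: int
    n_individuals: int
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Full-precision machine output, one row per term."""
        out = self.table.copy()
        out.insert(0, "model", self.model)
        out["chi2"] = self.chi2
        out["df"] = self.df
        out["P"] = self.p
        out["B"] = self.B
        out["n_obs"] = self.n_obs
        out["n_individuals"] = self.n_individuals
        return out

    def display(self) -> pd.DataFrame:
        """Rounded (3 decimals) view for reports."""
        out = self.to_frame()
        num = out.select_dtypes(include=[np.number]).columns
        out[num] = out[num].round(3)
        return out


def summarize(
    fitted: FittedModel,
    lrt: LRTResult,
    bootstrap: BootstrapResult,
    stability: StabilityResult,
) -> FitSummary:
    """Assemble the per-model reporting block from its four components.

    All components must refer to the same model specification.  Percentile
    intervals need not contain the point estimate and leave-one-out ranges
    need not bracket the full-data fit; violations are reported as warnings,
    not errors.
    """
    spec = fitted.model_spec
    if lrt.full.model_spec != spec:
        raise ValueError("LRT was computed for a different model specification")
    if bootstrap.term_names != fitted.term_names or stability.term_names != fitted.term_names:
        raise ValueError("bootstrap/stability terms do not match the fitted model")

    est = fitted.params.beta_array
    lo, hi = bootstrap.ci(0.95)
    warnings_list = []
    if np.any(est < lo) or np.any(est > hi):
        warnings_list.append("point estimate outside the 95% bootstrap interval for some term")
    if np.any(est < stability.min) or np.any(est > stability.max):
        warnings_list.append("point estimate outside the leave-one-out range for some term")
    if bootstrap.unreliable:
        warnings_list.append(
            f"bootstrap unreliable: {bootstrap.n_failed}/{bootstrap.n_boot} replicates failed"
        )

    table = pd.DataFrame(
        {
            "term": list(fitted.term_names),
            "estimate": est,
            "se": fitted.se_beta,
            "ci_lower": lo,
            "ci_upper": hi,
            "min": stability.min,
            "max": stability.max,
        }
    )
    return FitSummary(
        model=spec.label(),
        table=table,
        chi2=lrt.chi2,
        df=lrt.df,
        p=lrt.p,
        B=fitted.params.B,
        n_obs=fitted.n_obs,
        n_individuals=fitted.n_individuals,
        warnings=warnings_list,
    )
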