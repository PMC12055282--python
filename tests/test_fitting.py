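"""Maximum-likelihood fitting, the B profile, and the activity-type LRT."""

import shutil
import subprocess

import numpy as np
import pytest

from occumix import (
    Dataset,
    SimulationConfig,
    collapse_periods,
    fit_inner,
    lrt_activity,
    profile_B,
    simulate_dataset,
    simulate_study,
    write_events,
)
from occumix.model import build_matrix, _marginal_core


def test_fit_inner_recovers_null_parameters_at_fixed_B(spec_before):
    """sigma=0, beta=0, B matching the fixed B: estimates shrink to truth."""
    cfg = SimulationConfig(
        n_individuals=250, events_per_individual=20, true_beta=(0, 0, 0),
        true_sigma=0.0, true_B=0.05, seed=8,
    )
    d = simulate_dataset(cfg)  # 5,000 events
    f = fit_inner(d, spec_before, B=0.05)
    assert f.converged
    assert np.max(np.abs(f.params.beta_array)) < 0.15
    # sigma-hat at a boundary truth has sampling spread ~0.2 at 20 events
    # per individual; "recovered" means small, not numerically zero
    assert f.params.sigma < 0.3


def test_single_individual_raises_boundary_flag(spec_before):
    cfg = SimulationConfig(n_individuals=1, events_per_individual=30, seed=3)
    d = simulate_dataset(cfg)
    f = fit_inner(d, spec_before, B=0.05)
    assert f.boundary_sigma and not f.converged


def test_fitted_loglik_is_local_maximum(small_dataset, spec_before):
    """Grid oracle: no probed (beta, sigma) beats the optimum."""
    f = fit_inner(small_dataset, spec_before, B=0.08, se=False)
    mat = build_matrix(small_dataset, spec_before)
    best = f.loglik
    rng = np.random.default_rng(0)
    for _ in range(60):
        beta = f.params.beta_array + rng.uniform(-0.5, 0.5, 3)
        sigma = abs(f.params.sigma + rng.uniform(-0.5, 0.5))
        assert _marginal_core(beta, sigma, 0.08, mat, 20) <= best + 1e-8


def test_fit_matches_lme4_glmer(tmp_path, spec_before):
    """Independent oracle: lme4::glmer with the offset as a known covariate.

    At fixed B the model is an ordinary binomial GLMM, which glmer fits with
    adaptive Gauss-Hermite quadrature; estimates, sigma and log-likelihood
    must agree.
    """
    cfg = SimulationConfig(
        n_individuals=15, events_per_individual=8, true_beta=(0.3, -0.4, 0.8),
        true_sigma=0.8, true_B=0.07, seed=17,
    )
    d = simulate_dataset(cfg)
    f = fit_inner(d, spec_before, B=0.06, nodes=25)
    events = tmp_path / "events.csv"
    write_events(d, events)
    script = tmp_path / "fit.R"
    script.write_text(
        'suppressMessages(library(lme4))\n'
        f'd <- read.csv("{events}")\n'
        'O <- 1 - (1 - 0.06)^d$duration_s\n'
        'd$off <- log(O / (1 - O))\n'
        'd$activity <- factor(d$activity, levels=c("drum","stone_and_drum","stone"))\n'
        'm <- glmer(occurred ~ activity + offset(off) + (1|individual_id), data=d,\n'
        '           family=binomial, nAGQ=25,\n'
        '           control=glmerControl(optimizer="bobyqa"))\n'
        'cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")\n'
    )
    rscript = shutil.which("Rscript")
    assert rscript, "Rscript not on PATH"
    out = subprocess.run([rscript, str(script)], capture_output=True, text=True, check=True)
    vals = [float(v) for v in out.stdout.split()]
    assert np.allclose(vals[:3], f.params.beta_array, atol=2e-4)
    assert vals[3] == pytest.approx(f.params.sigma, abs=2e-4)
    assert vals[4] == pytest.approx(f.loglik, abs=1e-3)


def test_profile_recovers_B(recovery_dataset, spec_before):
    B_hat, fitted = profile_B(recovery_dataset, spec_before, se=False)
    assert 0.02 <= B_hat <= 0.10
    assert fitted.converged and not fitted.B_fixed


def test_profile_maximum_beats_grid(spec_before):
    """L*(B_hat) >= L*(B) on a 50-point grid across (0.001, 0.999)."""
    cfg = SimulationConfig(
        n_individuals=40, events_per_individual=5, true_B=0.05,
        true_beta=(0.3, 0, 0), true_sigma=0.8, seed=23,
    )
    d = simulate_dataset(cfg)
    B_hat, fitted = profile_B(d, spec_before, se=False)
    mat = build_matrix(d, spec_before)
    from occumix.fitting import _fit_arrays

    start = (fitted.params.beta_array, max(fitted.params.sigma, 0.05))
    for B in np.linspace(0.001, 0.999, 50):
        assert _fit_arrays(mat, float(B), start=start).loglik <= fitted.loglik + 1e-6


def test_profile_flat_when_durations_constant(spec_before):
    """Constant T makes the offset a constant: B is absorbed by the
    intercept and the profile is flat."""
    cfg = SimulationConfig(
        n_individuals=20, events_per_individual=10,
        duration_probs=tuple([0.0] * 29 + [1.0] + [0.0] * 31), seed=4,
    )
    d = simulate_dataset(cfg)
    assert d.df["duration_s"].nunique() == 1
    B_hat, fitted = profile_B(d, spec_before, se=False)
    assert any("flat profile" in m for m in fitted.messages)


def test_refit_at_profiled_B_reproduces_estimates(recovery_dataset, spec_before):
    """Consistency of the profile and the joint optimum."""
    B_hat, fitted = profile_B(recovery_dataset, spec_before, se=False)
    refit = fit_inner(recovery_dataset, spec_before, B=B_hat, se=False)
    assert np.allclose(refit.params.beta_array, fitted.params.beta_array, atol=1e-5)
    assert refit.params.sigma == pytest.approx(fitted.params.sigma, abs=1e-5)


def test_estimates_invariant_to_relabelling_and_row_order(spec_before):
    cfg = SimulationConfig(n_individuals=25, events_per_individual=8, true_sigma=0.8, seed=31)
    d = simulate_dataset(cfg)
    B1, f1 = profile_B(d, spec_before, se=False)

    df = d.df.copy()
    mapping = {f"ind_{i+1:02d}": f"chimp_{chr(65 + i)}" for i in range(25)}
    df["individual_id"] = df["individual_id"].map(mapping)
    df = df.sample(frac=1.0, random_state=99).reset_index(drop=True)
    B2, f2 = profile_B(Dataset(df), spec_before, se=False)

    # permutation changes float summation order; equality is to optimizer
    # precision, not bitwise
    assert B2 == pytest.approx(B1, abs=1e-4)
    assert np.allclose(f2.params.beta_array, f1.params.beta_array, atol=1e-4)
    assert f2.params.sigma == pytest.approx(f1.params.sigma, abs=1e-4)


def test_lrt_full_never_below_reduced(spec_before):
    for seed in range(41, 47):
        cfg = SimulationConfig(
            n_individuals=30, events_per_individual=5, true_sigma=0.8,
            true_beta=(0.2, 0.4, -0.3), seed=seed,
        )
        d = simulate_dataset(cfg)
        res = lrt_activity(d, spec_before)
        assert res.df == 2
        assert res.full.loglik >= res.reduced.loglik - 1e-6
        assert res.chi2 >= 0.0 and 0.0 <= res.p <= 1.0


def test_lrt_detects_large_activity_contrast(spec_before):
    cfg = SimulationConfig(
        n_individuals=100, events_per_individual=5, true_sigma=1.0,
        true_beta=(0.0, 0.0, 2.0), true_B=0.05, seed=51,
    )
    d = simulate_dataset(cfg)
    res = lrt_activity(d, spec_before)
    assert res.p < 0.01


def test_lrt_single_activity_level_is_null_test(spec_before):
    cfg = SimulationConfig(
        n_individuals=15, events_per_individual=6,
        activity_probs=(1.0, 0.0, 0.0), true_sigma=0.5, seed=6,
    )
    d = simulate_dataset(cfg)
    res = lrt_activity(d, spec_before)
    assert res.chi2 == 0.0 and res.p == 1.0


def test_collapse_periods_or_response_and_summed_duration():
    cfg = SimulationConfig(n_individuals=10, events_per_individual=4, seed=19)
    d = simulate_study(cfg)
    combined = collapse_periods(d)
    assert set(combined.df["period"]) == {"combined"}
    assert combined.metadata["unpaired"] == 0

    merged = combined.df.set_index(["event_id", "behaviour"])
    for (event_id, behaviour), g in d.df.groupby(["event_id", "behaviour"]):
        row = merged.loc[(event_id, behaviour)]
        assert row["occurred"] == int(g["occurred"].max())
        assert row["duration_s"] == g["duration_s"].sum()


def test_collapse_periods_keeps_unpaired_windows():
    cfg = SimulationConfig(n_individuals=6, events_per_individual=3, seed=20)
    d = simulate_study(cfg)
    # drop the after-window of one event: it must survive with its own window
    df = d.df[~((d.df["event_id"] == "ev_000001") & (d.df["period"] == "after"))]
    combined = collapse_periods(Dataset(df.copy()))
    assert combined.metadata["unpaired"] == 6  # one event x six behaviours
    kept = combined.df[combined.df["event_id"] == "ev_000001"]
    before = d.df[(d.df["event_id"] == "ev_000001") & (d.df["period"] == "before")]
    assert kept["duration_s"].tolist() == before["duration_s"].tolist()


def test_fit_inner_rejects_bad_B(small_dataset, spec_before):
    with pytest.raises(ValueError):
        fit_inner(small_dataset, spec_before, B=0.0)
    with pytest.raises(ValueError):
        profile_B(small_dataset, spec_before, bounds=(0.5, 0.1))
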