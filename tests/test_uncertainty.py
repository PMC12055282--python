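"""Parametric bootstrap, leave-one-individual-out stability, and the
table-shaped summary blocks."""

import numpy as np
import pandas as pd
import pytest

from occumix import (
    Dataset,
    ModelSpec,
    SimulationConfig,
    fit_inner,
    loo_stability,
    lrt_activity,
    parametric_bootstrap,
    profile_B,
    simulate_dataset,
    summarize,
)


@pytest.fixture(scope="module")
def medium_fit(spec_before):
    cfg = SimulationConfig(
        n_individuals=30, events_per_individual=8, true_beta=(0.3, -0.2, 0.5),
        true_sigma=0.8, true_B=0.05, seed=61,
    )
    d = simulate_dataset(cfg)
    B_hat, fitted = profile_B(d, spec_before)
    return d, fitted


def test_bootstrap_deterministic_given_seed(medium_fit):
    d, fitted = medium_fit
    a = parametric_bootstrap(fitted, d, n_boot=25, seed=5)
    b = parametric_bootstrap(fitted, d, n_boot=25, seed=5)
    assert np.array_equal(a.replicate_estimates, b.replicate_estimates)
    assert a.n_failed == b.n_failed
    assert a.n_failed + a.replicate_estimates.shape[0] == 25


def test_bootstrap_sd_matches_wald_se_without_random_effect(spec_before):
    """With sigma=0 and many events the bootstrap SD of beta must agree with
    the analytic (observed-information) SE."""
    cfg = SimulationConfig(
        n_individuals=100, events_per_individual=100, true_beta=(0.2, -0.3, 0.6),
        true_sigma=0.0, true_B=0.05, seed=62,
    )
    d = simulate_dataset(cfg)  # 10,000 events
    fitted = fit_inner(d, spec_before, B=0.05)
    assert fitted.boundary_sigma
    boot = parametric_bootstrap(fitted, d, n_boot=80, seed=7)
    assert boot.n_failed == 0
    sd = boot.replicate_estimates.std(axis=0, ddof=1)
    assert np.all(np.abs(sd / fitted.se_beta - 1.0) < 0.20)


def test_bootstrap_refuses_nonconverged(medium_fit, spec_before):
    d, fitted = medium_fit
    from dataclasses import replace

    broken = replace(fitted, converged=False)
    with pytest.raises(ValueError):
        parametric_bootstrap(broken, d, n_boot=5, seed=1)


def test_bootstrap_interval_width_shrinks_with_sample_size(spec_before):
    """Percentile interval widths scale roughly as 1/sqrt(n_events)."""
    widths = {}
    for n_ind, n_ev in ((25, 20), (100, 20), (100, 80)):  # 500, 2000, 8000 events
        cfg = SimulationConfig(
            n_individuals=n_ind, events_per_individual=n_ev,
            true_beta=(0.2, -0.3, 0.6), true_sigma=0.0, true_B=0.05, seed=63,
        )
        d = simulate_dataset(cfg)
        fitted = fit_inner(d, spec_before, B=0.05, se=False)
        boot = parametric_bootstrap(fitted, d, n_boot=100, seed=9)
        lo, hi = boot.ci(0.95)
        widths[n_ind * n_ev] = hi - lo
    sizes = sorted(widths)
    for a, b in zip(sizes, sizes[1:]):
        assert np.all(widths[b] < widths[a])  # monotone shrinkage
        expected = np.sqrt(a / b)
        ratio = widths[b] / widths[a]
        assert np.all(np.abs(ratio / expected - 1.0) < 0.30)


def test_loo_produces_one_subset_per_individual(medium_fit):
    d, fitted = medium_fit
    stab = loo_stability(fitted, d)
    assert len(stab.estimates) + stab.n_failed == fitted.n_individuals
    assert np.all(stab.min <= stab.max)


def test_loo_flags_influential_individual(spec_before):
    """One individual carrying all successes for one activity level moves
    that contrast sharply when dropped."""
    rng = np.random.default_rng(3)
    rows = []
    for i in range(8):
        for k in range(6):
            act = "drum" if k < 3 else "stone"
            # only individual 0 ever shows the behaviour during stone events
            occ = int(act == "stone" and i == 0) or int(act == "drum" and rng.random() < 0.4)
            rows.append(
                {
                    "individual_id": f"i{i}", "site": "s", "activity": act,
                    "period": "before", "duration_s": int(rng.integers(5, 40)),
                    "behaviour": "pant_hoot", "occurred": occ,
                }
            )
    d = Dataset(pd.DataFrame(rows))
    fitted = fit_inner(d, ModelSpec("pant_hoot", "before"), B=0.05, se=False)
    stab = loo_stability(fitted, d)
    spread = stab.max - stab.min
    assert spread[2] > 2.0  # the stone contrast collapses without i0


def test_loo_stable_on_balanced_data(spec_before):
    cfg = SimulationConfig(
        n_individuals=30, events_per_individual=30, true_beta=(0.3, -0.2, 0.5),
        true_sigma=0.5, true_B=0.05, seed=64,
    )
    d = simulate_dataset(cfg)
    fitted = fit_inner(d, spec_before, B=0.05, se=False)
    stab = loo_stability(fitted, d)
    assert np.all(stab.max - stab.min < 0.5)


def test_loo_requires_three_individuals(spec_before):
    cfg = SimulationConfig(n_individuals=2, events_per_individual=10, seed=1)
    d = simulate_dataset(cfg)
    fitted = fit_inner(d, spec_before, B=0.05, se=False)
    with pytest.raises(ValueError):
        loo_stability(fitted, d)


def test_summary_block_structure_and_rounding(medium_fit, spec_before):
    d, fitted = medium_fit
    lrt = lrt_activity(d, spec_before)
    boot = parametric_bootstrap(fitted, d, n_boot=40, seed=11)
    stab = loo_stability(fitted, d)
    summary = summarize(fitted, lrt, boot, stab)

    frame = summary.to_frame()
    assert list(frame["term"]) == ["intercept", "beh_st_dr", "beh_st"]
    assert summary.df == 2
    expected_cols = {"model", "term", "estimate", "se", "ci_lower", "ci_upper",
                     "min", "max", "chi2", "df", "P", "B", "n_obs", "n_individuals"}
    assert expected_cols <= set(frame.columns)

    shown = summary.display()
    num = frame.select_dtypes("number")
    assert shown[num.columns].equals(num.round(3))


def test_summarize_refuses_mismatched_components(medium_fit):
    d, fitted = medium_fit
    other_spec = ModelSpec("swaying", "before")
    other_d = Dataset(
        d.df.assign(behaviour="swaying"), metadata={}
    )
    lrt_other = lrt_activity(other_d, other_spec)
    boot = parametric_bootstrap(fitted, d, n_boot=10, seed=2)
    stab = loo_stability(fitted, d)
    with pytest.raises(ValueError):
        summarize(fitted, lrt_other, boot, stab)


def test_stability_ranges_bracket_recomputed_subsets(medium_fit, spec_before):
    """Self-consistency: independently refitting a few subsets lands inside
    the reported min/max."""
    d, fitted = medium_fit
    stab = loo_stability(fitted, d)
    for ind in sorted(d.individuals)[:5]:
        sub = Dataset(d.df[d.df["individual_id"] != ind].copy())
        refit = fit_inner(sub, spec_before, B=fitted.params.B, se=False)
        assert np.all(refit.params.beta_array >= stab.min - 1e-6)
        assert np.all(refit.params.beta_array <= stab.max + 1e-6)
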