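"""Model-based threshold-crossing machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cd4traj.cohort import from_frame
from cd4traj.crossing import (
    Threshold,
    bootstrap_crossing_ci,
    crossing_mass,
    cumulative_crossing_prob,
    expected_crossing_time,
    phi_tilde,
    sorted_crossing_probabilities,
)
from cd4traj.fp import FPSpec
from conftest import manual_model

import pandas as pd

TAU350 = math.log(350.0)


def geometric_model(sigma=0.5):
    """mu(t) = tau for every t, so each phi factor is exactly 0.5."""
    return manual_model([TAU350, 0.0, 0.0], (0.0, 0.5), sigma2=sigma**2, time_offset=0.0)


def test_threshold_invariant():
    th = Threshold.from_cd4(350.0)
    assert th.tau == pytest.approx(math.log(350.0), abs=1e-15)
    with pytest.raises(ValueError):
        Threshold(350.0, 5.0)


def test_phi_tilde_values():
    th = Threshold.from_cd4(350.0)
    m = geometric_model()
    assert phi_tilde(m, "p", 7.0, th) == pytest.approx(0.5, abs=1e-12)
    # tau -> +inf limit
    m2 = manual_model([5.0, 0.0, 0.0], (0.0, 0.5), sigma2=0.25, time_offset=0.0)
    assert phi_tilde(m2, "p", 7.0, Threshold.from_cd4(1e9)) == pytest.approx(1.0)
    # mu = 5.0, sigma = 0.5, tau = 5.8579 -> Phi(1.7158) = 0.9569
    assert phi_tilde(m2, "p", 7.0, Threshold(350.0)) == pytest.approx(0.9569, abs=1e-4)
    m2.sigma2_ = 0.0
    with pytest.raises(ValueError):
        phi_tilde(m2, "p", 7.0, th)


def test_crossing_mass_geometric():
    dist = crossing_mass(geometric_model(), "p", np.arange(1.0, 11.0), Threshold(350.0))
    np.testing.assert_allclose(dist.masses, 0.5 ** np.arange(1, 11), atol=1e-14)
    assert dist.masses.sum() + dist.residual_mass == pytest.approx(1.0, abs=1e-12)


def test_crossing_mass_saturated():
    # mu 10 sigma above tau at the first grid point -> all mass at t1
    m = manual_model([TAU350 + 5.0, 0.0, 0.0], (0.0, 0.5), sigma2=0.25, time_offset=0.0)
    dist = crossing_mass(m, "p", np.arange(1.0, 61.0), Threshold(350.0))
    assert dist.masses[0] == pytest.approx(1.0, abs=1e-12)
    assert dist.residual_mass == pytest.approx(0.0, abs=1e-12)


def test_crossing_mass_grid_validation():
    m = geometric_model()
    with pytest.raises(ValueError):
        crossing_mass(m, "p", [], Threshold(350.0))
    with pytest.raises(ValueError):
        crossing_mass(m, "p", [3.0, 2.0], Threshold(350.0))


@settings(derandomize=True, max_examples=60)
@given(
    beta0=st.floats(3.0, 8.0),
    slope=st.floats(-0.3, 0.5),
    sigma=st.floats(0.05, 1.0),
    cd4=st.sampled_from([200.0, 350.0, 500.0]),
)
def test_mass_conservation_property(beta0, slope, sigma, cd4):
    """Sum of crossing masses plus residual mass is exactly one for any
    trajectory, threshold and grid (telescoping product)."""
    m = manual_model([beta0, slope, 0.02], (0.0, 0.5), sigma2=sigma**2, time_offset=1.0)
    for grid in (np.arange(1.0, 121.0), np.array([0.5, 2.0, 7.5, 30.0, 66.0])):
        dist = crossing_mass(m, "p", grid, Threshold(cd4))
        assert abs(dist.masses.sum() + dist.residual_mass - 1.0) < 1e-10
        assert (dist.masses >= 0).all() and (dist.masses <= 1).all()


def test_expected_time_geometric_closed_form():
    dist = expected_crossing_time(geometric_model(), "p", Threshold(350.0), horizon=50, spacing=1.0)
    # sum j * 0.5^j = 2 (truncation at 50 is far below 1e-9)
    assert dist.expected_time_unconditional == pytest.approx(2.0, abs=1e-9)
    assert dist.expected_time_conditional == pytest.approx(2.0, abs=1e-9)


def test_expected_time_noiseless_limit():
    # mu(t) = 5 + 0.1 t crosses tau = 5.75 at t = 7.5; with sigma -> 0 the
    # first grid time at or past the crossing is month 8
    beta = [5.0, 0.1, 0.0]
    m = manual_model(beta, (1.0, 2.0), sigma2=1e-20, time_offset=0.0)
    th_cd4 = math.exp(5.75)
    dist = expected_crossing_time(m, "p", Threshold.from_cd4(th_cd4), horizon=60, spacing=1.0)
    assert dist.expected_time_conditional == pytest.approx(8.0, abs=1e-9)


def test_residual_mass_warning():
    m = manual_model([2.0, 0.0, 0.0], (0.0, 0.5), sigma2=0.04, time_offset=0.0)
    dist = expected_crossing_time(m, "p", Threshold(350.0), horizon=24)
    assert dist.residual_mass > 0.5
    assert dist.warnings_


def test_cumulative_prob():
    m = geometric_model()
    th = Threshold(350.0)
    assert cumulative_crossing_prob(m, "p", th, 0.4) == 0.0  # before first grid point
    assert cumulative_crossing_prob(m, "p", th, 3.0) == pytest.approx(0.875, abs=1e-12)
    probs = [cumulative_crossing_prob(m, "p", th, t) for t in np.arange(1.0, 80.0, 2.5)]
    assert all(b >= a for a, b in zip(probs, probs[1:]))


def test_expected_time_monotone_in_threshold():
    b = {"p": np.array([0.2, 0.05, -0.01])}
    m = manual_model([5.0, 0.1, 0.1], (0.0, 0.5), sigma2=0.16, time_offset=1.0, ranef=b)
    taus = [100.0, 200.0, 350.0, 500.0, 800.0]
    times = [
        expected_crossing_time(m, "p", Threshold.from_cd4(c), horizon=120).expected_time_conditional
        for c in taus
    ]
    assert all(b >= a - 1e-9 for a, b in zip(times, times[1:]))


def test_grid_refinement_stability():
    # smooth low-noise trajectory: the crossing region (sigma / slope ~ 0.2
    # months) is narrower than the spacing, so refinement barely moves the
    # expectation.  (With large residual noise the discrete-monitoring
    # expectation is genuinely schedule-dependent.)
    m = manual_model([5.0, 0.1, 0.0], (1.0, 2.0), sigma2=0.02**2, time_offset=0.0)
    coarse = expected_crossing_time(m, "p", Threshold(350.0), 120, 1.0)
    fine = expected_crossing_time(m, "p", Threshold(350.0), 120, 0.5)
    assert abs(coarse.expected_time_conditional - fine.expected_time_conditional) < 1.0


def test_sorted_probabilities_structure():
    ranef = {f"hi{i}": np.array([1.5, 0.0, 0.0]) for i in range(6)}
    ranef.update({f"lo{i}": np.array([-2.5, 0.0, 0.0]) for i in range(14)})
    m = manual_model([TAU350, 0.05, 0.0], (0.0, 0.5), sigma2=0.16, time_offset=1.0, ranef=ranef)
    rows = [
        {"patient_id": pid, "t": 0.0, "cd4": 100.0} for pid in ranef
    ] + [{"patient_id": pid, "t": 6.0, "cd4": 120.0} for pid in ranef]
    cohort = from_frame(pd.DataFrame(rows))
    out = sorted_crossing_probabilities(m, cohort, Threshold(350.0), 60.0)
    p = out["probabilities"]
    assert len(p) == 20
    assert (np.diff(p) >= 0).all()
    # bimodal: the high subpopulation crosses almost surely, the low one rarely
    assert out["n_above_half"] == 6
    assert out["frac_above_half"] == pytest.approx(0.3)
    # output is a permutation of the per-patient values
    direct = sorted(
        cumulative_crossing_prob(m, pid, Threshold(350.0), 60.0) for pid in ranef
    )
    np.testing.assert_allclose(p, direct, atol=1e-12)


def _bootstrap_cohort(rng, n=14, identical=False):
    rows = []
    base_t = np.array([0.0, 2.0, 6.0, 12.0, 20.0])
    # fixed off-curve wiggle keeps sigma^2 estimable even when every
    # patient contributes the identical profile
    base_y = 5.0 + 0.25 * np.log(base_t + 1.0) + np.array([0.05, -0.08, 0.1, -0.04, 0.06])
    for i in range(n):
        y = base_y if identical else base_y + rng.normal(0, 0.3) + rng.normal(0, 0.15, base_t.size)
        for t, yy in zip(base_t, y):
            rows.append({"patient_id": f"p{i}", "t": t, "cd4": float(np.exp(yy))})
    return from_frame(pd.DataFrame(rows))


def test_bootstrap_seeded_reproducibility(rng):
    cohort = _bootstrap_cohort(rng)
    spec = FPSpec((0.0, 0.5), 1.0, "intercept")
    kw = dict(spec=spec, B=8, seed=5, horizon=60.0)
    ci1 = bootstrap_crossing_ci(cohort, "p0", Threshold(350.0), **kw)
    ci2 = bootstrap_crossing_ci(cohort, "p0", Threshold(350.0), **kw)
    assert (ci1.lower, ci1.upper, ci1.se) == (ci2.lower, ci2.upper, ci2.se)
    assert ci1.replicates == 8


def test_bootstrap_identical_patients_zero_width(rng):
    cohort = _bootstrap_cohort(rng, identical=True)
    spec = FPSpec((0.0, 0.5), 1.0, "intercept")
    ci = bootstrap_crossing_ci(cohort, "p0", Threshold(350.0), spec=spec, B=8, seed=1, horizon=60.0)
    assert ci.upper - ci.lower < 0.2
    assert abs(ci.point - ci.lower) < 0.2


def test_bootstrap_unknown_patient(rng):
    cohort = _bootstrap_cohort(rng)
    with pytest.raises(KeyError):
        bootstrap_crossing_ci(
            cohort, "ghost", Threshold(350.0), spec=FPSpec((0.0, 0.5)), B=2, seed=0
        )


def test_eq3_matches_monte_carlo_single_patient(rng):
    """The product-form expectation agrees with brute-force first-crossing
    simulation of independent Gaussian visits on the same grid."""
    b = {"p": np.array([-0.3, 0.02, 0.01])}
    m = manual_model([5.1, 0.08, 0.07], (0.0, 0.5), sigma2=0.2**2, time_offset=1.0, ranef=b)
    th = Threshold(350.0)
    horizon, spacing = 120, 1.0
    dist = expected_crossing_time(m, "p", th, horizon, spacing)
    grid = dist.grid
    from cd4traj.fp import build_design

    X, Z = build_design(grid, m.spec_)
    mu = X @ m.beta_ + Z @ b["p"]
    draws = mu + rng.normal(0, 0.2, size=(40_000, grid.size))
    crossed = draws >= th.tau
    any_cross = crossed.any(axis=1)
    first_t = grid[crossed[any_cross].argmax(axis=1)]
    mc_mean = first_t.mean()
    mc_se = first_t.std(ddof=1) / math.sqrt(len(first_t))
    assert dist.expected_time_conditional == pytest.approx(mc_mean, abs=3 * mc_se)
    assert dist.residual_mass == pytest.approx(1.0 - any_cross.mean(), abs=0.01)
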