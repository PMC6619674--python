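"""Mixed-model fitting, empirical-Bayes prediction and AIC selection."""

import numpy as np
import pandas as pd
import pytest

from cd4traj.cohort import from_frame
from cd4traj.fp import FPSpec, build_design
from cd4traj.lmm import (
    FPMixedModel,
    FPModelSelector,
    InsufficientDataError,
    empirical_bayes,
    fit_fp_lmm,
    rank_candidates,
    select_fp_model,
)
from conftest import manual_model


def _balanced_cohort(rng, n=60, times=(0.0, 3.0, 6.0, 12.0, 24.0)):
    rows = []
    for i in range(n):
        b0 = rng.normal(0, 0.5)
        for t in times:
            y = 5.2 + 0.3 * np.log(t + 1) + b0 + rng.normal(0, 0.3)
            rows.append({"patient_id": i, "t": t, "cd4": float(np.exp(y))})
    return from_frame(pd.DataFrame(rows))


def test_balanced_fit_reproduces_grand_mean(rng):
    """With an intercept in the fixed design and a balanced cohort, the
    marginal residuals of the ML fit average to zero, so the mean fitted
    value equals the grand mean of the responses."""
    cohort = _balanced_cohort(rng)
    m = fit_fp_lmm(cohort, FPSpec((0.0,), 1.0, "intercept"), method="ml")
    assert m.converged_
    v = cohort.visits
    fitted = m.predict(v["t"].to_numpy(), groups=v["patient_id"].to_numpy())
    assert fitted.mean() == pytest.approx(v["log_cd4"].mean(), abs=1e-4)


def test_single_patient_insufficient():
    df = pd.DataFrame({"patient_id": ["A"] * 3, "t": [0.0, 3.0, 6.0], "cd4": [100.0, 150, 200]})
    with pytest.raises(InsufficientDataError):
        fit_fp_lmm(from_frame(df), FPSpec((0.0, 0.5)))


def test_empirical_bayes_matches_dense_oracle():
    """BLUP from hand-set parameters equals a from-scratch dense evaluation."""
    D = np.array([[0.36, 0.05, 0.0], [0.05, 0.04, 0.01], [0.0, 0.01, 0.02]])
    beta = np.array([5.2, 0.1, 0.08])
    sigma2 = 0.16
    model = manual_model(beta, (0.0, 0.5), sigma2, D=D, time_offset=1.0)
    times = np.array([0.0, 6.0, 18.0])
    y = np.array([5.0, 5.9, 6.3])
    b = empirical_bayes(model, times, y)
    # independent evaluation with explicit matrices
    X, Z = build_design(times, model.spec_)
    V = Z @ D @ Z.T + sigma2 * np.eye(3)
    expected = D @ Z.T @ np.linalg.inv(V) @ (y - X @ beta)
    np.testing.assert_allclose(b, expected, atol=1e-10)


def test_empirical_bayes_degenerate_cases():
    model = manual_model([5.2, 0.1, 0.08], D=np.zeros((3, 3)))
    # no visits -> prior mean
    np.testing.assert_array_equal(empirical_bayes(model, [], []), np.zeros(3))
    # D = 0 -> zero vector regardless of data
    np.testing.assert_allclose(
        empirical_bayes(model, [1.0, 5.0, 9.0], [9.0, 9.0, 9.0]), np.zeros(3), atol=1e-14
    )


def test_aic_identity_and_serialization(nvp_model):
    model, _ = nvp_model
    q = model.cov_re_.shape[0]
    k = model.n_fixed_ + q * (q + 1) // 2 + 1
    assert model.aic_ == pytest.approx(-2 * model.loglik_ + 2 * k)
    d = model.to_dict()
    assert d["spec"]["powers"] == [0.0, 0.5]
    assert np.asarray(d["D"]).shape == (q, q)
    # D symmetric PSD, sigma2 positive
    np.testing.assert_allclose(model.cov_re_, model.cov_re_.T, atol=1e-10)
    assert np.linalg.eigvalsh(model.cov_re_).min() > -1e-10
    assert model.sigma2_ > 0


def test_ranef_populated_and_shrinkage(nvp_model):
    """Every patient in the fit has an EB vector, and EB estimates shrink
    toward zero: the fitted subject-specific deviation Z b_EB is never
    longer than the patient's own least-squares deviation fit Z b_OLS.

    (The inequality is guaranteed in the observation space, where the EB
    deviation is Z b_OLS filtered through eigenvalue factors
    lambda/(lambda+sigma^2) <= 1; the coefficient-space Euclidean norm can
    grow under an anisotropic D.)"""
    model, sub = nvp_model
    from cd4traj.cohort import split_periods

    est, _ = split_periods(sub, 30.0)
    assert set(model.random_effects_) == set(est.patient_ids)
    q = model.cov_re_.shape[0]
    checked = 0
    for pid in est.patient_ids:
        v = est.patient(pid)
        t, y = v["t"].to_numpy(float), v["log_cd4"].to_numpy(float)
        X, Z = build_design(t, model.spec_)
        if len(t) <= q or np.linalg.matrix_rank(Z) < q:
            continue
        b_ols, *_ = np.linalg.lstsq(Z, y - X @ model.beta_, rcond=None)
        b_eb = model.random_effects_[pid]
        assert np.linalg.norm(Z @ b_eb) <= np.linalg.norm(Z @ b_ols) + 1e-8
        checked += 1
    assert checked >= 5


def test_reml_vs_ml_beta_close(rng):
    cohort = _balanced_cohort(rng, n=150)
    ml = fit_fp_lmm(cohort, FPSpec((0.0,), 1.0, "intercept"), method="ml")
    reml = fit_fp_lmm(cohort, FPSpec((0.0,), 1.0, "intercept"), method="reml")
    np.testing.assert_allclose(ml.beta_, reml.beta_, rtol=0.01)


def test_rank_candidates_tie_break():
    table = pd.DataFrame(
        {
            "order": [2, 1, 2, 2],
            "powers": [(0.0, 1.0), (1.0,), (0.0, 0.5), (0.0, 0.5)],
            "loglik": [-10.0] * 4,
            "aic": [24.0, 24.0, 24.0, 30.0],
            "converged": [True, True, True, True],
        }
    )
    ranked = rank_candidates(table)
    assert ranked.iloc[0]["powers"] == (1.0,)  # smaller order wins the tie
    assert ranked.iloc[1]["powers"] == (0.0, 0.5)  # then lexicographic powers
    with pytest.raises(RuntimeError):
        rank_candidates(table.assign(converged=False))


def test_select_fp_model_small_grid(rng):
    """On data generated from a log mean, the scan over a small grid picks
    the log power and reports one row per candidate."""
    cohort = _balanced_cohort(rng, n=80, times=(0.0, 1.0, 3.0, 6.0, 12.0, 24.0, 48.0))
    best, table = select_fp_model(
        cohort, orders=(1,), grid=(-1.0, 0.0, 1.0), random_structure="intercept"
    )
    assert len(table) == 3
    assert best.powers == (0.0,)
    assert {"order", "powers", "loglik", "aic", "converged"} <= set(table.columns)


def test_select_recovers_fp2_under_strong_curvature():
    """With strong curvature and low noise the AIC scan recovers the
    generating FP2 power pair (restricted grid keeps the test fast)."""
    import numpy as np
    from cd4traj.simulate import GroupConfig, SimulationConfig, simulate_cohort

    sds = np.array([0.4, 0.05, 0.02])
    world = SimulationConfig(
        groups=(GroupConfig("NVP", 300, (5.2, 0.4, 0.3), (0.0, 0.5)),),
        D=tuple(map(tuple, np.diag(sds**2))),
        sigma2=0.2**2,
    )
    for seed in (0, 1):
        cohort, _ = simulate_cohort(world, seed=seed)
        best, _t = select_fp_model(
            cohort, grid=(-1.0, 0.0, 0.5, 1.0), random_structure="intercept"
        )
        assert best.powers == (0.0, 0.5)


def test_selector_estimator_api(rng):
    cohort = _balanced_cohort(rng, n=60, times=(0.0, 2.0, 6.0, 15.0, 30.0))
    v = cohort.visits
    sel = FPModelSelector(
        orders=(1,), grid=(0.0, 1.0), random_structure="intercept", refit_method="reml"
    )
    sel.fit(v["t"].to_numpy(), v["log_cd4"].to_numpy(), groups=v["patient_id"].to_numpy())
    assert sel.best_spec_.order == 1
    assert sel.best_model_.converged_
    pred = sel.predict(v["t"].to_numpy()[:5], groups=v["patient_id"].to_numpy()[:5])
    assert pred.shape == (5,)
    # sklearn param plumbing
    from sklearn.base import clone

    assert clone(sel).get_params()["grid"] == (0.0, 1.0)


def test_unseen_patient_population_prediction(nvp_model):
    model, _ = nvp_model
    with pytest.warns(UserWarning, match="unseen"):
        pop = model.predict(np.array([6.0]), groups=np.array(["nobody"]))
    X, _ = build_design(np.array([6.0]), model.spec_)
    assert pop[0] == pytest.approx(float((X @ model.beta_)[0]))
    with pytest.raises(KeyError):
        model.predict(np.array([6.0]), groups=np.array(["nobody"]), strict=True)
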