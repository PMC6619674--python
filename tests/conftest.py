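import warnings

import numpy as np
import pandas as pd
import pytest

from cd4traj import FPMixedModel, FPSpec, default_cohort_config, simulate_cohort
from cd4traj.cohort import from_frame
from cd4traj.lmm import fit_fp_lmm

# statsmodels is chatty about optimizer retries on small cohorts
warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")


def manual_model(
    beta,
    powers=(0.0, 0.5),
    sigma2=0.16,
    D=None,
    ranef=None,
    time_offset=0.0,
    window=(0.0, 30.0),
):
    """An FPMixedModel with hand-set parameters, bypassing any fitting."""
    m = FPMixedModel(powers=powers, time_offset=time_offset)
    m.spec_ = FPSpec(tuple(powers), time_offset, "all")
    m.beta_ = np.asarray(beta, dtype=float)
    m.beta_se_ = np.zeros_like(m.beta_)
    q = len(beta)
    m.cov_re_ = np.asarray(D, dtype=float) if D is not None else np.zeros((q, q))
    m.sigma2_ = float(sigma2)
    m.random_effects_ = dict(ranef or {})
    m.loglik_ = np.nan
    m.aic_ = np.nan
    m.converged_ = True
    m.window_ = window
    m.method_ = "manual"
    m.n_obs_ = 0
    return m


def tiny_cohort_frame():
    """Three visits, two patients, with full covariates."""
    return pd.DataFrame(
        {
            "patient_id": ["A", "A", "B"],
            "visit_month": [0.0, 6.0, 3.0],
            "cd4": [150, 250, 200],
            "gender": ["F", "F", "M"],
            "age": [30, 30, 41],
            "who_stage": [3, 3, 2],
            "regimen": ["NVP", "NVP", "EFV"],
            "backbone": ["AZT", "AZT", "AZT"],
        }
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """Moderate two-group cohort from the default generator (seed 7)."""
    cfg = default_cohort_config(150, 80, seed=7)
    cohort, truth = simulate_cohort(cfg, seed=7)
    return cohort, truth


@pytest.fixture(scope="session")
def nvp_model(sim_cohort):
    """REML fit of the true NVP spec on the NVP group's 0-30 month window."""
    from cd4traj.cohort import split_periods

    cohort, _ = sim_cohort
    sub = cohort.by_regimen()["NVP"]
    est, _pred = split_periods(sub, 30.0)
    model = fit_fp_lmm(est, FPSpec((0.0, 0.5), 1.0, "all"), method="reml")
    return model, sub


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
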