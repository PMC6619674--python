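"""Model-based time to cross a CD4 threshold.

Given a fitted mixed model, a patient's log CD4 at an evaluation time t is
Gaussian with mean mu_i(t) = X(t) beta + Z(t) b_i and residual variance
sigma^2 (conditioning on the empirical-Bayes random effects b_i).  With
visits treated as conditionally independent given b_i, the probability
that the patient first reaches the threshold tau = ln(CD4 threshold) at
the j-th evaluation time is

    S_ij = [prod_{k<j} Phi((tau - mu_i(t_k)) / sigma)] * [1 - Phi((tau - mu_i(t_j)) / sigma)],

a discrete first-crossing mass over the evaluation grid.  The expected
crossing time is sum_j t_j S_ij, truncated at a finite horizon; both the
truncated (mass-deficient) sum and its renormalised conditional version
are reported together with the residual never-crossed-within-horizon mass.

Uncertainty comes from a case-resampling bootstrap: the focal patient is
held out, the remaining N-1 patients are resampled with replacement, the
focal patient is appended, the model is refit with the same FP spec, and
the expected crossing time is recomputed.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortData, from_frame
from .fp import FPSpec, build_design
from .lmm import FPMixedModel, fit_fp_lmm

logger = logging.getLogger(__name__)

__all__ = [
    "Threshold",
    "CrossingDistribution",
    "BootstrapCI",
    "phi_tilde",
    "crossing_mass",
    "expected_crossing_time",
    "cumulative_crossing_prob",
    "sorted_crossing_probabilities",
    "bootstrap_crossing_ci",
    "crossing_table",
]

#: default evaluation horizon (months) and grid spacing
DEFAULT_HORIZON = 120.0
DEFAULT_SPACING = 1.0


@dataclass(frozen=True)
class Threshold:
    """A CD4 threshold on both scales: cells/mm^3 and tau = ln(CD4)."""

    cd4_value: float
    tau: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tau is None:
            object.__setattr__(self, "tau", math.log(self.cd4_value))
        elif abs(self.tau - math.log(self.cd4_value)) > 1e-12:
            raise ValueError(
                f"tau={self.tau} is not ln({self.cd4_value}) = {math.log(self.cd4_value)}"
            )

    @classmethod
    def from_cd4(cls, cd4_value: float) -> "Threshold":
        return cls(float(cd4_value))


def _mu(model: FPMixedModel, patient_id, t) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    X, Z = build_design(t, model.spec_)
    mu = X @ model.beta_[: X.shape[1]]
    b = model.random_effects_.get(patient_id)
    if b is not None:
        mu = mu + Z @ b
    return mu


def phi_tilde(model: FPMixedModel, patient_id, t, threshold: Threshold) -> np.ndarray | float:
    """Probability the patient's log CD4 at time t lies below the threshold.

    ``Phi((tau - mu_i(t)) / sigma)`` with the subject-specific mean using
    both fixed and empirical-Bayes random effects.
    """
    if model.sigma2_ <= 0:
        raise ValueError(f"non-positive residual variance {model.sigma2_}")
    scalar = np.isscalar(t)
    out = stats.norm.cdf((threshold.tau - _mu(model, patient_id, t)) / math.sqrt(model.sigma2_))
    return float(out[0]) if scalar else out


@dataclass
class CrossingDistribution:
    """First-crossing mass of one patient over an evaluation grid."""

    patient_id: object
    threshold: Threshold
    grid: np.ndarray  # evaluation times (months), strictly increasing
    masses: np.ndarray  # S_ij per grid point
    residual_mass: float  # probability of not crossing within the horizon
    horizon: float
    warnings_: list = field(default_factory=list)

    @property
    def expected_time_unconditional(self) -> float:
        """Truncated sum  sum_j t_j S_ij  (mass-deficient)."""
        return float(self.grid @ self.masses)

    @property
    def expected_time_conditional(self) -> float:
        """Expected crossing time given crossing within the horizon."""
        total = float(self.masses.sum())
        if total <= 0:
            return math.nan
        return float(self.grid @ self.masses) / total

    def cumulative_prob(self, t: float) -> float:
        """Probability of having crossed by time t (within the grid)."""
        return float(self.masses[self.grid <= t].sum())

    def to_dict(self) -> dict:
        return {
            "patient_id": str(self.patient_id),
            "cd4_threshold": self.threshold.cd4_value,
            "tau": self.threshold.tau,
            "horizon": self.horizon,
            "expected_time_unconditional": self.expected_time_unconditional,
            "expected_time_conditional": self.expected_time_conditional,
            "residual_mass": self.residual_mass,
            "warnings": list(self.warnings_),
        }


def crossing_mass(
    model: FPMixedModel, patient_id, grid, threshold: Threshold
) -> CrossingDistribution:
    """First-crossing masses S_ij on an arbitrary strictly increasing grid.

    ``S_ij = [prod_{k<j} phi_ik] * (1 - phi_ij)`` and the residual mass is
    the product of all below-threshold probabilities, so the masses and the
    residual always sum to one (telescoping identity).
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("evaluation grid must be strictly increasing")
    phi = np.asarray(phi_tilde(model, patient_id, grid, threshold))
    cum = np.concatenate([[1.0], np.cumprod(phi)])  # cum[j] = prod_{k<=j} phi_k
    masses = cum[:-1] * (1.0 - phi)
    return CrossingDistribution(
        patient_id=patient_id,
        threshold=threshold,
        grid=grid,
        masses=masses,
        residual_mass=float(cum[-1]),
        horizon=float(grid[-1]),
    )


def expected_crossing_time(
    model: FPMixedModel,
    patient_id,
    threshold: Threshold,
    horizon: float = DEFAULT_HORIZON,
    spacing: float = DEFAULT_SPACING,
) -> CrossingDistribution:
    """Expected time to cross a threshold on a regular monthly grid.

    The grid runs ``spacing, 2*spacing, ..., horizon``; the infinite series
    is truncated there, so both the truncated (unconditional) expectation
    and the renormalised conditional expectation are exposed along with the
    residual mass.  A residual mass above 0.5 attaches a warning: the
    conditional expectation then conditions on a minority event.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    n = int(round(horizon / spacing))
    grid = spacing * np.arange(1, n + 1)
    dist = crossing_mass(model, patient_id, grid, threshold)
    if dist.residual_mass > 0.5:
        msg = (
            f"residual mass {dist.residual_mass:.3f} > 0.5: patient "
            f"{patient_id!r} is unlikely to cross CD4 {threshold.cd4_value:g} "
            f"within {horizon:g} months; conditional expectation is fragile"
        )
        dist.warnings_.append(msg)
        logger.warning(msg)
    return dist


def cumulative_crossing_prob(
    model: FPMixedModel,
    patient_id,
    threshold: Threshold,
    t: float,
    spacing: float = DEFAULT_SPACING,
) -> float:
    """Probability of crossing the threshold by time t (monthly grid)."""
    grid = spacing * np.arange(1, int(round(t / spacing)) + 1)
    if grid.size == 0:
        return 0.0
    phi = np.asarray(phi_tilde(model, patient_id, grid, threshold))
    return float(1.0 - np.prod(phi))


def sorted_crossing_probabilities(
    model: FPMixedModel,
    cohort: CohortData,
    threshold: Threshold,
    t: float,
    spacing: float = DEFAULT_SPACING,
) -> dict:
    """Per-patient crossing probabilities by time t, sorted ascending.

    Returns the sorted probabilities, the patient order, and the count and
    fraction of patients whose probability exceeds 0.5.
    """
    ids = list(cohort.patient_ids)
    probs = np.array(
        [cumulative_crossing_prob(model, pid, threshold, t, spacing) for pid in ids]
    )
    order = np.argsort(probs, kind="mergesort")
    sorted_probs = probs[order]
    n_above = int((probs > 0.5).sum())
    return {
        "probabilities": sorted_probs,
        "patient_ids": [ids[i] for i in order],
        "n_above_half": n_above,
        "frac_above_half": n_above / len(ids) if ids else math.nan,
        "t": t,
        "cd4_threshold": threshold.cd4_value,
    }


@dataclass
class BootstrapCI:
    """Percentile bootstrap interval for an expected crossing time."""

    point: float  # months, from the full-data fit
    se: float
    lower: float
    upper: float
    replicates: int
    n_failed: int
    seed: int
    order_violated: bool = False  # lower <= point <= upper failed (skewed resamples)

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def bootstrap_crossing_ci(
    cohort: CohortData,
    patient_id,
    threshold: Threshold,
    spec: FPSpec,
    B: int = 1000,
    seed: int = 0,
    horizon: float = DEFAULT_HORIZON,
    spacing: float = DEFAULT_SPACING,
    method: str = "ml",
    conditional: bool = True,
    max_failure_frac: float = 0.2,
) -> BootstrapCI:
    """Case-resampling bootstrap CI for one patient's expected crossing time.

    Each replicate removes the focal patient, resamples N-1 patients with
    replacement from the rest, appends the focal patient, refits the model
    with the already-selected FP spec (powers are *not* re-selected), and
    recomputes the expected crossing time.  Replicate fit failures are
    skipped and counted; more than ``max_failure_frac`` failing is an error.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    ids = list(cohort.patient_ids)
    if patient_id not in set(ids):
        raise KeyError(f"patient {patient_id!r} not in cohort")
    rng = np.random.default_rng(seed)
    others = [g for g in ids if g != patient_id]

    full = fit_fp_lmm(cohort, spec, method=method)
    point_dist = expected_crossing_time(full, patient_id, threshold, horizon, spacing)
    point = (
        point_dist.expected_time_conditional
        if conditional
        else point_dist.expected_time_unconditional
    )

    focal_visits = cohort.patient(patient_id)
    estimates = []
    n_failed = 0
    for _ in range(B):
        sampled = rng.choice(len(others), size=len(others), replace=True)
        frames = [focal_visits.assign(patient_id="__focal__")]
        for k, idx in enumerate(sampled):
            pv = cohort.visits[cohort.visits["patient_id"] == others[idx]]
            frames.append(pv.assign(patient_id=f"__bs{k}__"))
        boot = from_frame(pd.concat(frames, ignore_index=True))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_fp_lmm(boot, spec, method=method)
            if not m.converged_:
                n_failed += 1
                continue
            d = expected_crossing_time(m, "__focal__", threshold, horizon, spacing)
            estimates.append(
                d.expected_time_conditional if conditional else d.expected_time_unconditional
            )
        except Exception as err:  # noqa: BLE001 - any replicate failure is skipped
            logger.debug("bootstrap replicate failed: %s", err)
            n_failed += 1
    if n_failed > max_failure_frac * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to fit (> {max_failure_frac:.0%})"
        )
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est)]
    lower, upper = np.percentile(est, [2.5, 97.5])
    violated = not (lower <= point <= upper)
    if violated:
        logger.warning(
            "percentile interval (%.3f, %.3f) does not bracket the point %.3f "
            "(skewed resampling distribution)",
            lower,
            upper,
            point,
        )
    return BootstrapCI(
        point=float(point),
        se=float(est.std(ddof=1)),
        lower=float(lower),
        upper=float(upper),
        replicates=len(est),
        n_failed=n_failed,
        seed=seed,
        order_violated=violated,
    )


def crossing_table(
    model: FPMixedModel,
    patient_ids,
    thresholds=(200, 350, 500),
    horizon: float = DEFAULT_HORIZON,
    spacing: float = DEFAULT_SPACING,
) -> pd.DataFrame:
    """Per-patient expected crossing times for a set of CD4 thresholds.

    One row per (patient, threshold) with both the conditional and the
    truncated unconditional expectations and the residual mass.
    """
    rows = []
    for pid in patient_ids:
        for cd4 in thresholds:
            th = Threshold.from_cd4(cd4)
            d = expected_crossing_time(model, pid, th, horizon, spacing)
            rows.append(
                {
                    "patient_id": pid,
                    "cd4_threshold": cd4,
                    "expected_time_conditional": d.expected_time_conditional,
                    "expected_time_unconditional": d.expected_time_unconditional,
                    "residual_mass": d.residual_mass,
                }
            )
    return pd.DataFrame(rows)
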