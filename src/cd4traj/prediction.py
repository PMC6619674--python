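"""Subject-specific prediction diagnostics.

A model fitted on the early estimation window (0--30 months by default)
predicts each patient's log CD4 at later visits via the fixed effects plus
the patient's empirical-Bayes random effects.  Agreement is summarised by
the Pearson correlation of observed vs predicted values separately within
the estimation and prediction windows, by last-observation pairs, and by
kernel density overlays of observed and predicted values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortData
from .lmm import FPMixedModel

__all__ = [
    "predict_trajectory",
    "obs_pred_correlation",
    "prediction_report",
    "predict_last_observation",
    "density_compare",
    "PredictionReport",
]


class UndefinedCorrelationError(ValueError):
    """Observed or predicted series is constant; Pearson r undefined."""


def predict_trajectory(model: FPMixedModel, patient_id, times) -> np.ndarray:
    """Predicted log CD4 trajectory ``X beta + Z b_i`` for one patient.

    A patient unseen at fit time gets the population trajectory (b = 0)
    with a warning; see ``FPMixedModel.predict`` for strict mode.
    """
    return model.predict_patient(patient_id, times)


def _matched_pairs(model: FPMixedModel, cohort: CohortData) -> pd.DataFrame:
    v = cohort.visits
    pred = model.predict(v["t"].to_numpy(float), groups=v["patient_id"].to_numpy())
    return pd.DataFrame(
        {
            "patient_id": v["patient_id"].to_numpy(),
            "t": v["t"].to_numpy(float),
            "observed": v["log_cd4"].to_numpy(float),
            "predicted": pred,
        }
    )


def obs_pred_correlation(
    model: FPMixedModel, cohort: CohortData, window: str = "estimation", cutoff: float | None = None
) -> float:
    """Pearson correlation of observed vs predicted log CD4 in one window.

    ``window`` is ``"estimation"`` (visits at t <= cutoff) or
    ``"prediction"`` (t > cutoff); the cutoff defaults to the upper edge of
    the model's estimation window.
    """
    if cutoff is None:
        if model.window_ is None or model.window_[1] is None:
            raise ValueError("model has no bounded estimation window; pass cutoff explicitly")
        cutoff = float(model.window_[1])
    pairs = _matched_pairs(model, cohort)
    mask = pairs["t"] <= cutoff if window == "estimation" else pairs["t"] > cutoff
    sub = pairs[mask]
    if len(sub) < 2:
        raise ValueError(f"fewer than 2 matched pairs in the {window} window")
    if sub["observed"].std() == 0 or sub["predicted"].std() == 0:
        raise UndefinedCorrelationError(f"constant series in the {window} window")
    return float(stats.pearsonr(sub["observed"], sub["predicted"])[0])


def predict_last_observation(
    model: FPMixedModel, cohort: CohortData, cutoff: float = 30.0
) -> pd.DataFrame:
    """Observed vs predicted log CD4 at each patient's last visit.

    Only patients whose last visit falls strictly after the estimation
    cutoff are reported — for the rest the "last observation" was already
    available to the fit, so the comparison would be circular.
    """
    last = cohort.visits.groupby("patient_id", sort=False).last().reset_index()
    last = last[last["t"] > cutoff]
    if last.empty:
        return pd.DataFrame(columns=["patient_id", "t", "observed", "predicted"])
    pred = model.predict(last["t"].to_numpy(float), groups=last["patient_id"].to_numpy())
    return pd.DataFrame(
        {
            "patient_id": last["patient_id"].to_numpy(),
            "t": last["t"].to_numpy(float),
            "observed": last["log_cd4"].to_numpy(float),
            "predicted": pred,
        }
    )


def density_compare(observed, predicted, gridsize: int = 512) -> pd.DataFrame:
    """Gaussian-kernel density estimates of two samples on a common grid.

    Silverman bandwidth; the grid spans both samples plus 3 pooled standard
    deviations so each density integrates to 1 (within 1e-3) on the grid.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size < 5 or predicted.size < 5:
        raise ValueError("need at least 5 points per sample for a density estimate")
    pad = 3.0 * max(observed.std(), predicted.std(), 1e-6)
    lo = min(observed.min(), predicted.min()) - pad
    hi = max(observed.max(), predicted.max()) + pad
    grid = np.linspace(lo, hi, gridsize)
    kde_obs = stats.gaussian_kde(observed, bw_method="silverman")
    kde_pred = stats.gaussian_kde(predicted, bw_method="silverman")
    return pd.DataFrame(
        {"grid": grid, "observed_density": kde_obs(grid), "predicted_density": kde_pred(grid)}
    )


@dataclass
class PredictionReport:
    """Observed/predicted pairs with per-window correlations."""

    pairs: pd.DataFrame  # patient_id, t, observed, predicted, window
    correlations: dict = field(default_factory=dict)
    last_observation: pd.DataFrame | None = None

    def write_csv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"correlations": self.correlations}, indent=2))


def prediction_report(
    model: FPMixedModel, cohort: CohortData, cutoff: float = 30.0
) -> PredictionReport:
    """Full observed-vs-predicted diagnostic for both windows."""
    pairs = _matched_pairs(model, cohort)
    pairs["window"] = np.where(pairs["t"] <= cutoff, "estimation", "prediction")
    corr = {}
    for w in ("estimation", "prediction"):
        sub = pairs[pairs["window"] == w]
        if len(sub) >= 2 and sub["observed"].std() > 0 and sub["predicted"].std() > 0:
            corr[w] = float(stats.pearsonr(sub["observed"], sub["predicted"])[0])
    last = predict_last_observation(model, cohort, cutoff)
    if len(last) >= 2 and last["observed"].std() > 0:
        corr["last_observation"] = float(stats.pearsonr(last["observed"], last["predicted"])[0])
    return PredictionReport(pairs, corr, last)
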