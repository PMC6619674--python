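"""Observed time to cross a CD4 threshold: KM curves and log-rank tests.

The observed counterpart of the model-based crossing time: per patient,
the first clinic visit at which log CD4 reaches or exceeds tau counts as
the event; patients never observed above the threshold are right-censored
at their last visit.  Kaplan–Meier estimation, median survival with
log-log Greenwood confidence limits and the two-group log-rank test are
delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

from .cohort import CohortData
from .crossing import Threshold

__all__ = [
    "observed_crossing",
    "cohort_crossing_times",
    "km_curve",
    "logrank_test",
    "crossing_proportions",
    "SurvivalEstimate",
]


def observed_crossing(visits: pd.DataFrame, threshold: Threshold) -> tuple[float, int]:
    """First observed crossing of one patient: (time in months, event 0/1).

    The event is the first visit (the first visit itself included) with
    ``log_cd4 >= tau``; a patient never observed at or above the threshold
    is censored at the last visit time.
    """
    if len(visits) == 0:
        raise ValueError("patient has no visits")
    v = visits.sort_values("t")
    above = v["log_cd4"].to_numpy(float) >= threshold.tau
    if above.any():
        return float(v["t"].to_numpy(float)[above.argmax()]), 1
    return float(v["t"].iloc[-1]), 0


def cohort_crossing_times(
    cohort: CohortData,
    threshold: Threshold,
    exclude_baseline_above: bool = True,
) -> pd.DataFrame:
    """Observed crossing time and event indicator for every patient.

    By default patients already at or above the threshold at their first
    visit are excluded: a "time to cross" starting above the line is not a
    meaningful reconstitution time.  With ``exclude_baseline_above=False``
    the literal first-crossing rule applies and such patients are events at
    their first visit time.
    """
    rows = []
    for pid in cohort.patient_ids:
        v = cohort.patient(pid)
        if exclude_baseline_above and float(v["log_cd4"].iloc[0]) >= threshold.tau:
            continue
        time, event = observed_crossing(v, threshold)
        rows.append({"patient_id": pid, "time": time, "event": event})
    return pd.DataFrame(rows, columns=["patient_id", "time", "event"])


@dataclass
class SurvivalEstimate:
    """Kaplan–Meier estimate of the crossing-time distribution."""

    times: np.ndarray  # event/censoring times per patient
    events: np.ndarray  # 1 = crossed, 0 = censored
    curve: pd.DataFrame  # step function: time, survival
    median: float  # months; inf if never reached
    median_ci: tuple[float, float]
    label: str | None = None

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)

    def survival_at(self, t: float) -> float:
        """S(t): probability of not yet having crossed at time t."""
        s = self.curve[self.curve["time"] <= t]["survival"]
        return float(s.iloc[-1]) if len(s) else 1.0


def km_curve(times, events, label: str | None = None) -> SurvivalEstimate:
    """Product-limit estimate of the time-to-cross distribution.

    The median is the smallest time with S(t) <= 0.5 (infinity — "not
    reached" — when survival never falls that far); its 95% CI uses
    lifelines' log-log Greenwood limits.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(times, events, label=label or "KM")
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return SurvivalEstimate(times, events, curve, median, (lo, hi), label)


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if ea.sum() == 0 or eb.sum() == 0:
        warnings.warn("a group has zero events; log-rank test is weakly informative",
                      stacklevel=2)
    res = _ll_logrank(times_a, times_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def compare_groups(
    cohort: CohortData,
    threshold: Threshold,
    group_column: str = "regimen",
    exclude_baseline_above: bool = True,
) -> dict:
    """KM estimate per group plus the log-rank comparison of the first two."""
    out: dict = {"groups": {}}
    tables = {}
    for name, sub in cohort.by_regimen().items():
        tab = cohort_crossing_times(sub, threshold, exclude_baseline_above)
        if tab.empty:
            continue
        tables[name] = tab
        est = km_curve(tab["time"], tab["event"], label=name)
        out["groups"][name] = est
    names = list(tables)
    if len(names) >= 2:
        a, b = tables[names[0]], tables[names[1]]
        stat, p = logrank_test(a["time"], a["event"], b["time"], b["event"])
        out["logrank"] = {"groups": names[:2], "statistic": stat, "p_value": p}
    return out


def crossing_proportions(
    cohort: CohortData,
    threshold: Threshold,
    horizons,
    baseline_max_cd4: float | None = None,
    exclude_baseline_above: bool = True,
) -> dict[float, float]:
    """Fraction of patients with an observed crossing by each horizon.

    ``baseline_max_cd4`` restricts the denominator to patients whose first
    visit CD4 is strictly below that value (e.g. 200 to mirror the
    low-baseline subgroup).  Proportions are cumulative, hence
    non-decreasing in the horizon.
    """
    base = cohort.baseline().set_index("patient_id")
    ids = base.index
    if baseline_max_cd4 is not None:
        ids = base.index[base["cd4"] < baseline_max_cd4]
    sub = cohort.subset(ids)
    tab = cohort_crossing_times(sub, threshold, exclude_baseline_above)
    if tab.empty:
        raise ValueError("no patients pass the baseline filter")
    out = {}
    for h in horizons:
        if h <= 0:
            raise ValueError("horizons must be positive")
        out[float(h)] = float(((tab["event"] == 1) & (tab["time"] <= h)).mean())
    return out
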