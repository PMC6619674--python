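"""Long-format CD4 cohort container, validation, filters and period splits.

The single input currency of the pipeline is a long table of clinic visits:
one row per visit with the patient identifier, months since ART initiation,
the absolute CD4 count (cells/mm^3) and per-patient baseline covariates
(gender, age, WHO stage, NNRTI regimen, NRTI backbone).  Modelling happens
on the natural-log scale, so ``log_cd4 = ln(cd4)`` is attached on load.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VISIT_COLUMNS = ["patient_id", "t", "cd4", "log_cd4"]
COVARIATE_COLUMNS = ["gender", "age", "who_stage", "regimen", "backbone"]

#: default mapping from raw CSV column names to internal names
DEFAULT_COLUMN_MAP = {
    "patient_id": "patient_id",
    "visit_month": "t",
    "cd4": "cd4",
    "gender": "gender",
    "age": "age",
    "who_stage": "who_stage",
    "regimen": "regimen",
    "backbone": "backbone",
}


class SchemaError(ValueError):
    """Input table is missing a required column."""


class CohortValidationError(ValueError):
    """Input rows violate a cohort invariant (non-positive CD4, duplicates...)."""


@dataclass
class CohortData:
    """Visits grouped by patient plus per-patient covariates.

    ``visits`` has columns ``patient_id, t, cd4, log_cd4`` sorted by
    ``(patient_id, t)``; ``covariates`` is indexed by ``patient_id``.
    ``provenance`` records the source file and every filter applied.
    """

    visits: pd.DataFrame
    covariates: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.visits = self.visits.reset_index(drop=True)
        _validate_visits(self.visits)

    # -- basic accessors -------------------------------------------------
    @property
    def patient_ids(self) -> np.ndarray:
        return self.visits["patient_id"].unique()

    @property
    def n_patients(self) -> int:
        return self.visits["patient_id"].nunique()

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def patient(self, patient_id) -> pd.DataFrame:
        """Visit rows of one patient, time-ordered."""
        out = self.visits[self.visits["patient_id"] == patient_id]
        if out.empty:
            raise KeyError(f"unknown patient id {patient_id!r}")
        return out

    def subset(self, patient_ids: Iterable, note: str | None = None) -> "CohortData":
        ids = pd.Index(pd.unique(pd.Series(list(patient_ids))))
        visits = self.visits[self.visits["patient_id"].isin(ids)]
        cov = self.covariates.loc[self.covariates.index.intersection(ids)]
        prov = dict(self.provenance)
        if note:
            prov.setdefault("filters", []).append(note)
        return CohortData(visits.copy(), cov.copy(), prov)

    def by_regimen(self) -> dict[str, "CohortData"]:
        """Split into one cohort per NNRTI regimen group."""
        out = {}
        for reg, cov in self.covariates.groupby("regimen", observed=True):
            out[str(reg)] = self.subset(cov.index, note=f"regimen == {reg}")
        return out

    def baseline(self) -> pd.DataFrame:
        """First visit per patient (earliest time)."""
        return self.visits.groupby("patient_id", sort=False).first().reset_index()

    # -- IO --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Re-join visits and covariates into one long table."""
        return self.visits.merge(
            self.covariates.reset_index().rename(columns={"index": "patient_id"}),
            on="patient_id",
            how="left",
        )

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame().rename(columns={"t": "visit_month"})
        df.drop(columns=["log_cd4"]).to_csv(path, index=False)

    def filter_report(self) -> dict:
        return {
            "n_patients": int(self.n_patients),
            "n_visits": int(self.n_visits),
            "filters": list(self.provenance.get("filters", [])),
            "source": self.provenance.get("source"),
        }


def _validate_visits(visits: pd.DataFrame) -> None:
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise SchemaError(f"visit table missing columns {missing}")
    if (visits["t"] < 0).any():
        bad = visits.loc[visits["t"] < 0].iloc[0]
        raise CohortValidationError(
            f"negative visit time {bad['t']} for patient {bad['patient_id']!r}"
        )
    dup = visits.duplicated(subset=["patient_id", "t"])
    if dup.any():
        bad = visits.loc[dup].iloc[0]
        raise CohortValidationError(
            f"duplicate (patient, time) pair: patient {bad['patient_id']!r} at t={bad['t']}"
        )
    if not np.allclose(visits["log_cd4"], np.log(visits["cd4"]), atol=1e-12):
        raise CohortValidationError("log_cd4 is not ln(cd4)")


def from_frame(df: pd.DataFrame, provenance: dict | None = None) -> CohortData:
    """Build a CohortData from one long table with internal column names."""
    df = df.copy()
    if "log_cd4" not in df.columns:
        if (df["cd4"] < 1).any():
            bad = df.loc[df["cd4"] < 1].iloc[0]
            raise CohortValidationError(
                f"CD4 count {bad['cd4']} < 1 for patient {bad['patient_id']!r} "
                f"(row {bad.name}); log undefined"
            )
        df["log_cd4"] = np.log(df["cd4"].astype(float))
    df = df.sort_values(["patient_id", "t"], kind="mergesort")
    visits = df[VISIT_COLUMNS].reset_index(drop=True)
    cov_cols = [c for c in COVARIATE_COLUMNS if c in df.columns]
    cov = (
        df.groupby("patient_id", sort=False)[cov_cols].first()
        if cov_cols
        else pd.DataFrame(index=pd.Index(visits["patient_id"].unique(), name="patient_id"))
    )
    return CohortData(visits, cov, provenance or {})


def load_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    cd4_offset: float = 0.0,
) -> CohortData:
    """Read and validate a long-format cohort CSV.

    Parameters
    ----------
    path
        Comma-separated file with a header row (UTF-8).
    column_map
        Optional mapping ``{raw_name: internal_name}`` overriding the
        default column names (``patient_id, visit_month, cd4, gender, age,
        who_stage, regimen, backbone``).
    cd4_offset
        Additive offset applied to the CD4 count before the log transform.
        Defaults to 0: a recorded count of 0 is treated as a data error
        rather than silently offset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    present = {src: dst for src, dst in cmap.items() if src in raw.columns}
    required = {"patient_id", "t", "cd4"}
    mapped_targets = set(present.values())
    if not required <= mapped_targets:
        raise SchemaError(
            f"missing required columns mapping to {sorted(required - mapped_targets)}; "
            f"file has {list(raw.columns)}"
        )
    df = raw.rename(columns=present)
    df["t"] = df["t"].astype(float)
    df["cd4"] = df["cd4"].astype(float) + cd4_offset
    if (df["cd4"] < 1).any():
        bad = df.loc[df["cd4"] < 1].iloc[0]
        raise CohortValidationError(
            f"CD4 count {bad['cd4']:g} < 1 for patient {bad['patient_id']!r} "
            f"(row {bad.name}); natural log undefined"
        )
    return from_frame(df, provenance={"source": str(path), "filters": []})


def apply_inclusion_filters(
    cohort: CohortData,
    min_visits: int = 2,
    regimens: tuple[str, ...] = ("NVP", "EFV"),
    backbone: str | None = "AZT",
) -> CohortData:
    """Apply the cohort inclusion criteria.

    Retains patients with at least ``min_visits`` visits (each visit carries
    a CD4 measurement by construction), an NNRTI regimen in ``regimens``
    and, when covariates include it, the stated NRTI backbone.  Counts
    removed per criterion are appended to the provenance filter log.
    Applying the filters twice is a no-op.
    """
    visits, cov = cohort.visits, cohort.covariates
    counts = visits.groupby("patient_id", sort=False).size()
    keep = set(counts[counts >= min_visits].index)
    n_visits_removed = cohort.n_patients - len(keep)

    n_regimen_removed = n_backbone_removed = 0
    if "regimen" in cov.columns:
        ok = set(cov.index[cov["regimen"].isin(regimens)])
        n_regimen_removed = len(keep - ok)
        keep &= ok
    if backbone is not None and "backbone" in cov.columns:
        ok = set(cov.index[cov["backbone"] == backbone])
        n_backbone_removed = len(keep - ok)
        keep &= ok

    notes = [
        f"min_visits>={min_visits}: removed {n_visits_removed}",
        f"regimen in {regimens}: removed {n_regimen_removed}",
    ]
    if backbone is not None:
        notes.append(f"backbone == {backbone}: removed {n_backbone_removed}")
    out = cohort.subset(sorted(keep, key=str))
    out.provenance.setdefault("filters", []).extend(notes)
    if out.n_patients == 0:
        warnings.warn("inclusion filters removed every patient", stacklevel=2)
    logger.info("inclusion filters: %s -> %s patients", cohort.n_patients, out.n_patients)
    return out


def split_periods(cohort: CohortData, cutoff: float) -> tuple[CohortData, CohortData]:
    """Partition visits into an estimation period and a prediction period.

    Visits with ``t <= cutoff`` form the estimation cohort, the rest the
    prediction cohort (the boundary visit belongs to the estimation side,
    keeping the fitted window maximal).  Visit counts are conserved.
    """
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    est_mask = cohort.visits["t"] <= cutoff
    prov = dict(cohort.provenance)

    def _half(mask: pd.Series, label: str, bounds) -> CohortData:
        v = cohort.visits[mask].copy()
        ids = pd.Index(v["patient_id"].unique())
        cov = cohort.covariates.loc[cohort.covariates.index.intersection(ids)]
        p = dict(prov)
        p["window"] = label
        p["window_bounds"] = bounds
        return CohortData(v, cov.copy(), p)

    est = _half(est_mask, f"estimation (t <= {cutoff:g})", (0.0, float(cutoff)))
    pred = _half(~est_mask, f"prediction (t > {cutoff:g})", (float(cutoff), None))
    assert est.n_visits + pred.n_visits == cohort.n_visits
    return est, pred


def person_time_summary(cohort: CohortData) -> dict:
    """Follow-up summaries: total person-years and per-100-person-years rate."""
    fu_months = cohort.visits.groupby("patient_id", sort=False)["t"].max()
    person_years = float(fu_months.sum()) / 12.0
    return {
        "n_patients": int(cohort.n_patients),
        "median_followup_months": float(fu_months.median()),
        "total_person_years": person_years,
        "per_100_person_years": 100.0 * person_years / max(cohort.n_patients, 1),
        "median_visits": float(cohort.visits.groupby("patient_id", sort=False).size().median()),
    }
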