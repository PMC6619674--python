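"""Fractional-polynomial linear mixed models for log CD4 trajectories.

The model for patient *i* at visit time *t_ij* is

    y_ij = X_ij beta + Z_ij b_i + e_ij,   b_i ~ N(0, D),  e_ij ~ N(0, sigma^2),

with the fixed design X holding an intercept plus FP basis columns (and
optional baseline covariates) and the random design Z a subset of those
columns.  Likelihood maximisation is delegated to statsmodels MixedLM;
empirical-Bayes random effects are computed here with the explicit BLUP
formula  b_i = D Z_i' V_i^{-1} (y_i - X_i beta),  V_i = Z_i D Z_i' + s2 I.

Powers are selected by scanning the FP grid and minimising the ML AIC
(REML likelihoods are not comparable across fixed-effects structures);
the chosen model is refit with REML for reporting.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .cohort import CohortData
from .fp import POWER_GRID, FPSpec, build_design, enumerate_power_grid

logger = logging.getLogger(__name__)

__all__ = [
    "FPMixedModel",
    "FPModelSelector",
    "InsufficientDataError",
    "fit_fp_lmm",
    "select_fp_model",
    "empirical_bayes",
]


class InsufficientDataError(ValueError):
    """Too few patients or visits to identify the mixed model."""


def _as_time_and_covariates(X) -> tuple[np.ndarray, np.ndarray | None]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return X, None
    if X.shape[1] == 1:
        return X[:, 0], None
    return X[:, 0], X[:, 1:]


def cohort_arrays(cohort: CohortData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, log_cd4, patient groups) arrays from a cohort."""
    v = cohort.visits
    return v["t"].to_numpy(float), v["log_cd4"].to_numpy(float), v["patient_id"].to_numpy()


class FPMixedModel(RegressorMixin, BaseEstimator):
    """Linear mixed model with a fractional-polynomial mean structure.

    Parameters
    ----------
    powers
        FP powers (sorted non-decreasing, from the conventional grid).
    time_offset
        Months added to visit times before the power transform so baseline
        (t = 0) visits stay in the log domain.
    random_structure
        ``"all"`` (random intercept + every FP term), ``"intercept"``, or a
        tuple of 1-based FP-term indices.
    method
        ``"ml"`` or ``"reml"``.
    fallback
        If True, non-convergence or a singular random-effects covariance
        triggers the ladder unstructured -> diagonal -> intercept-only.

    Attributes (after fit)
    ----------------------
    beta_ : fixed-effects vector (intercept, FP terms, covariates)
    cov_re_ : random-effects covariance D (q x q)
    sigma2_ : residual variance
    random_effects_ : dict patient id -> empirical-Bayes vector b_i
    loglik_, aic_, converged_, n_fixed_, n_vc_params_
    spec_ : the FPSpec actually fitted (after any fallback)
    window_ : (lo, hi) months of the estimation window, if known
    """

    def __init__(
        self,
        powers: Sequence[float] = (0.0, 0.5),
        time_offset: float = 1.0,
        random_structure: str | tuple[int, ...] = "all",
        method: str = "ml",
        fallback: bool = True,
        maxiter: int = 200,
    ):
        self.powers = powers
        self.time_offset = time_offset
        self.random_structure = random_structure
        self.method = method
        self.fallback = fallback
        self.maxiter = maxiter

    # ------------------------------------------------------------------
    def fit(self, X, y, groups=None):
        """Fit the model on visit-level data.

        ``X`` is an ``(n,)``/``(n,1)`` array of months since ART start
        (extra columns are taken as fixed-effect covariates), ``y`` the
        log CD4 responses and ``groups`` the patient identifiers.
        """
        if groups is None:
            raise ValueError("groups (patient identifiers) are required")
        times, cov = _as_time_and_covariates(X)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if len({len(times), len(y), len(groups)}) != 1:
            raise ValueError("X, y and groups must have equal length")

        counts = pd.Series(groups).value_counts()
        if (counts >= 2).sum() < 2:
            raise InsufficientDataError(
                f"need >= 2 patients with >= 2 visits, got {int((counts >= 2).sum())}"
            )

        ladder = [self.random_structure]
        if self.fallback:
            if self.random_structure == "all":
                ladder += ["diagonal", (1,), "intercept"]
            elif self.random_structure not in ("intercept",):
                ladder += ["intercept"]
        result = None
        for structure in ladder:
            spec, res, nvc, ok = self._fit_once(times, cov, y, groups, structure)
            result = (spec, res, nvc)
            if ok:
                if structure != ladder[0]:
                    logger.warning(
                        "random structure fell back from %r to %r", ladder[0], structure
                    )
                break
        spec, res, nvc = result
        self.spec_ = spec
        self.fallback_used_ = spec.random_structure != self.random_structure and not (
            self.random_structure == "all" and spec.random_structure == "all"
        )
        self.beta_ = np.asarray(res.fe_params, dtype=float)
        self.beta_se_ = np.asarray(res.bse_fe, dtype=float)
        self.cov_re_ = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        self.sigma2_ = float(res.scale)
        self.loglik_ = float(res.llf)
        self.converged_ = bool(res.converged)
        self.n_fixed_ = len(self.beta_)
        self.n_vc_params_ = nvc
        self.aic_ = -2.0 * self.loglik_ + 2.0 * (self.n_fixed_ + self.n_vc_params_ + 1)
        self.method_ = self.method
        self.n_obs_ = len(y)
        self.groups_ = groups
        self._cov_names = None if cov is None else cov.shape[1]
        self.window_ = getattr(self, "window_", None)

        # empirical-Bayes BLUPs for every patient in the fit
        self.random_effects_ = {}
        for g in pd.unique(groups):
            m = groups == g
            ci = cov[m] if cov is not None else None
            self.random_effects_[g] = empirical_bayes(self, times[m], y[m], ci)
        return self

    def _fit_once(self, times, cov, y, groups, structure):
        spec = FPSpec(tuple(self.powers), self.time_offset, structure if structure != "diagonal" else "all")
        X, Z = build_design(times, spec, covariates=cov, check_rank=True)
        q = Z.shape[1]
        free = None
        if structure == "diagonal" and q > 1:
            free = MixedLMParams.from_components(
                fe_params=np.ones(X.shape[1]), cov_re=np.eye(q)
            )
            nvc = q
        else:
            nvc = q * (q + 1) // 2
        model = MixedLM(y, X, groups, exog_re=Z)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(
                    reml=(self.method == "reml"),
                    free=free,
                    maxiter=self.maxiter,
                    # bfgs first: the lbfgs path can return a spurious zero
                    # intercept when a variance component hits the boundary;
                    # powell last: gradient methods flag non-convergence on
                    # boundary (D -> 0) solutions that powell accepts
                    method=["bfgs", "lbfgs", "cg", "powell"],
                )
            except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
                logger.warning("MixedLM raised %s for structure %r", err, structure)
                return spec, None, nvc, False
        # singular D also triggers fallback: the structure is over-specified
        eigvals = np.linalg.eigvalsh(np.atleast_2d(np.asarray(res.cov_re)))
        singular = q > 1 and eigvals.min() < 1e-10 * max(eigvals.max(), 1.0)
        return spec, res, nvc, bool(res.converged) and not singular

    # ------------------------------------------------------------------
    def predict(self, X, groups=None, strict: bool = False):
        """Predicted log CD4, ``X beta + Z b_i``.

        Unknown (or omitted) patients get the population prediction
        ``b_i = 0``; with ``strict=True`` an unknown patient raises.
        """
        times, cov = _as_time_and_covariates(X)
        Xd, Zd = build_design(times, self.spec_, covariates=cov)
        mu = Xd @ self.beta_
        if groups is not None:
            groups = np.asarray(groups)
            for g in pd.unique(groups):
                b = self.random_effects_.get(g)
                if b is None:
                    if strict:
                        raise KeyError(f"patient {g!r} not in the fitted model")
                    warnings.warn(
                        f"patient {g!r} unseen at fit time; population prediction used",
                        stacklevel=2,
                    )
                    continue
                m = groups == g
                mu[m] += Zd[m] @ b
        return mu

    def predict_patient(self, patient_id, times) -> np.ndarray:
        """Subject-specific trajectory at arbitrary times (scalar or array)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        return self.predict(times, groups=np.repeat(patient_id, times.size))

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spec": self.spec_.to_dict(),
            "beta": self.beta_.tolist(),
            "beta_se": self.beta_se_.tolist(),
            "D": self.cov_re_.tolist(),
            "sigma2": self.sigma2_,
            "loglik": self.loglik_,
            "aic": self.aic_,
            "method": self.method_,
            "converged": self.converged_,
            "window": self.window_,
            "n_obs": self.n_obs_,
        }

    def ranef_frame(self) -> pd.DataFrame:
        """Per-patient empirical-Bayes estimates keyed by patient_id."""
        q = self.cov_re_.shape[0]
        cols = ["b0"] + [f"b{i}" for i in range(1, q)]
        return pd.DataFrame.from_dict(self.random_effects_, orient="index", columns=cols).rename_axis(
            "patient_id"
        )


def empirical_bayes(model: FPMixedModel, times, y, covariates=None) -> np.ndarray:
    """BLUP of one patient's random effects given a fitted model.

    Evaluates ``D Z' V^{-1} (y - X beta)`` with ``V = Z D Z' + sigma2 I``.
    A patient with no visits gets the prior mean (zero vector), as does the
    degenerate no-between-subject-variance limit D -> 0.
    """
    D = model.cov_re_
    q = D.shape[0]
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        return np.zeros(q)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    X, Z = build_design(times, model.spec_, covariates=covariates)
    V = Z @ D @ Z.T + model.sigma2_ * np.eye(len(times))
    try:
        sol = linalg.solve(V, y - X @ model.beta_, assume_a="pos")
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular V_i for patient visits at {times}: {err}")
    return D @ (Z.T @ sol)


def fit_fp_lmm(
    cohort: CohortData,
    spec: FPSpec,
    method: str = "ml",
    fallback: bool = True,
) -> FPMixedModel:
    """Fit one FP mixed model to a cohort (no covariates in the mean)."""
    times, y, groups = cohort_arrays(cohort)
    est = FPMixedModel(
        powers=spec.powers,
        time_offset=spec.time_offset,
        random_structure=spec.random_structure,
        method=method,
        fallback=fallback,
    )
    window = cohort.provenance.get("window_bounds")
    est.fit(times, y, groups=groups)
    est.window_ = window
    return est


def rank_candidates(table: pd.DataFrame) -> pd.DataFrame:
    """Order converged candidates by AIC, breaking exact ties toward the
    smaller order and then the lexicographically smaller powers."""
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError(
            f"no candidate FP model converged ({len(table)} attempted); "
            "check the data or simplify the random structure"
        )
    return ok.sort_values(["aic", "order", "powers"], kind="mergesort")


def select_fp_model(
    cohort: CohortData,
    orders: Sequence[int] = (1, 2),
    grid: Sequence[float] = POWER_GRID,
    time_offset: float = 1.0,
    random_structure: str | tuple[int, ...] = "all",
    method: str = "ml",
) -> tuple[FPSpec, pd.DataFrame]:
    """Scan the FP power grid and pick the spec with minimal AIC.

    All candidates are fitted by maximum likelihood (REML fits are not
    comparable across fixed-effects structures).  Non-converged fits are
    kept in the table but excluded from the minimum.  Exact AIC ties break
    toward the smaller order, then lexicographically smaller powers.
    """
    candidates: list[FPSpec] = []
    for order in orders:
        candidates.extend(enumerate_power_grid(order, grid, time_offset, random_structure))
    if not candidates:
        raise ValueError("empty candidate grid")
    rows = []
    for spec in candidates:
        try:
            m = fit_fp_lmm(cohort, spec, method=method)
            rows.append(
                {
                    "order": spec.order,
                    "powers": spec.powers,
                    "loglik": m.loglik_,
                    "aic": m.aic_,
                    "converged": m.converged_,
                }
            )
        except (InsufficientDataError, np.linalg.LinAlgError, ValueError) as err:
            rows.append(
                {
                    "order": spec.order,
                    "powers": spec.powers,
                    "loglik": np.nan,
                    "aic": np.nan,
                    "converged": False,
                    "error": str(err),
                }
            )
    table = pd.DataFrame(rows)
    best = rank_candidates(table).iloc[0]
    best_spec = FPSpec(tuple(best["powers"]), time_offset, random_structure)
    logger.info("selected FP%s powers %s (AIC %.2f)", best["order"], best["powers"], best["aic"])
    return best_spec, table.sort_values(["aic"], kind="mergesort").reset_index(drop=True)


class FPModelSelector(BaseEstimator):
    """AIC-driven FP power selection with a final REML refit.

    ``fit(X, y, groups)`` scans FP1 and FP2 candidates over the power grid
    by ML, stores the selection table, and refits the winner with
    ``refit_method`` (REML by default, for unbiased variance components).
    """

    def __init__(
        self,
        orders: Sequence[int] = (1, 2),
        grid: Sequence[float] = POWER_GRID,
        time_offset: float = 1.0,
        random_structure: str | tuple[int, ...] = "all",
        scan_random_structure: str | tuple[int, ...] | None = None,
        refit_method: str = "reml",
    ):
        self.orders = orders
        self.grid = grid
        self.time_offset = time_offset
        self.random_structure = random_structure
        self.scan_random_structure = scan_random_structure
        self.refit_method = refit_method

    def fit(self, X, y, groups=None):
        times, _ = _as_time_and_covariates(X)
        df = pd.DataFrame(
            {"patient_id": np.asarray(groups), "t": times, "cd4": np.exp(np.asarray(y))}
        )
        df["log_cd4"] = np.asarray(y, dtype=float)
        from .cohort import CohortData  # local to avoid cycle in type checkers

        cohort = CohortData(df[["patient_id", "t", "cd4", "log_cd4"]], pd.DataFrame(), {})
        return self.fit_cohort(cohort)

    def fit_cohort(self, cohort: CohortData):
        scan_rs = (
            self.scan_random_structure
            if self.scan_random_structure is not None
            else self.random_structure
        )
        self.best_spec_, self.table_ = select_fp_model(
            cohort,
            orders=self.orders,
            grid=self.grid,
            time_offset=self.time_offset,
            random_structure=scan_rs,
        )
        final_spec = self.best_spec_.with_random_structure(self.random_structure)
        self.best_model_ = fit_fp_lmm(cohort, final_spec, method=self.refit_method)
        return self

    def predict(self, X, groups=None):
        return self.best_model_.predict(X, groups=groups)
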