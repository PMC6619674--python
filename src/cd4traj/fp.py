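"""Fractional-polynomial transformations and design matrices.

A fractional polynomial (FP) of order ``m`` represents a smooth mean
trajectory as a linear combination of power transforms ``t**p`` with the
powers drawn from a small conventional grid.  Two conventions from the
Royston–Altman family apply: power 0 denotes the natural logarithm, and a
repeated power multiplies the previous basis function by ``log(t)`` —
so powers ``(0, 0)`` give ``(log t, (log t)**2)`` and ``(0.5, 0.5)`` give
``(sqrt(t), sqrt(t) * log t)``.

CD4 trajectories on antiretroviral therapy rise steeply early and then
flatten; FP2 bases with a log and a square-root term capture this shape
with only three fixed effects.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

try:  # sklearn is optional at runtime; the transformer degrades gracefully
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    BaseEstimator = object

    class TransformerMixin:  # type: ignore[no-redef]
        pass


#: Conventional FP power grid: -2 to 3 in half-unit steps (11 values).
POWER_GRID: tuple[float, ...] = (-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


class FPDomainError(ValueError):
    """Effective time (t + offset) non-positive, so powers/logs are undefined."""


class RankDeficientDesignError(ValueError):
    """The fixed-effects design matrix does not have full column rank."""


def fp_transform(
    t: float | Sequence[float] | np.ndarray,
    powers: Sequence[float],
    time_offset: float = 0.0,
) -> np.ndarray:
    """Evaluate the FP basis functions ``H_1 .. H_m`` at time(s) ``t``.

    Parameters
    ----------
    t
        Time(s) in months since ART initiation.  Scalar or array-like.
    powers
        Non-decreasing sequence of powers ``p_1 <= ... <= p_m`` from the
        FP grid.  Power 0 denotes ``log``; a repeated power multiplies the
        previous column by ``log(t)``.
    time_offset
        Months added to ``t`` before transforming, so that baseline visits
        at ``t = 0`` stay inside the log/power domain.

    Returns
    -------
    ndarray
        Shape ``(m,)`` for scalar input, ``(n, m)`` otherwise.
    """
    powers = tuple(float(p) for p in powers)
    if any(b < a for a, b in zip(powers, powers[1:])):
        raise ValueError(f"powers must be non-decreasing, got {powers}")
    scalar = np.isscalar(t)
    u = np.atleast_1d(np.asarray(t, dtype=float)) + time_offset
    if np.any(u <= 0):
        raise FPDomainError(
            f"non-positive effective time: min(t + offset) = {u.min():g}; "
            "increase time_offset or drop the offending visits"
        )
    logu = np.log(u)
    cols = []
    prev_power: float | None = None
    for p in powers:
        if prev_power is not None and p == prev_power:
            col = cols[-1] * logu
        elif p == 0.0:
            col = logu.copy()
        else:
            col = u**p
        cols.append(col)
        prev_power = p
    out = np.column_stack(cols) if cols else np.empty((u.size, 0))
    return out[0] if scalar else out


@dataclass(frozen=True)
class FPSpec:
    """Skeleton of an FP mixed model: order, powers and random structure.

    ``random_structure`` names which mean-structure terms carry
    subject-specific coefficients: ``"all"`` (intercept plus every FP term,
    the default), ``"intercept"``, or an explicit tuple of FP-term indices
    (1-based; the intercept is always random).
    """

    powers: tuple[float, ...]
    time_offset: float = 1.0
    random_structure: str | tuple[int, ...] = "all"

    def __post_init__(self) -> None:
        object.__setattr__(self, "powers", tuple(float(p) for p in self.powers))
        if any(b < a for a, b in zip(self.powers, self.powers[1:])):
            raise ValueError(f"powers must be sorted non-decreasing: {self.powers}")
        if self.order not in (1, 2):
            raise ValueError(f"only FP1/FP2 supported, got order {self.order}")

    @property
    def order(self) -> int:
        return len(self.powers)

    def random_term_indices(self) -> tuple[int, ...]:
        """FP-term indices (1-based) that receive random coefficients."""
        if self.random_structure == "all":
            return tuple(range(1, self.order + 1))
        if self.random_structure == "intercept":
            return ()
        return tuple(int(i) for i in self.random_structure)

    @property
    def n_random(self) -> int:
        """Dimension q of the random-effect vector (intercept included)."""
        return 1 + len(self.random_term_indices())

    def with_random_structure(self, structure: str | tuple[int, ...]) -> "FPSpec":
        return FPSpec(self.powers, self.time_offset, structure)

    def to_dict(self) -> dict:
        rs = self.random_structure
        return {
            "order": self.order,
            "powers": list(self.powers),
            "time_offset": self.time_offset,
            "random_structure": list(rs) if isinstance(rs, tuple) else rs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPSpec":
        rs = d.get("random_structure", "all")
        if isinstance(rs, list):
            rs = tuple(rs)
        return cls(tuple(d["powers"]), d.get("time_offset", 1.0), rs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FPSpec":
        return cls.from_dict(json.loads(s))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"FP{self.order}{self.powers}"


def build_design(
    times: Sequence[float] | np.ndarray,
    spec: FPSpec,
    covariates: np.ndarray | None = None,
    check_rank: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Build fixed- and random-effects design matrices for one set of visits.

    The fixed matrix is ``[1, H_1(t), ..., H_m(t)]`` plus any covariate
    columns; the random matrix is ``[1]`` plus the FP columns named by the
    spec's random structure.

    With ``check_rank=True`` a rank-deficient fixed design (e.g. a single
    distinct time with an FP2 spec) raises :class:`RankDeficientDesignError`
    instead of being passed silently to a fit.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    H = fp_transform(times, spec.powers, spec.time_offset)
    ones = np.ones((times.size, 1))
    X = np.hstack([ones, H])
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != times.size:
            cov = cov.T
        X = np.hstack([X, cov])
    idx = spec.random_term_indices()
    Z = np.hstack([ones] + [H[:, [i - 1]] for i in idx]) if idx else ones
    if check_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError(
            f"fixed design is rank deficient ({X.shape[1]} columns, "
            f"rank {np.linalg.matrix_rank(X)}); too few distinct times?"
        )
    return X, Z


def enumerate_power_grid(
    order: int,
    grid: Sequence[float] = POWER_GRID,
    time_offset: float = 1.0,
    random_structure: str | tuple[int, ...] = "all",
) -> list[FPSpec]:
    """All candidate FPSpecs of a given order over the power grid.

    FP1 yields one spec per grid value; FP2 yields every multiset
    ``{p1 <= p2}`` (66 specs on the default 11-value grid).
    """
    if order == 1:
        combos = [(p,) for p in grid]
    elif order == 2:
        combos = [tuple(c) for c in itertools.combinations_with_replacement(sorted(grid), 2)]
    else:
        raise ValueError(f"unsupported FP order {order}; only 1 and 2")
    return [FPSpec(c, time_offset, random_structure) for c in combos]


class FractionalPolynomialFeatures(TransformerMixin, BaseEstimator):
    """scikit-learn transformer mapping times to FP basis columns.

    ``transform`` accepts an ``(n,)`` or ``(n, 1)`` array of months and
    returns the ``(n, m)`` FP basis (no intercept column, matching
    sklearn's convention that the downstream estimator adds one).
    """

    def __init__(self, powers: Sequence[float] = (0.0, 0.5), time_offset: float = 1.0):
        self.powers = powers
        self.time_offset = time_offset

    def fit(self, X, y=None):  # stateless: nothing to learn
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).reshape(-1)
        return np.atleast_2d(fp_transform(t, self.powers, self.time_offset))

    def get_feature_names_out(self, input_features=None):
        names = []
        prev = None
        for i, p in enumerate(self.powers):
            if prev is not None and p == prev:
                names.append(f"{names[-1]}*log(t)")
            elif p == 0.0:
                names.append("log(t)")
            else:
                names.append(f"t^{p:g}")
            prev = p
        return np.asarray(names, dtype=object)
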