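"""Strategy classes, the fixed emission matrix, and parameter containers.

Four strategy classes ordered by expected accuracy: uninformed guessing
(UG, any of 9 digits), avoiding direct contradictions (ADC, any of the 6
digits not already in the house), choosing between the two prevalent
digits (PD), and the successful elimination strategy (S). Response columns
follow the fixed order (in_house, absent, distractor, target).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .puzzle import CATEGORY_LABELS

N_STRATEGIES = 4
ROW_SUM_TOL = 1e-8
LOAD_ROW_SUM_RANGE = (0.999, 1.001)  # published rows are rounded to 3 decimals


class Strategy(IntEnum):
    UG = 0
    ADC = 1
    PD = 2
    S = 3


STRATEGY_LABELS = tuple(s.name for s in Strategy)

# Row s, column c: probability a strategy-s user emits a category-c response,
# given the 3/4/1/1 split of digits over (in_house, absent, distractor, target).
EMISSION_MATRIX = np.array(
    [
        [3 / 9, 4 / 9, 1 / 9, 1 / 9],
        [0.0, 4 / 6, 1 / 6, 1 / 6],
        [0.0, 0.0, 1 / 2, 1 / 2],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


def emission_matrix() -> np.ndarray:
    """The constant strategy-by-category emission matrix R (copy)."""
    return EMISSION_MATRIX.copy()


class ParamValidationError(ValueError):
    pass


def _check_simplex_rows(m: np.ndarray, name: str, tol: float = ROW_SUM_TOL) -> None:
    if np.any(m < -tol):
        raise ParamValidationError(f"{name} has negative entries")
    sums = m.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ParamValidationError(f"{name} rows must sum to 1 (got {sums})")


@dataclass
class AggregateParams:
    """Initial distribution a, upper-triangular transition matrix X, and
    lower-triangular error-fallback matrix W over the 4 strategy classes."""

    a: np.ndarray
    X: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.a.shape != (4,) or self.X.shape != (4, 4) or self.W.shape != (4, 4):
            raise ParamValidationError("a must be length 4; X and W must be 4x4")
        _check_simplex_rows(self.a[None, :], "a")
        _check_simplex_rows(self.X, "X")
        _check_simplex_rows(self.W, "W")
        lower = np.tril_indices(4, k=-1)
        upper = np.triu_indices(4, k=1)
        if np.any(self.X[lower] != 0.0):
            raise ParamValidationError("X must have exact zeros below the diagonal")
        if np.any(self.W[upper] != 0.0):
            raise ParamValidationError("W must have exact zeros above the diagonal")
        if not np.array_equal(self.X[3], [0.0, 0.0, 0.0, 1.0]):
            raise ParamValidationError("S row of X must be (0, 0, 0, 1)")

    @property
    def effective_emissions(self) -> np.ndarray:
        """W @ R: per-strategy response probabilities including errors."""
        return self.W @ EMISSION_MATRIX

    def to_record(self) -> dict:
        return {
            "a": self.a.tolist(),
            "X": self.X.tolist(),
            "W": self.W.tolist(),
            "strategy_order": list(STRATEGY_LABELS),
            "category_order": list(CATEGORY_LABELS),
        }

    @classmethod
    def from_record(cls, rec: dict, renormalize: bool = True) -> "AggregateParams":
        if rec.get("strategy_order", list(STRATEGY_LABELS)) != list(STRATEGY_LABELS):
            raise ParamValidationError(f"strategy_order must be {STRATEGY_LABELS}")
        if rec.get("category_order", list(CATEGORY_LABELS)) != list(CATEGORY_LABELS):
            raise ParamValidationError(f"category_order must be {CATEGORY_LABELS}")
        a = np.asarray(rec["a"], dtype=float)
        X = np.asarray(rec["X"], dtype=float)
        W = np.asarray(rec["W"], dtype=float)
        if renormalize:
            a = _renormalize_rows(a[None, :], "a")[0]
            X = _renormalize_rows(X, "X")
            W = _renormalize_rows(W, "W")
        return cls(a=a, X=X, W=W)


def _renormalize_rows(m: np.ndarray, name: str) -> np.ndarray:
    lo, hi = LOAD_ROW_SUM_RANGE
    sums = m.sum(axis=-1)
    eps = 1e-9  # boundary sums (e.g. exactly 0.999) must pass despite float error
    if np.any(sums < lo - eps) or np.any(sums > hi + eps):
        raise ParamValidationError(
            f"{name} row sums {sums} outside tolerated range [{lo}, {hi}]"
        )
    return m / sums[..., None]


def effective_emissions(W: np.ndarray) -> np.ndarray:
    """W @ R with structural validation of W."""
    W = np.asarray(W, dtype=float)
    if W.shape != (4, 4):
        raise ParamValidationError("W must be 4x4")
    _check_simplex_rows(W, "W", tol=1e-3)
    if np.any(W[np.triu_indices(4, k=1)] != 0.0):
        raise ParamValidationError("W must have exact zeros above the diagonal")
    return W @ EMISSION_MATRIX


def solver_params() -> AggregateParams:
    """Bundled reference fit for the solver group (rows renormalized)."""
    return AggregateParams.from_record(
        {
            "a": [0.085, 0.241, 0.310, 0.365],
            "X": [
                [0.000, 0.999, 0.000, 0.000],
                [0.0, 0.106, 0.892, 0.001],
                [0.0, 0.0, 0.783, 0.217],
                [0.0, 0.0, 0.0, 1.0],
            ],
            "W": [
                [1.000, 0.0, 0.0, 0.0],
                [0.000, 1.000, 0.0, 0.0],
                [0.000, 0.054, 0.946, 0.0],
                [0.000, 0.000, 0.090, 0.910],
            ],
        }
    )


def non_solver_params() -> AggregateParams:
    """Bundled reference fit for the non-solver group (rows renormalized)."""
    return AggregateParams.from_record(
        {
            "a": [0.109, 0.397, 0.463, 0.032],
            "X": [
                [0.560, 0.001, 0.437, 0.002],
                [0.0, 0.770, 0.229, 0.001],
                [0.0, 0.0, 0.993, 0.007],
                [0.0, 0.0, 0.0, 1.0],
            ],
            "W": [
                [1.000, 0.0, 0.0, 0.0],
                [0.109, 0.891, 0.0, 0.0],
                [0.024, 0.038, 0.939, 0.0],
                [0.016, 0.016, 0.185, 0.783],
            ],
        }
    )
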