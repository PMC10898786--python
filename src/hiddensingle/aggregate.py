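"""Aggregate Markov model of strategy acquisition and its MLE fitting.

The trial-t response distribution for a group is ``a @ X^(t-1) @ W @ R``.
The group negative log-likelihood sums ``-log p_t[category]`` over all
participants and trials; it is minimized over the constrained parameter
space by mapping each free row to the simplex with a softmax (structural
zeros stay exactly zero by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import softmax

from .puzzle import ResponseCategory
from .strategy import EMISSION_MATRIX, AggregateParams

logger = logging.getLogger(__name__)

# Free entries: a (4 logits), X rows 0..2 above-diagonal blocks, W rows 1..3
# at-or-below-diagonal blocks. Row 3 of X and row 0 of W are fully determined.
_X_ROW_SIZES = (4, 3, 2)
_W_ROW_SIZES = (2, 3, 4)
N_FREE = 4 + sum(_X_ROW_SIZES) + sum(_W_ROW_SIZES)


@dataclass
class ResponseSequence:
    """One participant's ordered practice responses as category codes."""

    participant_id: str
    categories: list[ResponseCategory]
    digits: list[int] | None = None
    correct: list[bool] | None = None

    def __post_init__(self) -> None:
        if len(self.categories) < 1:
            raise ValueError("response sequence must contain at least one trial")
        self.categories = [ResponseCategory(c) for c in self.categories]


@dataclass
class FitConfig:
    restarts: int = 5
    max_iter: int = 5000
    tol: float = 1e-8
    seed: int = 0


@dataclass
class FitResult:
    params: AggregateParams
    nll: float
    converged: bool
    n_restarts: int
    restart_nlls: list[float] = field(default_factory=list)


def trial_distributions(params: AggregateParams, T: int) -> np.ndarray:
    """(T, 4) array of response-category distributions for trials 1..T."""
    if T < 1:
        raise ValueError("T must be >= 1")
    WR = params.W @ EMISSION_MATRIX
    out = np.empty((T, 4))
    state = params.a.copy()  # a @ X^(t-1), updated incrementally
    for t in range(T):
        out[t] = state @ WR
        state = state @ params.X
    return out


def response_distribution(params: AggregateParams, t: int) -> np.ndarray:
    """Category distribution ``a @ X^(t-1) @ W @ R`` at 1-based trial t."""
    if t < 1:
        raise ValueError(f"trial must be >= 1, got {t}")
    return trial_distributions(params, t)[-1]


def cohort_counts(cohort: list[ResponseSequence]) -> np.ndarray:
    """(T, 4) matrix of observed category counts per trial."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    T = len(cohort[0].categories)
    if any(len(seq.categories) != T for seq in cohort):
        raise ValueError("all sequences must have equal length")
    counts = np.zeros((T, 4))
    for seq in cohort:
        for t, c in enumerate(seq.categories):
            counts[t, int(c)] += 1
    return counts


def aggregate_nll(params: AggregateParams, cohort: list[ResponseSequence]) -> float:
    """Negative log-likelihood of a cohort; +inf on zero-probability data."""
    counts = cohort_counts(cohort)
    probs = trial_distributions(params, counts.shape[0])
    mask = counts > 0
    if np.any(probs[mask] <= 0.0):
        return float("inf")
    return float(-(counts[mask] * np.log(probs[mask])).sum())


def _unpack(theta: np.ndarray) -> AggregateParams:
    a = softmax(theta[:4])
    X = np.zeros((4, 4))
    W = np.zeros((4, 4))
    pos = 4
    for i, size in enumerate(_X_ROW_SIZES):
        X[i, i:] = softmax(theta[pos : pos + size])
        pos += size
    X[3, 3] = 1.0
    W[0, 0] = 1.0
    for i, size in enumerate(_W_ROW_SIZES, start=1):
        W[i, : i + 1] = softmax(theta[pos : pos + size])
        pos += size
    return AggregateParams(a=a, X=X, W=W)


def _counts_nll(theta: np.ndarray, counts: np.ndarray) -> float:
    params = _unpack(theta)
    probs = trial_distributions(params, counts.shape[0])
    # softmax keeps all free entries strictly positive, so probs > 0 wherever
    # counts can be; clip only guards against underflow
    return float(-(counts * np.log(np.clip(probs, 1e-300, None))).sum())


def fit_aggregate(
    cohort: list[ResponseSequence], config: FitConfig | None = None
) -> FitResult:
    """Constrained MLE of (a, X, W) by multi-start quasi-Newton descent."""
    config = config or FitConfig()
    counts = cohort_counts(cohort)
    rng = np.random.default_rng(config.seed)

    best = None
    restart_nlls = []
    any_converged = False
    for k in range(config.restarts):
        theta0 = np.zeros(N_FREE) if k == 0 else rng.normal(scale=1.0, size=N_FREE)
        res = minimize(
            _counts_nll,
            theta0,
            args=(counts,),
            method="L-BFGS-B",
            options={"maxiter": config.max_iter, "ftol": config.tol},
        )
        restart_nlls.append(float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        logger.warning("aggregate fit: no restart reported convergence; "
                       "returning best iterate (nll=%.6f)", best.fun)
    return FitResult(
        params=_unpack(best.x),
        nll=float(best.fun),
        converged=any_converged,
        n_restarts=config.restarts,
        restart_nlls=restart_nlls,
    )
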