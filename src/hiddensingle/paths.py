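"""Per-participant inference over weakly monotone latent strategy paths.

With 4 ordered strategy classes and no regression to weaker strategies,
a length-T path is a non-decreasing sequence; there are C(T+3, 3) of them
(3,276 at T=25), few enough for exact enumeration. The posterior over
paths follows from Bayes' rule with the aggregate parameters as prior;
marginal and cumulative strategy probabilities and threshold-crossing
transition trials are derived from it. A forward-backward pass over the
constrained chain is provided as an independent cross-check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .puzzle import ResponseCategory
from .strategy import EMISSION_MATRIX, N_STRATEGIES, AggregateParams, Strategy


class DegeneratePosteriorError(ValueError):
    """All enumerated paths have zero likelihood for the given responses."""


def n_monotone_paths(T: int) -> int:
    """Closed-form count of weakly non-decreasing length-T paths."""
    return comb(T + N_STRATEGIES - 1, N_STRATEGIES - 1)


def enumerate_monotone_paths(T: int):
    """Yield every weakly non-decreasing length-T strategy tuple once."""
    if T < 1:
        raise ValueError("T must be >= 1")
    for combo in itertools.combinations_with_replacement(range(N_STRATEGIES), T):
        yield tuple(Strategy(s) for s in combo)


def monotone_path_array(T: int) -> np.ndarray:
    """(n_paths, T) int array of all monotone paths."""
    return np.array(
        list(itertools.combinations_with_replacement(range(N_STRATEGIES), T)),
        dtype=np.int8,
    )


def _check_monotone(path) -> np.ndarray:
    path = np.asarray(path, dtype=int)
    if np.any(np.diff(path) < 0):
        raise ValueError("strategy path must be weakly non-decreasing")
    return path


def path_prior(params: AggregateParams, path) -> float:
    """Prior probability a[s_1] * prod X[s_t, s_t+1] of a monotone path."""
    path = _check_monotone(path)
    p = params.a[path[0]]
    if len(path) > 1:
        p = p * np.prod(params.X[path[:-1], path[1:]])
    return float(p)


def _emissions(params: AggregateParams, mode: str) -> np.ndarray:
    if mode == "effective":
        return params.W @ EMISSION_MATRIX
    if mode == "raw":
        return EMISSION_MATRIX
    raise ValueError(f"mode must be 'effective' or 'raw', got {mode!r}")


def path_likelihood(
    path, responses, params: AggregateParams | None = None, mode: str = "effective"
) -> float:
    """Product of per-trial emission probabilities along a path.

    ``effective`` (default) uses W @ R so execution errors do not zero out
    otherwise-plausible paths; ``raw`` uses the error-free R.
    """
    path = np.asarray(path, dtype=int)
    resp = np.asarray([int(ResponseCategory(r)) for r in responses])
    if len(path) != len(resp):
        raise ValueError("path and responses must have equal length")
    if mode == "effective" and params is None:
        raise ValueError("effective mode requires params (for W)")
    E = _emissions(params, mode) if mode == "effective" else EMISSION_MATRIX
    return float(np.prod(E[path, resp]))


@dataclass
class PathPosterior:
    """Posterior over all monotone paths for one response sequence."""

    paths: np.ndarray  # (n_paths, T) strategy indices
    weights: np.ndarray  # (n_paths,) posterior probabilities, sum 1
    params: AggregateParams
    responses: np.ndarray  # (T,) category indices
    mode: str

    @property
    def T(self) -> int:
        return self.paths.shape[1]

    def top_paths(self, k: int = 3) -> list[tuple[tuple[Strategy, ...], float]]:
        """The k most probable paths with their posterior weights."""
        order = np.argsort(self.weights)[::-1][:k]
        return [
            (tuple(Strategy(int(s)) for s in self.paths[i]), float(self.weights[i]))
            for i in order
        ]

    def marginals(self) -> np.ndarray:
        """(T, 4) table of P(s_t = s)."""
        out = np.zeros((self.T, N_STRATEGIES))
        for s in range(N_STRATEGIES):
            out[:, s] = ((self.paths == s) * self.weights[:, None]).sum(axis=0)
        return out

    def cumulative(self) -> np.ndarray:
        """(T, 4) table of P(s_t >= s)."""
        marg = self.marginals()
        return np.cumsum(marg[:, ::-1], axis=1)[:, ::-1]


def path_posterior(
    params: AggregateParams, responses, mode: str = "effective"
) -> PathPosterior:
    """Exact posterior over monotone paths by full enumeration (Bayes rule)."""
    resp = np.asarray([int(ResponseCategory(r)) for r in responses])
    T = len(resp)
    paths = monotone_path_array(T)
    prior = params.a[paths[:, 0]]
    if T > 1:
        prior = prior * np.prod(params.X[paths[:, :-1], paths[:, 1:]], axis=1)
    E = _emissions(params, mode)
    lik = np.prod(E[paths, resp[None, :]], axis=1)
    joint = prior * lik
    total = joint.sum()
    if total <= 0.0:
        raise DegeneratePosteriorError(
            "all monotone paths have zero posterior mass for these responses"
        )
    return PathPosterior(
        paths=paths, weights=joint / total, params=params, responses=resp, mode=mode
    )


def strategy_marginals(posterior: PathPosterior) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial P(s_t = s) and tail P(s_t >= s) tables, each (T, 4)."""
    return posterior.marginals(), posterior.cumulative()


def forward_backward_marginals(
    params: AggregateParams, responses, mode: str = "effective"
) -> np.ndarray:
    """(T, 4) smoothed marginals via forward-backward on the chain.

    Independent dynamic-programming route used to cross-check the
    enumeration-based posterior (identical up to float tolerance).
    """
    resp = np.asarray([int(ResponseCategory(r)) for r in responses])
    T = len(resp)
    E = _emissions(params, mode)
    alpha = np.empty((T, N_STRATEGIES))
    alpha[0] = params.a * E[:, resp[0]]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ params.X) * E[:, resp[t]]
    beta = np.empty((T, N_STRATEGIES))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = params.X @ (E[:, resp[t + 1]] * beta[t + 1])
    joint = alpha * beta
    total = joint[-1].sum()
    if total <= 0.0:
        raise DegeneratePosteriorError("zero total likelihood in forward pass")
    return joint / joint.sum(axis=1, keepdims=True)


def transition_trial(
    cumulative: np.ndarray, s: Strategy | int, threshold: float = 0.5
) -> int | None:
    """First 1-based trial with P(s_t >= s) strictly above *threshold*."""
    col = cumulative[:, int(s)]
    above = np.nonzero(col > threshold)[0]
    return int(above[0]) + 1 if above.size else None
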