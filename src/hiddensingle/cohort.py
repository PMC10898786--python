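"""Synthetic experiment generator.

Simulates complete cohorts with the statistical structure the analysis
pipeline assumes: latent monotone strategy paths drawn from group-level
Markov parameters, practice responses emitted through the error-fallback
and emission matrices, concrete puzzles for digit-level realism, and
transfer-phase correctness/response-time records with configurable
feature effects. Ground truth (paths, groups) is kept alongside but never
consumed by the analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    FeatureAssignment,
    TestDesign,
    assign_training_features,
    build_practice_design,
    build_test_design,
)
from .puzzle import Puzzle, ResponseCategory
from .strategy import (
    EMISSION_MATRIX,
    AggregateParams,
    Strategy,
    non_solver_params,
    solver_params,
)

TIMEOUT_SECONDS = 120.0


@dataclass
class CohortConfig:
    """Simulation settings; effect-size defaults follow the reference
    window-1 transfer estimates and the bundled group parameter sets."""

    n_solvers: int = 88
    n_non_solvers: int = 183
    t_practice: int = 25
    seed: int = 0
    solver_group_params: AggregateParams = field(default_factory=solver_params)
    non_solver_group_params: AggregateParams = field(default_factory=non_solver_params)
    # accuracy generative model (logits)
    solver_base_logit: float = 3.0
    non_solver_base_logit: float = -0.09
    accuracy_shifts: dict = field(
        default_factory=lambda: {"ds_changed": -0.10, "ht_changed": -0.30, "gp_changed": 0.16}
    )
    accuracy_participant_sd: float = 0.5
    # response-time generative model (log2 seconds)
    rt_base_log2: float = np.log2(19.0)
    rt_shifts: dict = field(
        default_factory=lambda: {"ds_changed": -0.02, "ht_changed": 0.33, "gp_changed": 0.11}
    )
    rt_participant_sd: float = 0.3
    rt_sigma: float = 0.5
    include_puzzles: bool = True

    def __post_init__(self) -> None:
        if self.n_solvers < 0 or self.n_non_solvers < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_solvers + self.n_non_solvers < 1:
            raise ValueError("cohort must contain at least one participant")
        if self.t_practice < 1:
            raise ValueError("t_practice must be >= 1")


def sample_path(
    params: AggregateParams, T: int, rng: np.random.Generator
) -> tuple[Strategy, ...]:
    """Draw a latent path: s1 ~ a, s_{t+1} ~ X[s_t] (monotone by structure)."""
    path = [int(rng.choice(4, p=params.a))]
    for _ in range(T - 1):
        path.append(int(rng.choice(4, p=params.X[path[-1]])))
    return tuple(Strategy(s) for s in path)


def sample_categories(
    path, params: AggregateParams, rng: np.random.Generator
) -> list[ResponseCategory]:
    """Emit one response category per trial through W then R."""
    out = []
    for s in path:
        fallback = int(rng.choice(4, p=params.W[int(s)]))
        out.append(ResponseCategory(int(rng.choice(4, p=EMISSION_MATRIX[fallback]))))
    return out


def sample_responses(
    path,
    params: AggregateParams,
    puzzles: list[Puzzle],
    rng: np.random.Generator,
) -> tuple[list[ResponseCategory], list[int]]:
    """Categories plus concrete digits consistent with each trial's puzzle."""
    if len(path) != len(puzzles):
        raise ValueError("path and puzzle list must have equal length")
    categories = sample_categories(path, params, rng)
    digits = []
    for cat, puzzle in zip(categories, puzzles):
        pool = puzzle.roles.digits_in_category(cat)
        digits.append(int(rng.choice(pool)))
    return categories, digits


def sample_test_records(
    config: CohortConfig,
    design: TestDesign,
    solver: bool,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Correctness and response times for one participant's 64 test trials."""
    base = config.solver_base_logit if solver else config.non_solver_base_logit
    b_acc = rng.normal(0.0, config.accuracy_participant_sd)
    b_rt = rng.normal(0.0, config.rt_participant_sd)
    rows = []
    for trial in design.trials:
        flags = {
            "ds_changed": int(trial.ds_changed),
            "ht_changed": int(trial.ht_changed),
            "hi_changed": int(trial.hi_changed),
            "ci_changed": int(trial.ci_changed),
            "gp_changed": int(trial.gp_changed),
        }
        logit = base + b_acc + sum(
            shift * flags[name] for name, shift in config.accuracy_shifts.items()
        )
        correct = bool(rng.random() < 1.0 / (1.0 + np.exp(-logit)))
        log2_rt = (
            config.rt_base_log2
            + b_rt
            + sum(shift * flags[name] for name, shift in config.rt_shifts.items())
            + rng.normal(0.0, config.rt_sigma)
        )
        rt = float(2.0**log2_rt)
        if rt > TIMEOUT_SECONDS:  # no response within the limit
            rt = np.nan
            correct = False
        rows.append({"trial": trial.position, **flags, "correct": int(correct), "rt_seconds": rt})
    return pd.DataFrame(rows)


@dataclass
class SimulatedCohort:
    config: CohortConfig
    features: dict[str, FeatureAssignment]
    practice_responses: pd.DataFrame
    test_records: pd.DataFrame
    ground_truth: dict
    practice_puzzles: dict[str, list[Puzzle]] = field(default_factory=dict)


def simulate_experiment(config: CohortConfig) -> SimulatedCohort:
    """Simulate a full cohort: features, practice responses, test records."""
    rng = np.random.default_rng(config.seed)
    features: dict[str, FeatureAssignment] = {}
    truth: dict = {"groups": {}, "paths": {}}
    practice_rows = []
    test_frames = []
    puzzles_by_pid: dict[str, list[Puzzle]] = {}

    groups = [("solver", config.solver_group_params)] * config.n_solvers + [
        ("non_solver", config.non_solver_group_params)
    ] * config.n_non_solvers
    for i, (group, params) in enumerate(groups):
        pid = f"p{i + 1:04d}"
        feats = assign_training_features(rng)
        features[pid] = feats
        path = sample_path(params, config.t_practice, rng)
        truth["groups"][pid] = group
        truth["paths"][pid] = [int(s) for s in path]

        if config.include_puzzles:
            puzzles = build_practice_design(feats, rng, n=config.t_practice)
            puzzles_by_pid[pid] = puzzles
            categories, digits = sample_responses(path, params, puzzles, rng)
        else:
            categories = sample_categories(path, params, rng)
            digits = [0] * config.t_practice
        for t, (cat, digit) in enumerate(zip(categories, digits), start=1):
            practice_rows.append(
                {
                    "participant_id": pid,
                    "trial": t,
                    "category": cat.label,
                    "digit": digit,
                    "correct": int(cat is ResponseCategory.TARGET),
                }
            )

        design = build_test_design(feats, rng)
        records = sample_test_records(config, design, group == "solver", rng)
        records.insert(0, "participant_id", pid)
        test_frames.append(records)

    return SimulatedCohort(
        config=config,
        features=features,
        practice_responses=pd.DataFrame(practice_rows),
        test_records=pd.concat(test_frames, ignore_index=True),
        ground_truth=truth,
        practice_puzzles=puzzles_by_pid,
    )
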