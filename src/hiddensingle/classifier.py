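"""Preregistered solver/non-solver classification from practice accuracy.

A logistic mixed model predicts first-attempt correctness from log2(trial)
with a per-participant random intercept and slope; a participant is a
solver iff the conditional predicted accuracy at trial 25 strictly
exceeds 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .glmm import LogisticGLMMResult, fit_logistic_glmm

SOLVER_THRESHOLD = 0.8
N_PRACTICE = 25


class Label(str, Enum):
    SOLVER = "solver"
    NON_SOLVER = "non_solver"


@dataclass
class PracticeRecord:
    participant_id: str
    correct: list[bool]

    def __post_init__(self) -> None:
        if len(self.correct) != N_PRACTICE:
            raise ValueError(
                f"classification requires {N_PRACTICE} trials, got {len(self.correct)}"
            )


@dataclass
class SolverLabel:
    participant_id: str
    predicted_trial25_accuracy: float
    label: Label


def fit_practice_glmm(cohort: list[PracticeRecord]) -> LogisticGLMMResult:
    """Fit correct ~ log2(trial) with random intercept + slope per participant."""
    if len(cohort) < 2:
        raise ValueError("at least 2 participants are required")
    n = len(cohort)
    y = np.array([[float(v) for v in rec.correct] for rec in cohort])
    trials = np.arange(1, N_PRACTICE + 1, dtype=float)
    x = np.log2(trials)
    X = np.broadcast_to(
        np.column_stack([np.ones(N_PRACTICE), x]), (n, N_PRACTICE, 2)
    ).copy()
    Z = X.copy()  # random intercept and random log2(trial) slope
    return fit_logistic_glmm(
        y, X, Z, [rec.participant_id for rec in cohort],
        fixed_names=["intercept", "log2_trial"],
    )


def predict_trial25(fit: LogisticGLMMResult, participant_id: str) -> float:
    """Conditional predicted accuracy at practice trial 25."""
    x_row = np.array([1.0, np.log2(N_PRACTICE)])
    return fit.predict_proba(participant_id, x_row)


def classify(
    predictions: dict[str, float], threshold: float = SOLVER_THRESHOLD
) -> list[SolverLabel]:
    """Threshold predicted trial-25 accuracies (strict inequality)."""
    labels = []
    for pid, p in predictions.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prediction for {pid!r} outside [0, 1]: {p}")
        label = Label.SOLVER if p > threshold else Label.NON_SOLVER
        labels.append(SolverLabel(pid, float(p), label))
    return labels


def classify_cohort(
    cohort: list[PracticeRecord], threshold: float = SOLVER_THRESHOLD
) -> tuple[list[SolverLabel], LogisticGLMMResult]:
    """Fit the practice model and label every participant."""
    fit = fit_practice_glmm(cohort)
    preds = {rec.participant_id: predict_trial25(fit, rec.participant_id) for rec in cohort}
    return classify(preds, threshold), fit


def labels_to_frame(labels: list[SolverLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [l.participant_id for l in labels],
            "predicted_trial25": [l.predicted_trial25_accuracy for l in labels],
            "label": [l.label.value for l in labels],
        }
    )


def summarize_accuracy(
    records: pd.DataFrame, phase: str | None = None
) -> pd.DataFrame:
    """Per-participant accuracy table; empty input yields an empty table."""
    df = records
    if phase is not None and "phase" in df.columns:
        df = df[df["phase"] == phase]
    if df.empty:
        return pd.DataFrame(columns=["participant_id", "n_trials", "accuracy"])
    out = (
        df.groupby("participant_id", sort=True)["correct"]
        .agg(n_trials="size", accuracy="mean")
        .reset_index()
    )
    out["accuracy"] = out["accuracy"].astype(float)
    return out
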