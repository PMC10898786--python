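"""Per-participant experimental design: training features, the 25-trial
practice sequence, and the balanced 64-trial transfer design.

The transfer design arranges the 8 house-type x house-index x cell-index
change combinations in a Williams-type balanced Latin square (8 sets of 8):
each combination occurs once per set, once per within-set position, and
precedes every other combination exactly 4 times. Digit-set changes are
assigned to half of each set so that every consecutive pair of sets covers
all 16 four-flag combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DIGITS, HouseSpec, HouseType
from .puzzle import Puzzle, generate_puzzle

N_PRACTICE_TRIALS = 25
N_TEST_TRIALS = 64
N_SETS = 8
SET_SIZE = 8


@dataclass(frozen=True)
class FeatureAssignment:
    """Training features plus the disjoint transfer digit set."""

    train_house_type: HouseType
    train_house_index: int
    train_cell_index: int
    train_digit_set: frozenset[int]
    transfer_digit_set: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.train_digit_set) != 4 or len(self.transfer_digit_set) != 4:
            raise ValueError("digit sets must each contain 4 digits")
        if self.train_digit_set & self.transfer_digit_set:
            raise ValueError("training and transfer digit sets must be disjoint")

    @property
    def train_house(self) -> HouseSpec:
        return HouseSpec(self.train_house_type, self.train_house_index)

    def to_record(self) -> dict:
        return {
            "train_house_type": self.train_house_type.value,
            "train_house_index": self.train_house_index,
            "train_cell_index": self.train_cell_index,
            "train_digit_set": sorted(self.train_digit_set),
            "transfer_digit_set": sorted(self.transfer_digit_set),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "FeatureAssignment":
        return cls(
            HouseType(rec["train_house_type"]),
            rec["train_house_index"],
            rec["train_cell_index"],
            frozenset(rec["train_digit_set"]),
            frozenset(rec["transfer_digit_set"]),
        )


@dataclass
class TestTrial:
    __test__ = False  # domain type, not a pytest class

    position: int  # 1..64
    set_index: int  # 1..8
    ds_changed: bool
    ht_changed: bool
    hi_changed: bool
    ci_changed: bool
    house_type: HouseType | None = None
    house_index: int | None = None
    cell_index: int | None = None
    target: int | None = None
    distractor: int | None = None

    @property
    def gp_changed(self) -> bool:
        return self.hi_changed or self.ci_changed


@dataclass
class TestDesign:
    __test__ = False  # domain type, not a pytest class

    trials: list[TestTrial] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "position": t.position,
                    "set_index": t.set_index,
                    "ds_changed": int(t.ds_changed),
                    "ht_changed": int(t.ht_changed),
                    "hi_changed": int(t.hi_changed),
                    "ci_changed": int(t.ci_changed),
                    "gp_changed": int(t.gp_changed),
                    "house_type": None if t.house_type is None else t.house_type.value,
                    "house_index": t.house_index,
                    "cell_index": t.cell_index,
                    "target": t.target,
                    "distractor": t.distractor,
                }
            )
        return pd.DataFrame(rows)


def assign_training_features(rng: np.random.Generator) -> FeatureAssignment:
    """Uniform training features; transfer set = 4 of the 5 unused digits."""
    house_type = HouseType.ROW if rng.integers(2) == 0 else HouseType.COLUMN
    house_index = int(rng.integers(1, 10))
    cell_index = int(rng.integers(1, 10))
    train = frozenset(int(d) for d in rng.choice(DIGITS, size=4, replace=False))
    remaining = sorted(set(DIGITS) - train)
    transfer = frozenset(int(d) for d in rng.choice(remaining, size=4, replace=False))
    return FeatureAssignment(house_type, house_index, cell_index, train, transfer)


def _draw_trial_digits(
    digit_set: frozenset[int], rng: np.random.Generator
) -> tuple[int, int, frozenset[int]]:
    """Target and distractor from the digit set, in-house from the other 7."""
    target, distractor = (int(d) for d in rng.choice(sorted(digit_set), 2, replace=False))
    pool = sorted(set(DIGITS) - {target, distractor})
    in_house = frozenset(int(d) for d in rng.choice(pool, 3, replace=False))
    return target, distractor, in_house


def build_practice_design(
    features: FeatureAssignment,
    rng: np.random.Generator,
    n: int = N_PRACTICE_TRIALS,
) -> list[Puzzle]:
    """n practice puzzles sharing the training house, goal cell, and digit set."""
    puzzles = []
    for _ in range(n):
        target, distractor, in_house = _draw_trial_digits(features.train_digit_set, rng)
        puzzles.append(
            generate_puzzle(
                features.train_house, features.train_cell_index, target, distractor, in_house, rng
            )
        )
    return puzzles


def _williams_square(n: int) -> np.ndarray:
    """Williams balanced Latin square of even order n (rows x positions)."""
    if n % 2:
        raise ValueError("construction requires even order")
    first = [0, 1]
    hi, lo = n - 1, 2
    while len(first) < n:
        first.append(hi)
        if len(first) < n:
            first.append(lo)
        hi, lo = hi - 1, lo + 1
    row0 = np.array(first)
    return np.stack([(row0 + i) % n for i in range(n)])


def build_test_design(features: FeatureAssignment, rng: np.random.Generator) -> TestDesign:
    """64-trial transfer design with full Latin-square and digit-set balance."""
    square = _williams_square(SET_SIZE)
    # Random relabeling of conditions and rotation of sets keeps the balance
    # properties while varying the realized order across participants.
    relabel = rng.permutation(SET_SIZE)
    square = np.roll(relabel[square], int(rng.integers(SET_SIZE)), axis=0)

    # ds flags: half of the 8 combos per set, complemented on alternating
    # sets, so every consecutive pair of sets covers all 16 combinations.
    ds_half = set(int(c) for c in rng.choice(SET_SIZE, size=SET_SIZE // 2, replace=False))

    design = TestDesign()
    for set_ix in range(N_SETS):
        for pos_ix in range(SET_SIZE):
            combo = int(square[set_ix, pos_ix])
            ds = (combo in ds_half) if set_ix % 2 == 0 else (combo not in ds_half)
            trial = TestTrial(
                position=set_ix * SET_SIZE + pos_ix + 1,
                set_index=set_ix + 1,
                ds_changed=ds,
                ht_changed=bool(combo & 4),
                hi_changed=bool(combo & 2),
                ci_changed=bool(combo & 1),
            )
            realize_trial(features, trial, rng)
            design.trials.append(trial)
    return design


def realize_trial(
    features: FeatureAssignment, trial: TestTrial, rng: np.random.Generator
) -> TestTrial:
    """Fill in concrete features for a trial from its change flags.

    Changed house/cell indices are resampled uniformly from the 8
    non-training values per trial, which yields the 1/32 (single change)
    vs 1/256 (double change) per-cell goal distribution.
    """
    if trial.ht_changed:
        trial.house_type = (
            HouseType.COLUMN
            if features.train_house_type is HouseType.ROW
            else HouseType.ROW
        )
    else:
        trial.house_type = features.train_house_type

    def resample(train_value: int) -> int:
        alternatives = [i for i in range(1, 10) if i != train_value]
        return int(rng.choice(alternatives))

    trial.house_index = (
        resample(features.train_house_index) if trial.hi_changed else features.train_house_index
    )
    trial.cell_index = (
        resample(features.train_cell_index) if trial.ci_changed else features.train_cell_index
    )
    digit_set = features.transfer_digit_set if trial.ds_changed else features.train_digit_set
    trial.target, trial.distractor, _ = _draw_trial_digits(digit_set, rng)
    return trial


def realize_trial_puzzle(
    features: FeatureAssignment, trial: TestTrial, rng: np.random.Generator
) -> Puzzle:
    """Generate the concrete puzzle for a realized test trial."""
    if trial.house_type is None:
        realize_trial(features, trial, rng)
    pool = sorted(set(DIGITS) - {trial.target, trial.distractor})
    in_house = frozenset(int(d) for d in rng.choice(pool, 3, replace=False))
    return generate_puzzle(
        HouseSpec(trial.house_type, trial.house_index),
        trial.cell_index,
        trial.target,
        trial.distractor,
        in_house,
        rng,
    )
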