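import itertools

import numpy as np
import pytest

from hiddensingle.design import (
    FeatureAssignment,
    _williams_square,
    assign_training_features,
    build_practice_design,
    build_test_design,
    realize_trial,
    realize_trial_puzzle,
    TestTrial,
)
from hiddensingle.grid import HouseType
from hiddensingle.puzzle import validate_puzzle


class TestFeatureAssignment:
    def test_digit_sets_disjoint_union_8(self, rng):
        for _ in range(20):
            f = assign_training_features(rng)
            assert not f.train_digit_set & f.transfer_digit_set
            assert len(f.train_digit_set | f.transfer_digit_set) == 8

    def test_exactly_one_digit_unused(self, rng):
        f = assign_training_features(rng)
        unused = set(range(1, 10)) - f.train_digit_set - f.transfer_digit_set
        assert len(unused) == 1

    def test_reproducible_given_seed(self):
        a = assign_training_features(np.random.default_rng(3))
        b = assign_training_features(np.random.default_rng(3))
        assert a == b

    def test_invalid_sets_rejected(self):
        with pytest.raises(ValueError):
            FeatureAssignment(HouseType.ROW, 1, 1, frozenset({1, 2, 3, 4}), frozenset({4, 5, 6, 7}))


class TestPracticeDesign:
    def test_shared_features_and_digit_sets(self, features, rng):
        puzzles = build_practice_design(features, rng, n=8)
        assert len(puzzles) == 8
        layouts = set()
        for p in puzzles:
            assert p.house == features.train_house
            assert p.cell_index == features.train_cell_index
            assert p.roles.target in features.train_digit_set
            assert p.roles.distractor in features.train_digit_set
            validate_puzzle(p)
            layouts.add(p.grid.tobytes())
        assert len(layouts) >= 2


class TestLatinSquare:
    def test_williams_square_rows_and_columns(self):
        sq = _williams_square(8)
        for i in range(8):
            assert sorted(sq[i]) == list(range(8))
            assert sorted(sq[:, i]) == list(range(8))

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError):
            _williams_square(7)


class TestTestDesign:
    @pytest.fixture
    def design(self, features, rng):
        return build_test_design(features, rng)

    def test_64_trials_in_8_sets(self, design):
        assert len(design.trials) == 64
        sets = {t.set_index for t in design.trials}
        assert sets == set(range(1, 9))

    def test_combination_once_per_set_and_position(self, design):
        def combo(t):
            return (t.ht_changed, t.hi_changed, t.ci_changed)

        for s in range(1, 9):
            trials = [t for t in design.trials if t.set_index == s]
            assert len({combo(t) for t in trials}) == 8
        for pos in range(8):
            trials = [t for t in design.trials if (t.position - 1) % 8 == pos]
            assert len({combo(t) for t in trials}) == 8

    def test_precedence_balance_4_before_4_after(self, design):
        def combo(t):
            return (t.ht_changed, t.hi_changed, t.ci_changed)

        before = {}
        for s in range(1, 9):
            trials = sorted(
                (t for t in design.trials if t.set_index == s), key=lambda t: t.position
            )
            for i, j in itertools.combinations(range(8), 2):
                before[(combo(trials[i]), combo(trials[j]))] = before.get(
                    (combo(trials[i]), combo(trials[j])), 0
                ) + 1
        assert all(v == 4 for v in before.values())

    def test_four_digit_set_changes_per_set(self, design):
        for s in range(1, 9):
            assert sum(t.ds_changed for t in design.trials if t.set_index == s) == 4

    def test_consecutive_set_pairs_cover_all_16(self, design):
        def flags(t):
            return (t.ds_changed, t.ht_changed, t.hi_changed, t.ci_changed)

        for s in range(1, 8):
            trials = [t for t in design.trials if t.set_index in (s, s + 1)]
            assert len({flags(t) for t in trials}) == 16

    def test_each_flag_changes_on_32_trials(self, design):
        for attr in ("ds_changed", "ht_changed", "hi_changed", "ci_changed"):
            assert sum(getattr(t, attr) for t in design.trials) == 32


class TestRealizeTrial:
    def test_control_trial_matches_training(self, features, rng):
        trial = TestTrial(1, 1, False, False, False, False)
        realize_trial(features, trial, rng)
        assert trial.house_type == features.train_house_type
        assert trial.house_index == features.train_house_index
        assert trial.cell_index == features.train_cell_index
        assert {trial.target, trial.distractor} <= features.train_digit_set

    def test_ds_change_uses_transfer_set(self, features, rng):
        trial = TestTrial(1, 1, True, False, False, False)
        realize_trial(features, trial, rng)
        assert {trial.target, trial.distractor} <= features.transfer_digit_set

    def test_changed_indices_avoid_training_value(self, features, rng):
        for _ in range(30):
            trial = TestTrial(1, 1, False, True, True, True)
            realize_trial(features, trial, rng)
            assert trial.house_type != features.train_house_type
            assert trial.house_index != features.train_house_index
            assert trial.cell_index != features.train_cell_index

    def test_realized_puzzle_valid(self, features, rng):
        trial = TestTrial(1, 1, True, True, True, True)
        realize_trial(features, trial, rng)
        validate_puzzle(realize_trial_puzzle(features, trial, rng))

    def test_goal_cell_distribution(self, features, rng):
        """Single-change cells hit ~(1/32)/(3/4), double-change ~(1/256)/(3/4),
        conditional on a goal-position change (Monte Carlo at n=10,000)."""
        n = 10_000
        counts: dict[tuple[int, int], int] = {}
        for _ in range(n):
            hi, ci = bool(rng.integers(2)), bool(rng.integers(2))
            if not (hi or ci):
                continue
            trial = TestTrial(1, 1, False, False, hi, ci)
            realize_trial(features, trial, rng)
            key = (trial.house_index, trial.cell_index)
            counts[key] = counts.get(key, 0) + 1
        n_changed = sum(counts.values())
        hi0, ci0 = features.train_house_index, features.train_cell_index
        single = [k for k in counts if (k[0] == hi0) != (k[1] == ci0)]
        double = [k for k in counts if k[0] != hi0 and k[1] != ci0]
        assert len(single) == 16
        assert len(double) == 64
        p_single = np.mean([counts[k] / n_changed for k in single])
        p_double = np.mean([counts[k] / n_changed for k in double])
        assert p_single == pytest.approx((1 / 32) / (3 / 4), rel=0.15)
        assert p_double == pytest.approx((1 / 256) / (3 / 4), rel=0.15)
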