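"""Hidden-single puzzle construction, validation, solving, and feedback.

A hidden-single puzzle is a 9x9 grid with exactly 9 filled cells built from
5 distinct hint digits: a *target* (3 instances, forced into the goal cell),
a *distractor* (3 instances, plausible but not forced), and 3 *in-house*
digits (one instance each, inside the target house). The remaining 4 digits
are *absent*. The target house contains the goal cell, the 3 in-house hints,
and 5 empty cells; 3 of the empty cells lie in the *box-constraint box*,
where single target and distractor instances eliminate all three at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum, IntEnum

import numpy as np

from .grid import (
    EMPTY,
    CellCoord,
    HouseSpec,
    HouseType,
    box_of,
    boxes_of_house,
    cells_of_box,
    cells_of_house,
    check_digit,
    digit_cells,
    grid_from_string,
    grid_get,
    grid_is_consistent,
    grid_set,
    grid_to_string,
    iter_cells,
    peers,
)

MAX_GENERATION_ATTEMPTS = 1000


class ResponseCategory(IntEnum):
    """Role of a response digit. Order fixes emission-matrix columns."""

    IN_HOUSE = 0
    ABSENT = 1
    DISTRACTOR = 2
    TARGET = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "ResponseCategory":
        try:
            return cls[label.upper()]
        except KeyError:
            raise ValueError(f"unknown response category: {label!r}") from None


CATEGORY_LABELS = tuple(c.label for c in ResponseCategory)


class EliminationReason(str, Enum):
    FILLED = "filled"
    BOX_CONSTRAINED = "box_constrained"
    LINE_CONSTRAINED = "line_constrained"


class PuzzleGenerationError(RuntimeError):
    """Raised when no legal grid exists for a feature tuple within bounds."""


class PuzzleValidationError(ValueError):
    """Raised when a grid violates a structural puzzle invariant."""


@dataclass(frozen=True)
class RoleAssignment:
    """Partition of the 9 digits into target/distractor/in-house/absent."""

    target: int
    distractor: int
    in_house: frozenset[int]
    absent: frozenset[int]

    def __post_init__(self) -> None:
        groups = [{self.target}, {self.distractor}, set(self.in_house), set(self.absent)]
        if sorted(len(g) for g in groups) != [1, 1, 3, 4]:
            raise ValueError("role groups must have sizes 1/1/3/4")
        union = set().union(*groups)
        if union != set(range(1, 10)):
            raise ValueError("role groups must partition digits 1..9")

    def category_of(self, digit: int) -> ResponseCategory:
        check_digit(digit)
        if digit == self.target:
            return ResponseCategory.TARGET
        if digit == self.distractor:
            return ResponseCategory.DISTRACTOR
        if digit in self.in_house:
            return ResponseCategory.IN_HOUSE
        return ResponseCategory.ABSENT

    def digits_in_category(self, category: ResponseCategory) -> tuple[int, ...]:
        return tuple(
            d for d in range(1, 10) if self.category_of(d) is category
        )


@dataclass
class Puzzle:
    grid: np.ndarray
    house: HouseSpec
    cell_index: int
    roles: RoleAssignment
    box_constraint_box: int
    seed: int | None = None

    @property
    def goal(self) -> CellCoord:
        return cells_of_house(self.house)[self.cell_index - 1]

    def to_record(self) -> dict:
        return {
            "grid": grid_to_string(self.grid),
            "house_type": self.house.house_type.value,
            "house_index": self.house.house_index,
            "cell_index": self.cell_index,
            "target": self.roles.target,
            "distractor": self.roles.distractor,
            "in_house": sorted(self.roles.in_house),
            "absent": sorted(self.roles.absent),
            "box_constraint_box": self.box_constraint_box,
            "seed": self.seed,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Puzzle":
        roles = RoleAssignment(
            target=rec["target"],
            distractor=rec["distractor"],
            in_house=frozenset(rec["in_house"]),
            absent=frozenset(rec["absent"]),
        )
        return cls(
            grid=grid_from_string(rec["grid"]),
            house=HouseSpec(HouseType(rec["house_type"]), rec["house_index"]),
            cell_index=rec["cell_index"],
            roles=roles,
            box_constraint_box=rec["box_constraint_box"],
            seed=rec.get("seed"),
        )


@dataclass
class FeedbackReport:
    """Explanation of why a response digit is (in)correct for a puzzle."""

    category: ResponseCategory
    contradiction_cell: CellCoord | None
    open_cells: list[CellCoord]
    eliminated_cells: dict[CellCoord, EliminationReason]


def classify_response(puzzle: Puzzle, digit: int) -> ResponseCategory:
    """Category of *digit* for *puzzle* (target/distractor/absent/in-house)."""
    return puzzle.roles.category_of(digit)


def _perpendicular_line(house: HouseSpec, cell: CellCoord) -> list[CellCoord]:
    """Cells of the line through *cell* orthogonal to the house, off-house."""
    r, c = cell
    if house.house_type is HouseType.ROW:
        return [(rr, c) for rr in range(1, 10) if rr != r]
    return [(r, cc) for cc in range(1, 10) if cc != c]


def generate_puzzle(
    house: HouseSpec,
    cell_index: int,
    target: int,
    distractor: int,
    in_house: set[int] | frozenset[int],
    rng: np.random.Generator,
    max_attempts: int = MAX_GENERATION_ATTEMPTS,
) -> Puzzle:
    """Generate a puzzle by constructive placement with rejection sampling.

    Placement recipe: the box-constraint box is drawn uniformly from the two
    house boxes not containing the goal and its 3 house cells stay empty; 3
    of the remaining 5 non-goal house cells receive the in-house hints; one
    target and one distractor instance go inside the box-constraint box; the
    2 remaining target instances sit on the perpendicular lines through the
    2 leftover empty house cells; a second distractor covers exactly one of
    those cells and the third goes anywhere legal that leaves the other cell
    open and the goal unconstrained. Conflicting draws are rejected and
    retried up to *max_attempts* times.
    """
    if not 1 <= cell_index <= 9:
        raise ValueError(f"cell_index out of range: {cell_index}")
    in_house = frozenset(in_house)
    hints = {target, distractor} | in_house
    if len(hints) != 5 or len(in_house) != 3:
        raise ValueError("target, distractor, and 3 in-house digits must be distinct")
    for d in hints:
        check_digit(d)
    roles = RoleAssignment(
        target=target,
        distractor=distractor,
        in_house=in_house,
        absent=frozenset(set(range(1, 10)) - hints),
    )

    house_cells = cells_of_house(house)
    goal = house_cells[cell_index - 1]
    goal_peers = peers(goal)

    for _ in range(max_attempts):
        grid = np.zeros((9, 9), dtype=np.int8)

        bcb_choices = [b for b in boxes_of_house(house) if b != box_of(goal)]
        bcb = int(rng.choice(bcb_choices))
        bcb_cells = set(cells_of_box(bcb))
        bcb_house_cells = [c for c in house_cells if c in bcb_cells]

        rest = [c for c in house_cells if c != goal and c not in bcb_cells]
        order = list(rng.permutation(len(rest)))
        inhouse_cells = [rest[i] for i in order[:3]]
        open_house = [rest[i] for i in order[3:]]  # stay empty, off the bcb
        for cell, d in zip(inhouse_cells, rng.permutation(sorted(in_house))):
            grid_set(grid, cell, int(d))

        # One target + one distractor inside the bcb, off the house: each
        # eliminates all 3 empty bcb house cells through the shared box.
        off_house = [c for c in cells_of_box(bcb) if c not in bcb_house_cells]
        i, j = rng.choice(len(off_house), size=2, replace=False)
        grid_set(grid, off_house[int(i)], target)
        grid_set(grid, off_house[int(j)], distractor)

        if not _place_line_instances(grid, house, goal_peers, open_house, roles, rng):
            continue

        puzzle = Puzzle(
            grid=grid,
            house=house,
            cell_index=cell_index,
            roles=roles,
            box_constraint_box=bcb,
        )
        try:
            validate_puzzle(puzzle)
        except PuzzleValidationError:
            continue
        return puzzle

    raise PuzzleGenerationError(
        f"no legal grid after {max_attempts} attempts for "
        f"house={house.house_type.value}:{house.house_index}, "
        f"cell_index={cell_index}, target={target}, distractor={distractor}, "
        f"in_house={sorted(in_house)}"
    )


def _legal_spots(
    grid: np.ndarray, line: list[CellCoord], digit: int, forbidden: set[CellCoord]
) -> list[CellCoord]:
    existing = digit_cells(grid, digit)
    out = []
    for cell in line:
        if grid_get(grid, cell) != EMPTY or cell in forbidden:
            continue
        if any(cell in peers(e) or cell == e for e in existing):
            continue
        out.append(cell)
    return out


def _place_line_instances(grid, house, goal_peers, open_house, roles, rng) -> bool:
    """Place the 2 remaining targets and 2 remaining distractors; False on dead end."""
    target, distractor = roles.target, roles.distractor

    # Each leftover open house cell is covered by a target on its own
    # perpendicular line (the line-constrained eliminations of the feedback).
    for cell in open_house:
        line = _perpendicular_line(house, cell)
        spots = _legal_spots(grid, line, target, set(goal_peers))
        if not spots:
            return False
        grid_set(grid, spots[int(rng.integers(len(spots)))], target)

    # Second distractor covers exactly one of the two open cells; the other
    # must stay free of distractor peers so the distractor is never forced.
    covered_ix = int(rng.integers(2))
    covered, kept_open = open_house[covered_ix], open_house[1 - covered_ix]
    kept_open_peers = peers(kept_open)
    line = _perpendicular_line(house, covered)
    spots = _legal_spots(grid, line, distractor, set(goal_peers) | set(kept_open_peers))
    if not spots:
        return False
    grid_set(grid, spots[int(rng.integers(len(spots)))], distractor)

    # Third distractor: anywhere legal, seeing neither the goal nor kept_open.
    house_cells = set(cells_of_house(house))
    candidates = [
        c
        for c in iter_cells()
        if grid_get(grid, c) == EMPTY
        and c not in house_cells
        and c not in goal_peers
        and c not in kept_open_peers
    ]
    spots = _legal_spots(grid, candidates, distractor, set())
    if not spots:
        return False
    grid_set(grid, spots[int(rng.integers(len(spots)))], distractor)
    return True


def validate_puzzle(puzzle: Puzzle) -> None:
    """Check every structural invariant; raise PuzzleValidationError on failure."""
    grid = puzzle.grid
    roles = puzzle.roles
    house_cells = cells_of_house(puzzle.house)
    goal = puzzle.goal

    if not grid_is_consistent(grid):
        raise PuzzleValidationError("duplicate digit within a row, column, or box")
    if grid_get(grid, goal) != EMPTY:
        raise PuzzleValidationError("goal cell must be empty")

    filled = [(c, grid_get(grid, c)) for c in iter_cells() if grid_get(grid, c) != EMPTY]
    if len(filled) != 9:
        raise PuzzleValidationError(f"expected 9 filled cells, found {len(filled)}")

    t_cells = digit_cells(grid, roles.target)
    d_cells = digit_cells(grid, roles.distractor)
    if len(t_cells) != 3 or len(d_cells) != 3:
        raise PuzzleValidationError("target and distractor must each appear 3 times")
    for d in roles.in_house:
        cells = digit_cells(grid, d)
        if len(cells) != 1 or cells[0] not in house_cells:
            raise PuzzleValidationError(
                f"in-house digit {d} must appear exactly once, inside the house"
            )
    for d in roles.absent:
        if digit_cells(grid, d):
            raise PuzzleValidationError(f"absent digit {d} appears in the grid")

    empties = [c for c in house_cells if grid_get(grid, c) == EMPTY and c != goal]
    if len(empties) != 5:
        raise PuzzleValidationError("target house must have 5 empty non-goal cells")
    bcb_cells = set(cells_of_box(puzzle.box_constraint_box))
    if sum(c in bcb_cells for c in empties) != 3:
        raise PuzzleValidationError(
            "3 empty house cells must lie in the box-constraint box"
        )
    if box_of(goal) == puzzle.box_constraint_box:
        raise PuzzleValidationError("goal cell must not lie in the box-constraint box")

    goal_peers = peers(goal)
    for cell in t_cells + d_cells:
        if cell in goal_peers:
            raise PuzzleValidationError(
                "no target or distractor instance may see the goal cell"
            )

    for cell in empties:
        cell_peers = peers(cell)
        if not any(t in cell_peers for t in t_cells):
            raise PuzzleValidationError(f"house cell {cell} not eliminated for target")
    if not any(
        not any(d in peers(cell) for d in d_cells) for cell in empties
    ):
        raise PuzzleValidationError("distractor must leave at least one house cell open")


def is_forced(puzzle: Puzzle, digit: int) -> bool:
    """True iff *digit* is forced into the goal cell by peer elimination.

    Independent of the declared roles: checks that every empty non-goal
    house cell sees an instance of *digit* while the goal cell sees none.
    """
    check_digit(digit)
    grid = puzzle.grid
    if not grid_is_consistent(grid):
        raise PuzzleValidationError("grid is inconsistent")
    goal = puzzle.goal
    instances = digit_cells(grid, digit)
    if not instances:
        return False
    if any(i in peers(goal) for i in instances):
        return False
    house_cells = cells_of_house(puzzle.house)
    if any(grid_get(grid, c) == digit for c in house_cells):
        return False
    for cell in house_cells:
        if cell == goal or grid_get(grid, cell) != EMPTY:
            continue
        if not any(i in peers(cell) for i in instances):
            return False
    return True


def forced_digit(puzzle: Puzzle) -> int | None:
    """The unique hint digit forced into the goal cell, or None."""
    hints = {puzzle.roles.target, puzzle.roles.distractor} | set(puzzle.roles.in_house)
    forced = [d for d in sorted(hints) if is_forced(puzzle, d)]
    if len(forced) > 1:  # impossible for a valid puzzle
        raise PuzzleValidationError(f"multiple forced digits: {forced}")
    return forced[0] if forced else None


def compute_feedback(puzzle: Puzzle, response: int) -> FeedbackReport:
    """Puzzle- and response-specific explanation, as shown after an attempt.

    in-house: names the house cell already holding the digit. absent: the
    digit could still go in any open house cell. distractor: at least one
    open house cell is not seen by any distractor instance. target: every
    non-goal house cell carries one elimination reason (filled, shares the
    box-constraint box with an instance, or shares a perpendicular line).
    """
    check_digit(response)
    category = classify_response(puzzle, response)
    grid = puzzle.grid
    goal = puzzle.goal
    house_cells = cells_of_house(puzzle.house)
    non_goal = [c for c in house_cells if c != goal]
    empties = [c for c in non_goal if grid_get(grid, c) == EMPTY]
    filled = {c: EliminationReason.FILLED for c in non_goal if grid_get(grid, c) != EMPTY}

    if category is ResponseCategory.IN_HOUSE:
        cell = next(c for c in house_cells if grid_get(grid, c) == response)
        return FeedbackReport(category, cell, [], {})

    if category is ResponseCategory.ABSENT:
        return FeedbackReport(category, None, list(empties), dict(filled))

    instances = digit_cells(grid, response)

    if category is ResponseCategory.DISTRACTOR:
        eliminated = dict(filled)
        open_cells = []
        for cell in empties:
            blockers = [i for i in instances if i in peers(cell)]
            if blockers:
                eliminated[cell] = _constraint_reason(cell, blockers)
            else:
                open_cells.append(cell)
        return FeedbackReport(category, None, open_cells, eliminated)

    eliminated = dict(filled)
    for cell in empties:
        blockers = [i for i in instances if i in peers(cell)]
        if not blockers:
            raise PuzzleValidationError(f"target not eliminated from {cell}")
        eliminated[cell] = _constraint_reason(cell, blockers)
    return FeedbackReport(category, None, [], eliminated)


def _constraint_reason(cell: CellCoord, blockers: list[CellCoord]) -> EliminationReason:
    if any(box_of(b) == box_of(cell) for b in blockers):
        return EliminationReason.BOX_CONSTRAINED
    return EliminationReason.LINE_CONSTRAINED


def write_puzzles(puzzles: list[Puzzle], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_record() for p in puzzles], fh, indent=1)


def read_puzzles(path) -> list[Puzzle]:
    with open(path) as fh:
        return [Puzzle.from_record(rec) for rec in json.load(fh)]
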