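"""Board geometry for 9x9 Sudoku grids.

Coordinates are 1-based ``(row, col)`` tuples; boxes are indexed 0..8 in
row-major order. A *house* is a full row or column addressed by type and
1-based index.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator

import numpy as np

DIGITS = tuple(range(1, 10))
GRID_SIZE = 9
EMPTY = 0

CellCoord = tuple[int, int]


class HouseType(str, Enum):
    ROW = "row"
    COLUMN = "column"


@dataclass(frozen=True)
class HouseSpec:
    """A row or column of the grid, addressed by type and 1-based index."""

    house_type: HouseType
    house_index: int

    def __post_init__(self) -> None:
        if not 1 <= self.house_index <= 9:
            raise ValueError(f"house_index out of range: {self.house_index}")


def check_coord(cell: CellCoord) -> None:
    r, c = cell
    if not (1 <= r <= 9 and 1 <= c <= 9):
        raise ValueError(f"cell coordinate out of range: {cell}")


def check_digit(digit: int) -> None:
    if digit not in DIGITS:
        raise ValueError(f"digit out of range 1..9: {digit}")


def box_of(cell: CellCoord) -> int:
    """Box index 0..8 (row-major) containing *cell*."""
    r, c = cell
    return 3 * ((r - 1) // 3) + (c - 1) // 3


def cells_of_box(box: int) -> list[CellCoord]:
    if not 0 <= box <= 8:
        raise ValueError(f"box index out of range: {box}")
    r0, c0 = 3 * (box // 3) + 1, 3 * (box % 3) + 1
    return [(r, c) for r in range(r0, r0 + 3) for c in range(c0, c0 + 3)]


def cells_of_house(house: HouseSpec) -> list[CellCoord]:
    """The 9 cells of a house; position ``k`` (1-based) is cell index ``k``."""
    i = house.house_index
    if house.house_type is HouseType.ROW:
        return [(i, c) for c in range(1, 10)]
    return [(r, i) for r in range(1, 10)]


def boxes_of_house(house: HouseSpec) -> list[int]:
    """The 3 boxes a house passes through, in cell order."""
    cells = cells_of_house(house)
    return [box_of(cells[k]) for k in (0, 3, 6)]


def peers(cell: CellCoord) -> frozenset[CellCoord]:
    """All 20 cells sharing a row, column, or box with *cell* (exclusive)."""
    check_coord(cell)
    r, c = cell
    out: set[CellCoord] = set()
    out.update((r, cc) for cc in range(1, 10))
    out.update((rr, c) for rr in range(1, 10))
    out.update(cells_of_box(box_of(cell)))
    out.discard(cell)
    return frozenset(out)


def grid_to_string(grid: np.ndarray) -> str:
    """Serialize to the 81-character row-major string, '.' for empty."""
    return "".join(
        "." if grid[r, c] == EMPTY else str(int(grid[r, c]))
        for r in range(9)
        for c in range(9)
    )


def grid_from_string(s: str) -> np.ndarray:
    if len(s) != 81:
        raise ValueError(f"grid string must have 81 characters, got {len(s)}")
    grid = np.zeros((9, 9), dtype=np.int8)
    for i, ch in enumerate(s):
        if ch not in ".0123456789":
            raise ValueError(f"invalid grid character {ch!r} at position {i}")
        grid[i // 9, i % 9] = 0 if ch in ".0" else int(ch)
    return grid


def grid_get(grid: np.ndarray, cell: CellCoord) -> int:
    return int(grid[cell[0] - 1, cell[1] - 1])


def grid_set(grid: np.ndarray, cell: CellCoord, digit: int) -> None:
    grid[cell[0] - 1, cell[1] - 1] = digit


def iter_cells() -> Iterator[CellCoord]:
    for r in range(1, 10):
        for c in range(1, 10):
            yield (r, c)


def grid_is_consistent(grid: np.ndarray) -> bool:
    """True iff no row, column, or box contains a duplicate filled digit."""
    units: list[list[CellCoord]] = []
    units += [cells_of_house(HouseSpec(HouseType.ROW, i)) for i in range(1, 10)]
    units += [cells_of_house(HouseSpec(HouseType.COLUMN, i)) for i in range(1, 10)]
    units += [cells_of_box(b) for b in range(9)]
    for unit in units:
        filled = [grid_get(grid, cell) for cell in unit if grid_get(grid, cell) != EMPTY]
        if len(filled) != len(set(filled)):
            return False
    return True


def digit_cells(grid: np.ndarray, digit: int) -> list[CellCoord]:
    """All cells currently holding *digit*."""
    rows, cols = np.nonzero(grid == digit)
    return [(int(r) + 1, int(c) + 1) for r, c in zip(rows, cols)]
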