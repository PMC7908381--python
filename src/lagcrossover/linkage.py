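"""Link subject coordinates to grid cells and build lag-exposure vectors.

Cells are half-open, ``[edge, next_edge)``, indexed by floor division of the
coordinate offset — every point inside the grid extent belongs to exactly
one cell.  Missing exposure days never raise: they flag the lag vector
incomplete so the stratum assembly can drop the affected day explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExposureGrid, Subject

__all__ = ["LagVector", "OutOfDomainError", "locate_cell",
           "build_lag_vector", "link_cohort", "write_subject_exposures"]


class OutOfDomainError(ValueError):
    """A coordinate falls outside the grid extent."""


@dataclass
class LagVector:
    """Exposure at lags 0..L before ``reference_date``.

    ``values[l]`` is the concentration l days before the reference date;
    ``complete`` is False when any day is uncovered by the grid.
    """

    pollutant: str
    resolution: str
    reference_date: pd.Timestamp
    values: np.ndarray
    complete: bool = field(default=True)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            self.complete = False

    @property
    def max_lag(self) -> int:
        return len(self.values) - 1


def locate_cell(grid: ExposureGrid, x: float, y: float,
                subject_id: str | None = None) -> tuple[int, int]:
    """Containing-cell lookup by half-open floor indexing.

    ``index = floor((coordinate - origin) / cell_size)``; the point exactly
    on a lower cell edge belongs to that cell.
    """
    ix = int(np.floor((x - grid.origin_x) / grid.cell_size))
    iy = int(np.floor((y - grid.origin_y) / grid.cell_size))
    nx, ny = grid.n_cells
    if not (0 <= ix < nx and 0 <= iy < ny):
        who = f" for subject {subject_id}" if subject_id else ""
        raise OutOfDomainError(
            f"point ({x}, {y}){who} lies outside the "
            f"{grid.pollutant}/{grid.resolution} grid extent")
    return ix, iy


def build_lag_vector(grid: ExposureGrid, cell: tuple[int, int],
                     reference_date, L: int = 6) -> LagVector:
    """Exposures on ``reference_date`` and the L preceding days.

    Days outside the grid's coverage yield NaN and an ``incomplete`` flag
    rather than an exception — the caller decides whether to drop the day.
    """
    ix, iy = cell
    nx, ny = grid.n_cells
    if not (0 <= ix < nx and 0 <= iy < ny):
        raise KeyError(f"cell {cell} does not exist on the grid")
    reference_date = pd.Timestamp(reference_date)
    t = grid.date_index(reference_date)
    values = np.full(L + 1, np.nan)
    if t >= 0:
        lo = max(0, t - L)
        window = grid.values[ix, iy, lo:t + 1][::-1]  # lag order 0..L
        values[:len(window)] = window
    return LagVector(grid.pollutant, grid.resolution, reference_date, values)


def link_cohort(grid: ExposureGrid, cohort: list[Subject]) -> pd.DataFrame:
    """Map every subject to its containing cell on ``grid``."""
    rows = []
    for s in cohort:
        ix, iy = locate_cell(grid, s.x, s.y, subject_id=s.subject_id)
        rows.append({"subject_id": s.subject_id, "cell_ix": ix, "cell_iy": iy})
    return pd.DataFrame(rows)


def write_subject_exposures(grid: ExposureGrid, cohort: list[Subject],
                            path) -> Path:
    """Bulk linkage: one long CSV of daily exposure per subject."""
    linked = link_cohort(grid, cohort)
    date_str = grid.dates.strftime("%Y-%m-%d")
    frames = []
    for _, row in linked.iterrows():
        series = grid.values[row.cell_ix, row.cell_iy, :]
        frames.append(pd.DataFrame({
            "subject_id": row.subject_id, "date": date_str, "value": series}))
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, index=False)
    return path
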