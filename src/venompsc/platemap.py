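"""Well-plate geometry and fraction scheduling for nanofractionation.

A post-column fraction collector deposits LC effluent into a 384-well
plate, filling column by column in a serpentine pattern: down the first
column, up the second, and so on, so that consecutive fractions always
land in adjacent wells.  Each well therefore corresponds to a known
slice of chromatographic time, which is what lets downstream modules
re-assemble per-well protein identifications into retention-time traces.

The two collection resolutions in routine use are 6 s per well (one run
of 368 wells fills a plate) and 12 s per well (two runs of 184 wells
share a plate).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PlateLayout",
    "FractionSchedule",
    "WellAddress",
    "PlateCapacityError",
    "serpentine_sequence",
    "well_to_fraction",
    "fraction_to_rt",
    "rt_grid",
    "plan_plate",
    "well_map_frame",
    "run_well_ids",
]


class PlateCapacityError(ValueError):
    """Requested fractions or runs exceed the plate geometry."""


_ROW_LETTERS = string.ascii_uppercase


@dataclass(frozen=True)
class PlateLayout:
    """Rectangular well plate filled column-major in serpentine order.

    Parameters
    ----------
    n_rows, n_cols
        Plate geometry; defaults describe a 384-well plate with rows
        A..P and columns 1..24.
    start_corner
        Corner where fraction 1 is deposited.  Only ``"top_left"`` is
        supported; the first column is filled downward (A1 -> P1), the
        second upward, alternating.
    """

    n_rows: int = 16
    n_cols: int = 24
    start_corner: str = "top_left"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("plate must have at least one row and column")
        if self.n_rows > len(_ROW_LETTERS):
            raise ValueError("row labels limited to A..Z")
        if self.start_corner != "top_left":
            raise ValueError(f"unsupported start corner: {self.start_corner!r}")

    @property
    def capacity(self) -> int:
        return self.n_rows * self.n_cols

    def well_id(self, row: int, col: int) -> str:
        """0-based (row, col) -> label like ``"P2"``."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"well ({row}, {col}) outside plate")
        return f"{_ROW_LETTERS[row]}{col + 1}"

    def parse_well_id(self, well_id: str) -> tuple[int, int]:
        """Label -> 0-based (row, col); raises ValueError on bad labels."""
        well_id = well_id.strip().upper()
        if len(well_id) < 2 or well_id[0] not in _ROW_LETTERS:
            raise ValueError(f"malformed well id: {well_id!r}")
        row = _ROW_LETTERS.index(well_id[0])
        try:
            col = int(well_id[1:]) - 1
        except ValueError as exc:
            raise ValueError(f"malformed well id: {well_id!r}") from exc
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"well {well_id!r} outside {self.n_rows}x{self.n_cols} plate")
        return row, col


@dataclass(frozen=True)
class FractionSchedule:
    """Timing of fraction collection for one or more runs on a plate.

    Parameters
    ----------
    resolution_s
        Seconds of effluent per well (6 or 12 in routine use; any
        positive divisor of the window is accepted).
    collection_window_s
        Total collected effluent per chromatographic run.  The default
        2208 s yields 368 wells at 6 s and 184 wells at 12 s.
    collection_start_min
        LC time at which fraction 1 of the first run begins.
    rt_convention
        ``"midpoint"`` assigns each well the centre of its collection
        window (minimises systematic offset against peak apexes);
        ``"start"`` assigns the window start.
    """

    resolution_s: float = 6.0
    collection_window_s: float = 2208.0
    collection_start_min: float = 0.0
    rt_convention: str = "midpoint"

    def __post_init__(self) -> None:
        if self.resolution_s <= 0:
            raise ValueError("resolution_s must be positive")
        if self.collection_window_s <= 0:
            raise ValueError("collection_window_s must be positive")
        n = self.collection_window_s / self.resolution_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "collection_window_s must be an integer multiple of resolution_s "
                f"(got {self.collection_window_s} / {self.resolution_s})"
            )
        if self.rt_convention not in ("midpoint", "start"):
            raise ValueError(f"unknown rt convention: {self.rt_convention!r}")

    @property
    def wells_per_run(self) -> int:
        return round(self.collection_window_s / self.resolution_s)

    def runs_per_plate(self, layout: PlateLayout) -> int:
        """How many complete runs fit on one plate (at least 1 required)."""
        n = layout.capacity // self.wells_per_run
        if n < 1:
            raise PlateCapacityError(
                f"a run of {self.wells_per_run} wells does not fit a "
                f"{layout.capacity}-well plate"
            )
        return n


@dataclass(frozen=True)
class WellAddress:
    """Physical location of one fraction: plate, run, well and time."""

    plate_index: int
    run_index: int
    well_id: str
    fraction_index: int
    rt_min: float


def serpentine_sequence(layout: PlateLayout, n: int) -> list[str]:
    """First *n* well IDs in serpentine collection order.

    Column 1 is filled top to bottom (A1..P1), column 2 bottom to top
    (P2..A2), and so on alternating.  Raises :class:`PlateCapacityError`
    if *n* exceeds plate capacity.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n > layout.capacity:
        raise PlateCapacityError(f"{n} fractions exceed plate capacity {layout.capacity}")
    ids: list[str] = []
    for col in range(layout.n_cols):
        rows = range(layout.n_rows) if col % 2 == 0 else range(layout.n_rows - 1, -1, -1)
        for row in rows:
            ids.append(layout.well_id(row, col))
            if len(ids) == n:
                return ids
    return ids


def well_to_fraction(layout: PlateLayout, well_id: str) -> int:
    """1-based plate-level fraction index of a well under serpentine order."""
    row, col = layout.parse_well_id(well_id)
    within = row if col % 2 == 0 else layout.n_rows - 1 - row
    return col * layout.n_rows + within + 1


def fraction_to_rt(schedule: FractionSchedule, fraction_index: int) -> float:
    """Retention time (minutes) assigned to a fraction of one run.

    Under the default midpoint convention fraction *i* maps to
    ``start + (i - 0.5) * resolution / 60``.
    """
    if fraction_index < 1:
        raise ValueError("fraction_index must be >= 1")
    if fraction_index > schedule.wells_per_run:
        raise PlateCapacityError(
            f"fraction {fraction_index} beyond run length {schedule.wells_per_run}"
        )
    offset = 0.5 if schedule.rt_convention == "midpoint" else 1.0
    return schedule.collection_start_min + (fraction_index - offset) * schedule.resolution_s / 60.0


def rt_grid(schedule: FractionSchedule) -> list[float]:
    """Retention times of every fraction of one run, in order."""
    return [fraction_to_rt(schedule, i) for i in range(1, schedule.wells_per_run + 1)]


def plan_plate(
    layout: PlateLayout, schedule: FractionSchedule, n_plates: int
) -> dict[str, int]:
    """Capacity report for an injection sequence of *n_plates* plates.

    Returns wells_per_run, runs_per_plate and venoms_per_sequence (one
    venom per chromatographic run).
    """
    if n_plates < 0:
        raise ValueError("n_plates must be nonnegative")
    runs = schedule.runs_per_plate(layout)
    return {
        "wells_per_run": schedule.wells_per_run,
        "runs_per_plate": runs,
        "venoms_per_sequence": n_plates * runs,
    }


def well_map_frame(
    layout: PlateLayout,
    schedule: FractionSchedule,
    n_plates: int = 1,
) -> pd.DataFrame:
    """Full fraction <-> well <-> retention-time map as a DataFrame.

    Columns: plate_index, run_index, fraction_index (1-based within its
    run), well_id, rt_min.  Successive runs on one plate continue the
    same serpentine order, so run 2 of a 12 s plate starts at plate
    fraction 185.
    """
    runs = schedule.runs_per_plate(layout)
    wells = serpentine_sequence(layout, schedule.wells_per_run * runs)
    rts = rt_grid(schedule)
    records = []
    for plate in range(1, n_plates + 1):
        for run in range(1, runs + 1):
            base = (run - 1) * schedule.wells_per_run
            for i in range(schedule.wells_per_run):
                records.append(
                    {
                        "plate_index": plate,
                        "run_index": run,
                        "fraction_index": i + 1,
                        "well_id": wells[base + i],
                        "rt_min": rts[i],
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["plate_index", "run_index", "fraction_index", "well_id", "rt_min"]
    )


def run_well_ids(layout: PlateLayout, schedule: FractionSchedule, run_index: int = 1) -> list[str]:
    """Well IDs of one run, in fraction order."""
    runs = schedule.runs_per_plate(layout)
    if not (1 <= run_index <= runs):
        raise PlateCapacityError(f"run {run_index} outside 1..{runs}")
    wells = serpentine_sequence(layout, schedule.wells_per_run * runs)
    base = (run_index - 1) * schedule.wells_per_run
    return wells[base : base + schedule.wells_per_run]
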