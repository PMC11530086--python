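"""Intraoperative-hypotension exposure metrics computed on a regular MAP grid.

Every candidate definition of intraoperative hypotension (IOH) used in the
selection pipeline is a scalar summary of one anesthetic's mean-arterial-
pressure (MAP) record, resampled to a homogeneous 15-second grid:

* ``sustained_min_map`` — the lowest MAP threshold that was attained and not
  exceeded for N *contiguous* minutes (the upper "low MAP" limit of the
  lowest sustained episode).  Computed as a sliding-window maximum followed
  by a minimum over windows.
* ``cumulative_min_map`` — the lowest threshold at or below which the
  *total* (possibly interrupted) time reached N minutes; an order statistic
  of the grid values.
* ``abs_time_below`` — total minutes with MAP strictly under a fixed
  threshold.
* ``rel_time_below`` — the same, as a fraction of the anesthesia duration.

A grid tick represents a 15-second exposure interval, so "N minutes" means
``4 * N`` consecutive ticks and each tick below a threshold contributes
0.25 min of exposure time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .signal import MAPGrid

TICKS_PER_MINUTE = 4
MINUTES_PER_TICK = 0.25

#: MAP thresholds (mmHg) used by the time-below definitions.
THRESHOLDS_MMHG = (50, 55, 60, 65, 70, 75, 80)

#: Episode durations (minutes) in the core registry.
DURATIONS_CORE_MIN = (1, 3, 5, 10)

#: Episode durations including the 15-minute extension used in the
#: descriptive tables.
DURATIONS_EXTENDED_MIN = (1, 3, 5, 10, 15)

KINDS = ("sustained_min_map", "cumulative_min_map", "abs_time_below", "rel_time_below")
TIME_BELOW_KINDS = ("abs_time_below", "rel_time_below")


@dataclass(frozen=True, order=True)
class IOHDefinition:
    """One named exposure metric: a kind plus its duration or threshold.

    ``parameter`` is minutes for the episode kinds and a MAP threshold in
    mmHg for the time-below kinds.
    """

    kind: str
    parameter: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown IOH definition kind: {self.kind!r}")
        if self.parameter <= 0:
            raise ValueError("definition parameter must be positive")

    @property
    def is_time_below(self) -> bool:
        return self.kind in TIME_BELOW_KINDS

    @property
    def name(self) -> str:
        """Stable column name, e.g. ``sust_5min``, ``rel_t_lt80``."""
        p = int(self.parameter) if float(self.parameter).is_integer() else self.parameter
        if self.kind == "sustained_min_map":
            return f"sust_{p}min"
        if self.kind == "cumulative_min_map":
            return f"cum_{p}min"
        if self.kind == "abs_time_below":
            return f"abs_t_lt{p}"
        return f"rel_t_lt{p}"

    @property
    def label(self) -> str:
        p = int(self.parameter) if float(self.parameter).is_integer() else self.parameter
        if self.kind == "sustained_min_map":
            return f"Lowest MAP sustained for {p} min"
        if self.kind == "cumulative_min_map":
            return f"Lowest MAP for {p} cumulative min"
        if self.kind == "abs_time_below":
            return f"Absolute time with MAP < {p} mmHg"
        return f"Relative time with MAP < {p} mmHg"


def default_registry(which: str = "tables_24") -> list[IOHDefinition]:
    """Return the candidate-definition registry.

    ``tables_24`` uses episode durations {1, 3, 5, 10, 15} min (24 entries);
    ``methods_22`` restricts to {1, 3, 5, 10} min (22 entries).  Both are in
    circulation in the literature this registry mirrors; neither is asserted
    as canonical.
    """
    if which == "tables_24":
        durations: tuple[int, ...] = DURATIONS_EXTENDED_MIN
    elif which == "methods_22":
        durations = DURATIONS_CORE_MIN
    else:
        raise ValueError(f"unknown registry: {which!r}")
    reg = [IOHDefinition("sustained_min_map", d) for d in durations]
    reg += [IOHDefinition("cumulative_min_map", d) for d in durations]
    reg += [IOHDefinition("abs_time_below", t) for t in THRESHOLDS_MMHG]
    reg += [IOHDefinition("rel_time_below", t) for t in THRESHOLDS_MMHG]
    return reg


def registry_from_names(names: Iterable[str]) -> list[IOHDefinition]:
    by_name = {d.name: d for d in default_registry("tables_24")}
    out = []
    for n in names:
        if n not in by_name:
            raise ValueError(f"unknown definition name: {n!r}")
        out.append(by_name[n])
    return out


def _window_ticks(duration_min: float) -> int:
    w = duration_min * TICKS_PER_MINUTE
    if abs(w - round(w)) > 1e-9:
        raise ValueError("duration must be a multiple of 0.25 min")
    return int(round(w))


def lowest_sustained_map(grid: MAPGrid | np.ndarray, duration_min: float) -> float:
    """Lowest MAP threshold held continuously for ``duration_min`` minutes.

    Over all contiguous windows of exactly ``4 * duration_min`` ticks, take
    the maximum MAP within each window, then the minimum over windows.  This
    equals the smallest threshold T such that MAP stayed at or below T for
    the full duration, and is always an attained grid value.  Returns NaN if
    the record is shorter than the window.
    """
    values = grid.values if isinstance(grid, MAPGrid) else np.asarray(grid, dtype=float)
    w = _window_ticks(duration_min)
    if values.size < w:
        return float("nan")
    windows = np.lib.stride_tricks.sliding_window_view(values, w)
    return float(windows.max(axis=1).min())


def lowest_cumulative_map(grid: MAPGrid | np.ndarray, duration_min: float) -> float:
    """Lowest threshold reached for ``duration_min`` total (interruptible) minutes.

    The k-th smallest grid value with ``k = 4 * duration_min``: the smallest
    T such that total time with MAP <= T is at least the duration.  NaN on
    records shorter than k ticks.
    """
    values = grid.values if isinstance(grid, MAPGrid) else np.asarray(grid, dtype=float)
    k = _window_ticks(duration_min)
    if values.size < k:
        return float("nan")
    return float(np.partition(values, k - 1)[k - 1])


def time_below(grid: MAPGrid | np.ndarray, threshold_mmhg: float) -> float:
    """Total minutes with MAP strictly below the threshold (0.25 min per tick)."""
    values = grid.values if isinstance(grid, MAPGrid) else np.asarray(grid, dtype=float)
    if values.size == 0:
        raise ValueError("empty grid")
    return MINUTES_PER_TICK * int((values < threshold_mmhg).sum())


def relative_time_below(grid: MAPGrid, threshold_mmhg: float) -> float:
    """Fraction of the anesthesia duration spent with MAP below the threshold.

    The denominator is the time from first to last retained measurement; the
    ratio is clipped into [0, 1] (a one-tick record nominally exposes 0.25
    min over a zero-length interval).  NaN for zero-duration records.
    """
    if grid.anesthesia_duration_min <= 0:
        return float("nan")
    frac = time_below(grid, threshold_mmhg) / grid.anesthesia_duration_min
    return float(min(max(frac, 0.0), 1.0))


def compute_definition(grid: MAPGrid, definition: IOHDefinition) -> float:
    if definition.kind == "sustained_min_map":
        return lowest_sustained_map(grid, definition.parameter)
    if definition.kind == "cumulative_min_map":
        return lowest_cumulative_map(grid, definition.parameter)
    if definition.kind == "abs_time_below":
        return time_below(grid, definition.parameter)
    if definition.kind == "rel_time_below":
        return relative_time_below(grid, definition.parameter)
    raise ValueError(f"unknown IOH definition kind: {definition.kind!r}")


def compute_all_definitions(
    grid: MAPGrid, registry: Iterable[IOHDefinition] | None = None
) -> Mapping[str, float]:
    """Evaluate every registry entry on one grid; NaN flags short records."""
    if registry is None:
        registry = default_registry("tables_24")
    return {d.name: compute_definition(grid, d) for d in registry}


def definition_table(
    grids: Mapping[object, MAPGrid], registry: Iterable[IOHDefinition] | None = None
) -> "pd.DataFrame":
    """Evaluate the registry on every patient's grid.

    Returns one row per patient with one column per definition plus the
    anesthesia duration; NaN marks definitions undefined on short records.
    """
    import pandas as pd

    if registry is None:
        registry = default_registry("tables_24")
    registry = list(registry)
    rows = []
    for pid, grid in grids.items():
        row = {"patient_id": pid, "anesthesia_duration_min": grid.anesthesia_duration_min}
        row.update(compute_all_definitions(grid, registry))
        rows.append(row)
    cols = ["patient_id", "anesthesia_duration_min"] + [d.name for d in registry]
    return pd.DataFrame(rows, columns=cols)
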