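"""Artifact cleaning and resampling of intraoperative blood-pressure records.

Anesthesia charting systems log spurious values (flushed arterial lines,
cuff failures, transcription errors).  Before any hypotension metric is
computed, each patient's record passes through six cut-off rules:

1. systolic >= 300 mmHg
2. systolic <= 20 mmHg
3. diastolic <= 5 mmHg
4. diastolic >= 225 mmHg
5. systolic <= diastolic + 5 mmHg
6. any pressure channel outside the patient's mean +/- 3 SD

Rules 1-5 act per sample on the raw values; rule 6 is computed once, on the
survivors of rules 1-5, in a single non-iterated pass.  A sample failing
several rules is attributed to the lowest-numbered one.  Surviving records
are then linearly interpolated to a homogeneous 15-second MAP grid, with no
extrapolation beyond the first and last retained measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID_STEP_S = 15.0

RULE_DESCRIPTIONS = {
    1: "systolic >= 300 mmHg",
    2: "systolic <= 20 mmHg",
    3: "diastolic <= 5 mmHg",
    4: "diastolic >= 225 mmHg",
    5: "systolic <= diastolic + 5 mmHg",
    6: "outside mean +/- 3 SD of patient's pressures",
}


@dataclass
class BPSeries:
    """One patient's raw timestamped blood-pressure measurements.

    Timestamps are seconds from anesthesia start and must be strictly
    increasing.  Channels may contain NaN where a value was not recorded.
    """

    patient_id: object
    timestamp_s: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray

    def __post_init__(self) -> None:
        self.timestamp_s = np.asarray(self.timestamp_s, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        self.map = np.asarray(self.map, dtype=float)
        if self.timestamp_s.size == 0:
            raise ValueError("BPSeries requires at least one sample")
        if np.any(np.diff(self.timestamp_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.timestamp_s.size)


@dataclass
class CleaningReport:
    """Per-rule removal counts plus per-sample attribution codes (0 = kept)."""

    patient_id: object
    n_input: int
    removed_by_rule: dict[int, int]
    reason_codes: np.ndarray
    n_retained: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_retained = self.n_input - sum(self.removed_by_rule.values())
        assert self.n_retained == int((self.reason_codes == 0).sum())

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_by_rule": {str(k): int(v) for k, v in self.removed_by_rule.items()},
        }


@dataclass
class MAPGrid:
    """A regular 15-second MAP sequence for one anesthetic, post-cleaning.

    ``anesthesia_duration_min`` is the time from first to last retained
    measurement; it is the denominator of the relative-time definitions.
    """

    patient_id: object
    start_s: float
    values: np.ndarray
    anesthesia_duration_min: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("MAPGrid values must be finite and positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def timestamps_s(self) -> np.ndarray:
        return self.start_s + GRID_STEP_S * np.arange(self.values.size)


class NoValidBloodPressure(ValueError):
    """All samples of a record were removed: 'no valid blood pressure'."""


def derive_map(sbp: float, dbp: float) -> float:
    """Standard estimate MAP = (SBP + 2 DBP) / 3, for samples missing MAP."""
    if not (sbp > dbp):
        raise ValueError("derive_map requires sbp > dbp")
    return (sbp + 2.0 * dbp) / 3.0


def _rule_codes(
    sbp: np.ndarray, dbp: np.ndarray, map_: np.ndarray, channels: tuple[str, ...]
) -> np.ndarray:
    """Vectorized attribution of each sample to the first violated rule."""
    n = sbp.size
    codes = np.zeros(n, dtype=np.int8)

    def assign(rule: int, mask: np.ndarray) -> None:
        codes[(codes == 0) & np.nan_to_num(mask, nan=False)] = rule

    assign(1, sbp >= 300)
    assign(2, sbp <= 20)
    assign(3, dbp <= 5)
    assign(4, dbp >= 225)
    assign(5, sbp <= dbp + 5)

    survivors = codes == 0
    chan = {"sbp": sbp, "dbp": dbp, "map": map_}
    viol6 = np.zeros(n, dtype=bool)
    for name in channels:
        x = chan[name][survivors]
        x = x[np.isfinite(x)]
        if x.size == 0:
            continue
        mu, sd = float(x.mean()), float(x.std())
        viol6 |= np.nan_to_num(np.abs(chan[name] - mu) > 3.0 * sd, nan=False)
    assign(6, viol6)
    return codes


def clean_artifacts(
    series: BPSeries, rule6_channels: tuple[str, ...] = ("sbp", "dbp", "map")
) -> tuple[BPSeries, CleaningReport]:
    """Apply the six cut-off rules to one record.

    ``rule6_channels`` selects which pressure channels the 3-SD rule screens
    (default: all three; pass ``("map",)`` for the MAP-only reading).
    Samples with a missing MAP get it derived from SBP/DBP when possible;
    samples missing both MAP and a usable SBP/DBP pair are dropped with a
    missing-channel code (-1).  Raises :class:`NoValidBloodPressure` when no
    sample survives.
    """
    map_ = series.map.copy()
    derivable = np.isnan(map_) & np.isfinite(series.sbp) & np.isfinite(series.dbp) & (
        series.sbp > series.dbp
    )
    map_[derivable] = (series.sbp[derivable] + 2.0 * series.dbp[derivable]) / 3.0

    codes = _rule_codes(series.sbp, series.dbp, map_, rule6_channels)
    missing = (codes == 0) & ~np.isfinite(map_)
    full_codes = codes.astype(np.int8).copy()
    full_codes[missing] = -1

    keep = full_codes == 0
    if not keep.any():
        raise NoValidBloodPressure(
            f"patient {series.patient_id}: no valid blood pressure after cleaning"
        )
    cleaned = BPSeries(
        patient_id=series.patient_id,
        timestamp_s=series.timestamp_s[keep],
        sbp=series.sbp[keep],
        dbp=series.dbp[keep],
        map=map_[keep],
    )
    report = CleaningReport(
        patient_id=series.patient_id,
        n_input=len(series),
        removed_by_rule={r: int((full_codes == r).sum()) for r in (1, 2, 3, 4, 5, 6)}
        | {-1: int((full_codes == -1).sum())},
        reason_codes=full_codes,
    )
    return cleaned, report


def interpolate_to_grid(series: BPSeries, max_gap_s: float | None = None) -> MAPGrid:
    """Resample a cleaned series to the homogeneous 15-second MAP grid.

    Grid ticks run from the first retained measurement to the last, every
    15 s; values are linear between bracketing measurements and never
    extrapolated.  ``max_gap_s`` optionally fails records with an internal
    gap longer than the cap (default: no cap).  Records with fewer than two
    samples cannot be gridded and raise ``ValueError``.
    """
    if len(series) < 2:
        raise ValueError(
            f"patient {series.patient_id}: fewer than 2 valid samples, cannot interpolate"
        )
    t = series.timestamp_s
    if max_gap_s is not None and np.any(np.diff(t) > max_gap_s):
        raise ValueError(f"patient {series.patient_id}: gap exceeds {max_gap_s} s")
    n_ticks = int(np.floor((t[-1] - t[0]) / GRID_STEP_S)) + 1
    ticks = t[0] + GRID_STEP_S * np.arange(n_ticks)
    values = np.interp(ticks, t, series.map)
    return MAPGrid(
        patient_id=series.patient_id,
        start_s=float(t[0]),
        values=values,
        anesthesia_duration_min=float(t[-1] - t[0]) / 60.0,
    )


def clean_vitals_table(
    vitals: pd.DataFrame, rule6_channels: tuple[str, ...] = ("sbp", "dbp", "map")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized cleaning of a long-format vitals table.

    ``vitals`` needs columns patient_id, timestamp_s, sbp, dbp, map (sorted
    or sortable by patient and time).  Returns the retained rows and a
    per-patient report frame with one count column per rule; patients left
    with no valid sample appear with ``n_retained == 0``.
    """
    df = vitals.sort_values(["patient_id", "timestamp_s"], kind="stable").reset_index(drop=True)
    sbp = df["sbp"].to_numpy(float)
    dbp = df["dbp"].to_numpy(float)
    map_ = df["map"].to_numpy(float).copy()
    derivable = np.isnan(map_) & np.isfinite(sbp) & np.isfinite(dbp) & (sbp > dbp)
    map_[derivable] = (sbp[derivable] + 2.0 * dbp[derivable]) / 3.0

    codes = np.zeros(len(df), dtype=np.int8)

    def assign(rule: int, mask: np.ndarray) -> None:
        codes[(codes == 0) & np.nan_to_num(mask, nan=False)] = rule

    assign(1, sbp >= 300)
    assign(2, sbp <= 20)
    assign(3, dbp <= 5)
    assign(4, dbp >= 225)
    assign(5, sbp <= dbp + 5)

    # rule 6: per-patient mean/SD on survivors of rules 1-5, any listed channel
    surv = codes == 0
    chan = {"sbp": sbp, "dbp": dbp, "map": map_}
    pid = df["patient_id"]
    viol6 = np.zeros(len(df), dtype=bool)
    for name in rule6_channels:
        x = pd.Series(np.where(surv, chan[name], np.nan))
        g = x.groupby(pid.values)
        mu = g.transform("mean").to_numpy()
        # population SD via E[x^2] - E[x]^2 (matches np.std on the per-series path)
        m2 = pd.Series(x**2).groupby(pid.values).transform("mean").to_numpy()
        sd = np.sqrt(np.maximum(m2 - mu**2, 0.0))
        viol6 |= np.nan_to_num(np.abs(chan[name] - mu) > 3.0 * sd, nan=False)
    assign(6, viol6)
    codes[(codes == 0) & ~np.isfinite(map_)] = -1

    out = df[codes == 0].copy()
    out["map"] = map_[codes == 0]
    counts = (
        pd.DataFrame({"patient_id": pid, "rule": codes})
        .groupby(["patient_id", "rule"])
        .size()
        .unstack(fill_value=0)
    )
    counts.columns = counts.columns.astype(int)
    counts = counts.reindex(columns=[-1, 0, 1, 2, 3, 4, 5, 6], fill_value=0)
    counts = counts.rename(
        columns={
            r: (f"removed_rule{r}" if r > 0 else ("kept" if r == 0 else "removed_missing"))
            for r in (-1, 0, 1, 2, 3, 4, 5, 6)
        }
    )
    counts = counts.rename_axis(None, axis=1).reset_index()
    counts["n_retained"] = counts["kept"]
    return out, counts


def grids_from_vitals(
    cleaned_vitals: pd.DataFrame, max_gap_s: float | None = None
) -> tuple[dict, pd.DataFrame]:
    """Interpolate every patient of a cleaned vitals table to a MAP grid.

    Returns ``(grids, exclusions)``: a patient_id -> MAPGrid mapping and a
    frame of patients that could not be gridded, with reasons (mirrors a
    study-flowchart attrition log).
    """
    df = cleaned_vitals.sort_values(["patient_id", "timestamp_s"], kind="stable")
    pids = df["patient_id"].to_numpy()
    ts = df["timestamp_s"].to_numpy(float)
    maps = df["map"].to_numpy(float)
    uniq, starts = np.unique(pids, return_index=True)
    bounds = np.append(starts, len(df))
    grids: dict = {}
    excluded = []
    for i, pid in enumerate(uniq):
        t = ts[bounds[i] : bounds[i + 1]]
        m = maps[bounds[i] : bounds[i + 1]]
        if t.size < 2:
            excluded.append({"patient_id": pid, "reason": "fewer than 2 valid samples"})
            continue
        if max_gap_s is not None and np.any(np.diff(t) > max_gap_s):
            excluded.append({"patient_id": pid, "reason": f"gap exceeds {max_gap_s} s"})
            continue
        n_ticks = int(np.floor((t[-1] - t[0]) / GRID_STEP_S)) + 1
        ticks = t[0] + GRID_STEP_S * np.arange(n_ticks)
        grids[pid] = MAPGrid(
            patient_id=pid,
            start_s=float(t[0]),
            values=np.interp(ticks, t, m),
            anesthesia_duration_min=float(t[-1] - t[0]) / 60.0,
        )
    return grids, pd.DataFrame(excluded, columns=["patient_id", "reason"])
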