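"""Outcome-specific model inputs for the hypotension-definition models.

Assembles, for one candidate IOH definition and one outcome, the regression
design used throughout selection and estimation:

* the definition value, winsorized at the 99th percentile and expanded in a
  natural cubic spline basis (3 df by default), plus a binary spike-at-zero
  indicator for the time-below definitions (which have a point mass at zero
  exposure);
* adjustment covariates: sex, surgical specialty and ASA class as dummies;
  age and BMI as 2-df natural splines; duration of surgery, time from
  admission to surgery and comorbidity score as 3-df natural splines;
* the outcome: the 30-day mortality flag, or length of stay log-transformed
  after setting in-hospital deaths to infinity and trimming the top 1%.

Winsorization caps and spline knots are computed once on the dataset half
being modeled, before any cross-validation, and recorded in the matrix
metadata so that estimation-stage predictions reuse the same
parameterization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import IOHDefinition

SPECIALTIES = (
    "Urology, gynecology, general surgery",
    "Maxillofacial, ENT, derma",
    "Orthopedics, trauma",
    "Neurosurgery",
    "Non-OR anesthesia, obstetrics",
    "Robotic surgery",
)

#: Reference levels of the categorical covariates (the "average patient").
REFERENCE_SEX = "male"
REFERENCE_SPECIALTY = SPECIALTIES[0]
REFERENCE_ASA = 2

OUTCOMES = ("mortality", "hlos", "pacu")


@dataclass
class ModelSettings:
    """Tunable parameterization shared by shaping and estimation stages."""

    ioh_df: int = 3
    big_df: int = 3  # duration, time-to-surgery, comorbidity
    small_df: int = 2  # age, BMI
    winsor_percentile: float = 0.99
    trim_fraction: float = 0.01
    univariable: bool = False


def winsorize(
    values: np.ndarray, percentile: float = 0.99, cap: float | None = None
) -> tuple[np.ndarray, float]:
    """Cap the upper tail at the empirical percentile (lower tail untouched).

    Returns the capped values and the cap so it can be recorded and reused.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        raise ValueError("winsorize requires at least 2 finite values")
    if cap is None:
        cap = float(np.quantile(finite, percentile))
    return np.minimum(values, cap), cap


def zero_spike_indicator(values: np.ndarray, kind: str) -> np.ndarray:
    """Binary indicator of zero exposure, defined only for time-below kinds.

    The time-below definitions pile up at exactly zero (patients with no
    hypotensive time at all); the indicator lets the spline model the
    positive part without being anchored by that point mass.
    """
    if kind not in ("abs_time_below", "rel_time_below"):
        raise ValueError(
            f"zero-spike indicator is defined only for time-below definitions, got {kind!r}"
        )
    values = np.asarray(values, dtype=float)
    return (values == 0).astype(float)


def _quantile_knots(values: np.ndarray, df: int) -> np.ndarray:
    """Boundary knots at the extremes, df-1 interior knots at quantiles."""
    probs = np.linspace(0, 1, df + 1)
    return np.quantile(values, probs)


def natural_spline_basis(
    values: np.ndarray, df: int, knots: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Natural cubic spline basis (no intercept column).

    Uses the truncated-power natural basis: the linear term plus, for each
    interior knot, a difference of scaled truncated cubics constrained to be
    linear beyond the boundary knots.  ``df`` columns require ``df + 1``
    distinct knots; with tied quantiles the basis degrades gracefully and a
    degenerate variable (fewer than 3 distinct knots) falls back to a single
    linear column with a warning.

    Returns ``(basis, knots, linear_fallback)``.
    """
    x = np.asarray(values, dtype=float)
    if knots is None:
        if np.unique(x[np.isfinite(x)]).size < df + 1:
            knots_arr = np.array([])
        else:
            knots_arr = np.unique(_quantile_knots(x[np.isfinite(x)], df))
    else:
        knots_arr = np.unique(np.asarray(knots, dtype=float))
    if knots_arr.size < 3:
        if knots is None:
            warnings.warn(
                f"fewer distinct values than knots for df={df}; falling back to linear term",
                stacklevel=2,
            )
        return x[:, None].copy(), np.array([]), True

    xi = knots_arr
    K = xi.size
    xiK, xiK1 = xi[-1], xi[-2]

    def trunc3(z: np.ndarray) -> np.ndarray:
        return np.clip(z, 0.0, None) ** 3

    def d(k: int) -> np.ndarray:
        return (trunc3(x - xi[k]) - trunc3(x - xiK)) / (xiK - xi[k])

    dlast = (trunc3(x - xiK1) - trunc3(x - xiK)) / (xiK - xiK1)
    cols = [x] + [d(k) - dlast for k in range(K - 2)]
    return np.column_stack(cols), xi, False


def trim_and_log_los(
    los: np.ndarray,
    died_before_discharge: np.ndarray,
    trim_fraction: float = 0.01,
    patient_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deaths to infinity, trim the top fraction, log the remainder.

    Patients who died before discharge get an infinite stay, then the
    largest ``ceil(trim_fraction * n)`` values are removed (infinities
    first; exact ties broken by patient id for determinism) and the natural
    log of the kept values is returned together with the kept mask — the
    analysis thereafter describes the (1 - trim) 'best' patients.
    """
    if not (0.0 < trim_fraction < 0.5):
        raise ValueError("trim_fraction must lie in (0, 0.5)")
    los = np.asarray(los, dtype=float).copy()
    died = np.asarray(died_before_discharge, dtype=bool)
    los[died] = np.inf
    n = los.size
    if patient_ids is None:
        patient_ids = np.arange(n)
    m = math.ceil(trim_fraction * n)
    # descending value, ascending patient id among ties
    order = np.lexsort((np.asarray(patient_ids), -los))
    kept = np.ones(n, dtype=bool)
    kept[order[:m]] = False
    if np.any(los[kept] <= 0):
        raise ValueError("length of stay must be positive")
    if np.any(np.isinf(los[kept])):
        raise ValueError(
            "deaths before discharge exceed the trim fraction; "
            "retained log-stays must be finite"
        )
    return np.log(los[kept]), kept


@dataclass
class ModelMatrix:
    """A ready-to-fit design: outcome, named columns, and provenance."""

    outcome: str
    y: np.ndarray
    X: pd.DataFrame
    groups: dict[str, list[str]]
    patient_ids: np.ndarray
    meta: dict
    exclusions: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.y.size)

    def columns_without(self, group: str) -> list[str]:
        if group not in self.groups:
            raise ValueError(f"unknown variable group: {group!r}")
        drop = set(self.groups[group])
        return [c for c in self.X.columns if c not in drop]


def _spline_block(
    name: str, values: np.ndarray, df: int, meta: dict, knots: Sequence[float] | None = None
) -> pd.DataFrame:
    basis, used_knots, fallback = natural_spline_basis(values, df, knots=knots)
    meta["splines"][name] = {
        "df": int(basis.shape[1]),
        "knots": [float(k) for k in used_knots],
        "linear_fallback": bool(fallback),
    }
    cols = (
        [f"{name}_lin"]
        if fallback
        else [f"{name}_ns{i + 1}" for i in range(basis.shape[1])]
    )
    return pd.DataFrame(basis, columns=cols)


def build_model_matrix(
    cohort: pd.DataFrame,
    definition: IOHDefinition,
    outcome: str,
    settings: ModelSettings | None = None,
) -> ModelMatrix:
    """Assemble the design for one definition and one outcome.

    ``cohort`` is a per-patient table carrying covariates, outcomes and the
    computed definition columns.  Row exclusions (missing definition value,
    direct-to-ICU patients for the PACU outcome, trimmed stays) are logged
    in ``exclusions``; winsorization caps and knots land in ``meta``.
    """
    if settings is None:
        settings = ModelSettings()
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome: {outcome!r}")
    col = definition.name
    if col not in cohort.columns:
        raise ValueError(f"definition {col!r} not computed on this cohort")

    df = cohort.reset_index(drop=True)
    exclusions: list[dict] = []

    missing = df[col].isna()
    if missing.any():
        exclusions.append(
            {
                "reason": "record shorter than definition window",
                "n": int(missing.sum()),
                "patient_ids": df.loc[missing, "patient_id"].tolist(),
            }
        )
        df = df[~missing].reset_index(drop=True)

    if outcome == "pacu":
        icu = df["icu_direct"].astype(bool)
        if icu.all() or df.empty:
            raise ValueError("empty analysis set: every patient went directly to ICU")
        if icu.any():
            exclusions.append(
                {"reason": "admitted directly to ICU", "n": int(icu.sum()),
                 "patient_ids": df.loc[icu, "patient_id"].tolist()}
            )
            df = df[~icu].reset_index(drop=True)

    meta: dict = {
        "definition": {"kind": definition.kind, "parameter": definition.parameter,
                       "name": definition.name},
        "outcome": outcome,
        "settings": asdict(settings),
        "winsor_caps": {},
        "splines": {},
        "reference": {"sex": REFERENCE_SEX, "specialty": REFERENCE_SPECIALTY,
                      "asa": REFERENCE_ASA},
    }

    # outcome vector (trimming happens before the design is cut to rows)
    if outcome == "mortality":
        y = df["died_30d"].to_numpy(float)
    else:
        los_col = "hlos" if outcome == "hlos" else "pacu_los"
        # the set-to-infinity rule applies to the hospital stay of patients
        # who died before discharge; PACU stays are trimmed as observed
        died = (
            df["died_before_discharge"].to_numpy(bool)
            if outcome == "hlos"
            else np.zeros(len(df), dtype=bool)
        )
        y, kept = trim_and_log_los(
            df[los_col].to_numpy(float),
            died,
            trim_fraction=settings.trim_fraction,
            patient_ids=df["patient_id"].to_numpy(),
        )
        exclusions.append(
            {"reason": f"trimmed top {settings.trim_fraction:.1%} of {los_col}",
             "n": int((~kept).sum()), "patient_ids": df.loc[~kept, "patient_id"].tolist()}
        )
        df = df[kept].reset_index(drop=True)

    # exposure block
    raw = df[col].to_numpy(float)
    wins, cap = winsorize(raw, settings.winsor_percentile)
    meta["winsor_caps"][col] = cap
    blocks: dict[str, pd.DataFrame] = {}
    ioh_block = _spline_block(col, wins, settings.ioh_df, meta)
    if definition.is_time_below:
        ioh_block[f"{col}_is_zero"] = zero_spike_indicator(raw, definition.kind)
    blocks["ioh"] = ioh_block

    if not settings.univariable:
        blocks["sex"] = pd.DataFrame(
            {"sex_female": (df["sex"] == "female").astype(float)}
        )
        spec_cols = {}
        for s in SPECIALTIES:
            if s == REFERENCE_SPECIALTY:
                continue
            key = "specialty_" + s.split(",")[0].split()[0].lower()
            spec_cols[key] = (df["specialty"] == s).astype(float)
        blocks["specialty"] = pd.DataFrame(spec_cols)
        blocks["asa"] = pd.DataFrame(
            {f"asa_{a}": (df["asa"] == a).astype(float) for a in (1, 3, 4)}
        )
        blocks["age"] = _spline_block("age", df["age"].to_numpy(float), settings.small_df, meta)
        bmi_w, bmi_cap = winsorize(df["bmi"].to_numpy(float), settings.winsor_percentile)
        meta["winsor_caps"]["bmi"] = bmi_cap
        blocks["bmi"] = _spline_block("bmi", bmi_w, settings.small_df, meta)
        dur_w, dur_cap = winsorize(
            df["duration_surgery"].to_numpy(float), settings.winsor_percentile
        )
        meta["winsor_caps"]["duration_surgery"] = dur_cap
        blocks["duration"] = _spline_block("duration", dur_w, settings.big_df, meta)
        blocks["time_to_surgery"] = _spline_block(
            "time_to_surgery", df["time_to_surgery"].to_numpy(float), settings.big_df, meta
        )
        blocks["comorbidity"] = _spline_block(
            "comorbidity", df["comorbidity_score"].to_numpy(float), settings.big_df, meta
        )

    blocks["intercept"] = pd.DataFrame({"intercept": np.ones(len(df))})

    X = pd.concat(blocks.values(), axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"design contains missing cells in columns {bad}")
    groups = {g: list(b.columns) for g, b in blocks.items()}
    return ModelMatrix(
        outcome=outcome,
        y=np.asarray(y, dtype=float),
        X=X,
        groups=groups,
        patient_ids=df["patient_id"].to_numpy(),
        meta=meta,
        exclusions=exclusions,
    )


def rows_for_patient(
    meta: Mapping,
    patient: Mapping,
    exposure: np.ndarray,
    columns: Sequence[str],
) -> pd.DataFrame:
    """Design rows for one (reference) patient over a grid of exposure values.

    Reuses the winsorization caps and spline knots recorded in a fitted
    matrix's ``meta`` so that predictions live in the fitted
    parameterization.  ``columns`` fixes the output column order (the fitted
    design's columns).
    """
    exposure = np.atleast_1d(np.asarray(exposure, dtype=float))
    n = exposure.size
    name = meta["definition"]["name"]
    kind = meta["definition"]["kind"]
    out = {}

    def spline_cols(var: str, values: np.ndarray) -> None:
        spec = meta["splines"][var]
        if spec["linear_fallback"]:
            out[f"{var}_lin"] = values
            return
        basis, _, _ = natural_spline_basis(values, spec["df"], knots=spec["knots"])
        for i in range(basis.shape[1]):
            out[f"{var}_ns{i + 1}"] = basis[:, i]

    capped = np.minimum(exposure, meta["winsor_caps"][name])
    spline_cols(name, capped)
    if kind in ("abs_time_below", "rel_time_below"):
        out[f"{name}_is_zero"] = (exposure == 0).astype(float)

    if not meta["settings"].get("univariable", False):
        out["sex_female"] = np.full(n, float(patient["sex"] == "female"))
        for s in SPECIALTIES:
            if s == meta["reference"]["specialty"]:
                continue
            key = "specialty_" + s.split(",")[0].split()[0].lower()
            out[key] = np.full(n, float(patient["specialty"] == s))
        for a in (1, 3, 4):
            out[f"asa_{a}"] = np.full(n, float(patient["asa"] == a))
        spline_cols("age", np.full(n, float(patient["age"])))
        bmi = min(float(patient["bmi"]), meta["winsor_caps"]["bmi"])
        spline_cols("bmi", np.full(n, bmi))
        dur = min(float(patient["duration_surgery"]), meta["winsor_caps"]["duration_surgery"])
        spline_cols("duration", np.full(n, dur))
        spline_cols("time_to_surgery", np.full(n, float(patient["time_to_surgery"])))
        spline_cols("comorbidity", np.full(n, float(patient["comorbidity_score"])))
    out["intercept"] = np.ones(n)

    frame = pd.DataFrame(out)
    return frame.reindex(columns=list(columns), fill_value=0.0)
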