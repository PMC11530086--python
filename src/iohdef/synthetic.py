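"""Synthetic perioperative cohorts with known ground truth.

No public dataset carries intraoperative blood-pressure series together
with 30-day mortality and length-of-stay outcomes, so every downstream
stage of this package is exercised on simulated cohorts whose generative
parameters are known exactly:

* raw blood-pressure records in the two historical recording dialects
  (one sample every two minutes vs. every 15 seconds), built from a
  per-patient constant baseline, bounded AR(1) noise, and rectangular
  hypotensive episodes of configurable depth and duration;
* artifact contamination targeting each of the six cleaning rules, with a
  hidden truth channel recording which samples were corrupted and by which
  rule, so cleaning sensitivity is measurable;
* covariates loosely matched to a general non-cardiothoracic surgical
  population (median age ~53, BMI ~26, mostly ASA 1-2);
* outcomes generated from logistic (30-day mortality) and log-normal
  (hospital and PACU length of stay) models whose hypotension effect is
  routed through one chosen "true" definition, standardized across the
  cohort.

The artifact-free series are constructed to pass all six cleaning rules
(noise is clipped, channel margins enforced, and episode depth rescaled
when a record would trip the 3-SD rule), so with ``artifact_rate=0`` the
cleaning stage removes nothing and the recorded truth exposures equal the
pipeline's recomputation.

Randomness: one master seed; each patient draws from an independent
substream keyed by patient index, so enlarging the cohort does not
reshuffle earlier patients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import SPECIALTIES
from .metrics import IOHDefinition, compute_definition
from .signal import GRID_STEP_S, MAPGrid

_SPECIALTY_P = np.array([0.367, 0.144, 0.264, 0.055, 0.152, 0.019])
_SPECIALTY_P = _SPECIALTY_P / _SPECIALTY_P.sum()
_ASA_P = np.array([0.297, 0.455, 0.228, 0.020])
_ASA_P = _ASA_P / _ASA_P.sum()

#: AR(1) autocorrelation of the MAP noise at 15-s lag.
_AR_PHI_15S = 0.9
#: marginal SD (mmHg) of the MAP noise; clipped at 2.6 SD to keep clean
#: records inside the 3-SD artifact rule.
_MAP_NOISE_SD = 4.0
_NOISE_CLIP = 2.6
#: uniform half-width of the SBP/DBP measurement noise (mmHg)
_MEAS_NOISE = 1.5


def _default_covariate_effects() -> dict:
    """Per-outcome linear effects on standardized covariates (log-odds /
    log-days / log-hours per SD; sex coded female=1)."""
    return {
        "mortality": {"sex": -0.2, "age": 0.9, "bmi": -0.2, "duration": 0.3,
                      "time_to_surgery": 0.3, "asa": 0.8, "comorbidity": 0.5},
        "hlos": {"sex": 0.0, "age": 0.10, "bmi": 0.0, "duration": 0.35,
                 "time_to_surgery": 0.10, "asa": 0.15, "comorbidity": 0.10},
        "pacu": {"sex": 0.0, "age": 0.05, "bmi": 0.0, "duration": 0.30,
                 "time_to_surgery": 0.0, "asa": 0.05, "comorbidity": 0.0},
    }


@dataclass
class TruthConfig:
    """All parameters of the generative model.

    Fractions live in [0, 1]; rates are per hour; betas are per standard
    deviation of the chosen true definition's cohort distribution.  The
    mortality intercept default is calibrated (lognormal moment
    approximation) so that the default effect sizes yield roughly the 0.9%
    30-day mortality typical of a general surgical cohort.
    """

    n_patients: int = 1000
    dialect_fraction_2min: float = 0.4
    artifact_rate: float = 0.02
    baseline_map_mean: float = 85.0
    baseline_map_sd: float = 8.0
    episode_rate: float = 1.5  # expected hypotensive episodes per hour
    episode_depth_range: tuple[float, float] = (10.0, 35.0)  # mmHg
    episode_duration_range: tuple[float, float] = (1.0, 15.0)  # minutes
    true_definition: IOHDefinition = field(
        default_factory=lambda: IOHDefinition("rel_time_below", 80)
    )
    beta_mortality: float = 0.45
    beta_hlos: float = 0.06
    beta_pacu: float = 0.06
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    mortality_intercept: float = -5.75
    hlos_log_mean: float = float(np.log(5.1))  # days
    hlos_log_sd: float = 0.65
    pacu_log_mean: float = float(np.log(2.1))  # hours
    pacu_log_sd: float = 0.35
    icu_admission_prob: float = 0.10
    death_before_discharge_prob: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("invalid config field n_patients: must be >= 1")
        for name in ("dialect_fraction_2min", "artifact_rate", "icu_admission_prob",
                     "death_before_discharge_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"invalid config field {name}: must lie in [0, 1]")
        if self.episode_duration_range[0] <= 0 or (
            self.episode_duration_range[1] < self.episode_duration_range[0]
        ):
            raise ValueError("invalid config field episode_duration_range: must be positive")
        if self.episode_depth_range[1] < self.episode_depth_range[0]:
            raise ValueError("invalid config field episode_depth_range: must be ordered")
        if self.episode_rate < 0:
            raise ValueError("invalid config field episode_rate: must be >= 0")
        if self.baseline_map_sd < 0:
            raise ValueError("invalid config field baseline_map_sd: must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_definition"] = {"kind": self.true_definition.kind,
                                "parameter": self.true_definition.parameter}
        d["episode_depth_range"] = list(self.episode_depth_range)
        d["episode_duration_range"] = list(self.episode_duration_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthConfig":
        d = dict(d)
        d["true_definition"] = IOHDefinition(**d["true_definition"])
        d["episode_depth_range"] = tuple(d["episode_depth_range"])
        d["episode_duration_range"] = tuple(d["episode_duration_range"])
        return cls(**d)


@dataclass
class CohortDataset:
    """A generated cohort: raw vitals, covariates, outcomes, and the truth."""

    config: TruthConfig
    vitals: pd.DataFrame  # patient_id, timestamp_s, sbp, dbp, map, true_artifact_rule
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame  # true exposures, z-scores, linear predictors

    @property
    def cohort_table(self) -> pd.DataFrame:
        return self.covariates.merge(self.outcomes, on="patient_id")

    def public_vitals(self) -> pd.DataFrame:
        return self.vitals[["patient_id", "timestamp_s", "sbp", "dbp", "map"]]


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(index,))))


def _ar1_noise(rng: np.random.Generator, n: int, interval_s: float) -> np.ndarray:
    phi = _AR_PHI_15S ** (interval_s / GRID_STEP_S)
    innov_sd = _MAP_NOISE_SD * np.sqrt(1 - phi**2)
    e = rng.normal(0.0, innov_sd, n)
    x0 = rng.normal(0.0, _MAP_NOISE_SD)
    noise = lfilter([1.0], [1.0, -phi], e, zi=np.array([phi * x0]))[0]
    return np.clip(noise, -_NOISE_CLIP * _MAP_NOISE_SD, _NOISE_CLIP * _MAP_NOISE_SD)


def _rule6_ok(*channels: np.ndarray) -> bool:
    for x in channels:
        dev = x - x.mean()
        sd = np.sqrt(dev @ dev / dev.size)
        if sd > 0 and np.abs(dev).max() > 2.98 * sd:
            return False
    return True


def generate_bp_series(
    patient_id: object,
    duration_min: float,
    dialect: str,
    rng: np.random.Generator,
    config: TruthConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One patient's raw BP record plus the true MAP on the 15-s grid.

    Returns ``(frame, clean_map_grid)``: the recording-dialect frame with
    the hidden ``true_artifact_rule`` column, and the artifact-free MAP
    interpolated to the homogeneous grid (the basis of the truth exposure).
    """
    cols, grid = _generate_bp_arrays(duration_min, dialect, rng, config)
    frame = pd.DataFrame({"patient_id": patient_id, **cols})
    return frame, grid


def _generate_bp_arrays(
    duration_min: float,
    dialect: str,
    rng: np.random.Generator,
    config: TruthConfig,
) -> tuple[dict, np.ndarray]:
    if duration_min <= 0:
        raise ValueError("duration_surgery must be positive")
    if dialect not in ("2min", "15s"):
        raise ValueError(f"unknown recording dialect: {dialect!r}")
    interval = 120.0 if dialect == "2min" else 15.0
    n = int(np.floor(duration_min * 60.0 / interval)) + 1
    t = interval * np.arange(n)

    baseline = float(np.clip(rng.normal(config.baseline_map_mean, config.baseline_map_sd),
                             65.0, 110.0))
    noise = _ar1_noise(rng, n, interval)
    pp = float(np.clip(rng.normal(45.0, 8.0), 25.0, 70.0))

    depth_profile = np.zeros(n)
    n_ep = rng.poisson(config.episode_rate * duration_min / 60.0)
    for _ in range(n_ep):
        depth = rng.uniform(*config.episode_depth_range)
        dur_s = 60.0 * min(rng.uniform(*config.episode_duration_range), duration_min)
        start = rng.uniform(0.0, max(duration_min * 60.0 - dur_s, 0.0))
        depth_profile[(t >= start) & (t < start + dur_s)] += depth

    e_s = rng.uniform(-_MEAS_NOISE, _MEAS_NOISE, n)
    e_d = rng.uniform(-_MEAS_NOISE, _MEAS_NOISE, n)
    floor = pp / 3.0 + 12.0

    # scale episode depth down until the clean record passes the 3-SD rule
    # (short deep episodes are exactly what that rule flags), then clamp any
    # residual noise-wander outliers toward the per-channel mean
    scale = 1.0
    for _ in range(40):
        map_clean = np.maximum(baseline + noise - scale * depth_profile, floor)
        if _rule6_ok(map_clean):
            break
        scale *= 0.85
    sbp = map_clean + 2.0 * pp / 3.0 + e_s
    dbp = map_clean - pp / 3.0 + e_d
    for _ in range(60):
        if _rule6_ok(sbp, dbp, map_clean):
            break
        for x in (sbp, dbp, map_clean):
            sd = x.std()
            if sd > 0:
                np.clip(x, x.mean() - 2.9 * sd, x.mean() + 2.9 * sd, out=x)

    # inject artifacts on recording copies; truth channel notes the rule
    sbp_rec, dbp_rec, map_rec = sbp.copy(), dbp.copy(), map_clean.copy()
    rule = np.zeros(n, dtype=np.int8)
    hit = rng.random(n) < config.artifact_rate
    which = rng.integers(1, 7, size=n)
    for i in np.nonzero(hit)[0]:
        r = int(which[i])
        rule[i] = r
        if r == 1:
            sbp_rec[i] = rng.uniform(300.0, 340.0)
        elif r == 2:
            sbp_rec[i] = rng.uniform(1.0, 20.0)
        elif r == 3:
            dbp_rec[i] = rng.uniform(0.1, 5.0)
        elif r == 4:
            dbp_rec[i] = rng.uniform(225.0, 280.0)
        elif r == 5:
            sbp_rec[i] = dbp_rec[i] + rng.uniform(0.0, 5.0)
        else:  # a positive spike on every channel, well past 3 SD
            off = rng.uniform(60.0, 90.0)
            sbp_rec[i] += off
            dbp_rec[i] += off
        if r != 6:
            map_rec[i] = (sbp_rec[i] + 2.0 * dbp_rec[i]) / 3.0
        else:
            map_rec[i] += off

    if n >= 2:
        n_ticks = int(np.floor((t[-1] - t[0]) / GRID_STEP_S)) + 1
        grid = np.interp(t[0] + GRID_STEP_S * np.arange(n_ticks), t, map_clean)
    else:
        grid = map_clean.copy()
    cols = {"timestamp_s": t, "sbp": sbp_rec, "dbp": dbp_rec, "map": map_rec,
            "true_artifact_rule": rule}
    return cols, grid


def _draw_covariates(rng: np.random.Generator) -> dict:
    comorbidity = 0 if rng.random() < 0.55 else int(rng.poisson(1.2)) + 1
    return {
        "sex": "female" if rng.random() < 0.566 else "male",
        "age": float(np.clip(rng.normal(52.0, 19.0), 18.0, 95.0)),
        "bmi": float(np.clip(rng.lognormal(np.log(25.7), 0.20), 15.0, 55.0)),
        "duration_surgery": float(np.clip(rng.lognormal(np.log(100.0), 0.55), 15.0, 480.0)),
        "time_to_surgery": float(np.clip(rng.lognormal(0.0, 0.35), 0.05, 30.0)),
        "specialty": SPECIALTIES[int(rng.choice(len(SPECIALTIES), p=_SPECIALTY_P))],
        "asa": int(rng.choice([1, 2, 3, 4], p=_ASA_P)),
        "comorbidity_score": float(comorbidity),
    }


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(config: TruthConfig) -> CohortDataset:
    """Generate a full cohort under the configured truth.

    Deterministic given the config (identical seed, identical output); the
    truth frame records each patient's true exposure, its cohort z-score,
    and the linear predictors feeding every outcome.
    """
    config.validate()
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))

    chunks: dict[str, list[np.ndarray]] = {
        "patient_id": [], "timestamp_s": [], "sbp": [], "dbp": [], "map": [],
        "true_artifact_rule": [],
    }
    cov_rows = []
    draws = np.empty((config.n_patients, 5))
    exposures = np.empty(config.n_patients)
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        cov = _draw_covariates(rng)
        dialect = "2min" if rng.random() < config.dialect_fraction_2min else "15s"
        cols, clean_grid = _generate_bp_arrays(
            cov["duration_surgery"], dialect, rng, config
        )
        truth_grid = MAPGrid(
            i, 0.0, clean_grid, (len(clean_grid) - 1) * GRID_STEP_S / 60.0
        )
        exposures[i] = compute_definition(truth_grid, config.true_definition)
        # outcome randomness drawn per patient, independent of cohort size
        draws[i] = [rng.random(), rng.standard_normal(), rng.standard_normal(),
                    rng.random(), rng.random()]
        cov["patient_id"] = i
        cov["dialect"] = dialect
        cov_rows.append(cov)
        chunks["patient_id"].append(np.full(cols["timestamp_s"].size, i, dtype=np.int64))
        for key in ("timestamp_s", "sbp", "dbp", "map", "true_artifact_rule"):
            chunks[key].append(cols[key])

    covariates = pd.DataFrame(cov_rows)
    covariates = covariates[
        ["patient_id", "sex", "age", "bmi", "duration_surgery", "time_to_surgery",
         "specialty", "asa", "comorbidity_score", "dialect"]
    ]
    vitals = pd.DataFrame({k: np.concatenate(v) for k, v in chunks.items()})

    z_exp = _zscore(exposures)
    zcov = {
        "sex": (covariates["sex"] == "female").to_numpy(float),
        "age": _zscore(covariates["age"].to_numpy(float)),
        "bmi": _zscore(covariates["bmi"].to_numpy(float)),
        "duration": _zscore(np.log(covariates["duration_surgery"].to_numpy(float))),
        "time_to_surgery": _zscore(np.log(covariates["time_to_surgery"].to_numpy(float))),
        "asa": _zscore(covariates["asa"].to_numpy(float)),
        "comorbidity": _zscore(covariates["comorbidity_score"].to_numpy(float)),
    }

    def lp(outcome: str) -> np.ndarray:
        eff = config.covariate_effects.get(outcome, {})
        total = np.zeros(config.n_patients)
        for key, coef in eff.items():
            total += coef * zcov[key]
        return total

    lp_mort = config.mortality_intercept + config.beta_mortality * z_exp + lp("mortality")
    p_mort = expit(lp_mort)
    died_30d = draws[:, 0] < p_mort
    lp_hlos = config.hlos_log_mean + config.beta_hlos * z_exp + lp("hlos")
    hlos = np.maximum(np.exp(lp_hlos + config.hlos_log_sd * draws[:, 1]), 0.1)
    lp_pacu = config.pacu_log_mean + config.beta_pacu * z_exp + lp("pacu")
    pacu = np.maximum(np.exp(lp_pacu + config.pacu_log_sd * draws[:, 2]), 0.1)
    icu_direct = draws[:, 3] < config.icu_admission_prob
    died_before_discharge = died_30d & (draws[:, 4] < config.death_before_discharge_prob)
    pacu = np.where(icu_direct, np.nan, pacu)

    outcomes = pd.DataFrame(
        {
            "patient_id": covariates["patient_id"],
            "died_30d": died_30d.astype(int),
            "hlos": hlos,
            "pacu_los": pacu,
            "icu_direct": icu_direct.astype(int),
            "died_before_discharge": died_before_discharge.astype(int),
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": covariates["patient_id"],
            "true_exposure": exposures,
            "exposure_z": z_exp,
            "lp_mortality": lp_mort,
            "p_mortality": p_mort,
            "lp_hlos": lp_hlos,
            "lp_pacu": lp_pacu,
        }
    )
    truth.attrs["exposure_center"] = float(exposures.mean())
    truth.attrs["exposure_scale"] = float(exposures.std()) if exposures.std() > 0 else 1.0
    return CohortDataset(config, vitals, covariates, outcomes, truth)


def export_truth(dataset: CohortDataset, path=None) -> dict:
    """Truth table + generative parameters, JSON-serializable.

    Betas and every other config field round-trip exactly, enabling
    parameter-recovery tests against a reloaded record.
    """
    payload = {
        "config": dataset.config.to_dict(),
        "exposure_center": dataset.truth.attrs["exposure_center"],
        "exposure_scale": dataset.truth.attrs["exposure_scale"],
        "per_patient": dataset.truth.to_dict(orient="records"),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    return payload


def import_truth(path) -> tuple[TruthConfig, pd.DataFrame, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    config = TruthConfig.from_dict(payload["config"])
    truth = pd.DataFrame(payload["per_patient"])
    scales = {"exposure_center": payload["exposure_center"],
              "exposure_scale": payload["exposure_scale"]}
    return config, truth, scales


def write_cohort(dataset: CohortDataset, outdir) -> dict:
    """Write the public CSVs (vitals, covariates, outcomes) plus truth JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vitals": outdir / "vitals.csv",
        "covariates": outdir / "covariates.csv",
        "outcomes": outdir / "outcomes.csv",
        "truth": outdir / "truth.json",
    }
    dataset.public_vitals().to_csv(paths["vitals"], index=False)
    dataset.covariates.to_csv(paths["covariates"], index=False)
    dataset.outcomes.to_csv(paths["outcomes"], index=False)
    export_truth(dataset, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
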