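"""The estimation stage: independent effect estimation for the chosen definition.

After the shaping half has picked a best-fitting hypotension definition per
outcome, its multivariable model is refit on the held-out estimation half
(with the same degrees of freedom, winsorization rule and trim fraction,
re-parameterized on that half's data).  From the refit come:

* adjusted effect curves over the exposure range for a fixed reference
  patient, on the probability scale for mortality and back-transformed to
  days/hours for the stay outcomes, with delta-method pointwise 95% CIs;
* effect sizes at clinically relevant exposure values (MAP 50/65/75 mmHg
  for the episode definitions, 5 and 10 minutes or 5% and 10% of anesthesia
  time for the time-below definitions) expressed as odds ratios or LOS
  ratios against a reference exposure;
* a leave-one-group-out contribution table: the increase in cross-validated
  Brier score or MSE when each variable group is dropped from the model;
* sensitivity reruns of the shaping stage (alternative trim fractions,
  4-df exposure spline).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from . import models
from .design import ModelMatrix, ModelSettings, build_model_matrix, rows_for_patient
from .metrics import IOHDefinition
from .selection import SelectionResult, cross_validate_matrix, select_best

Z95 = float(stats.norm.ppf(0.975))

#: Clinically relevant evaluation points per definition kind.
EVALUATION_POINTS = {
    "sustained_min_map": (50.0, 65.0, 75.0),  # mmHg
    "cumulative_min_map": (50.0, 65.0, 75.0),  # mmHg
    "abs_time_below": (5.0, 10.0),  # minutes
    "rel_time_below": (0.05, 0.10),  # fraction of anesthesia time
}

#: Reference exposure contrasts are measured against: the highest listed
#: "clinically relevant" MAP for the episode kinds, zero time below the
#: threshold (indicator on) for the time-below kinds.
REFERENCE_EXPOSURE = {
    "sustained_min_map": 75.0,
    "cumulative_min_map": 75.0,
    "abs_time_below": 0.0,
    "rel_time_below": 0.0,
}


@dataclass(frozen=True)
class ReferencePatient:
    """The 'average patient' all adjusted curves are drawn for."""

    sex: str = "male"
    age: float = 53.0
    bmi: float = 26.0
    duration_surgery: float = 102.0  # minutes (~1.7 h)
    time_to_surgery: float = 1.0  # days
    specialty: str = "Urology, gynecology, general surgery"
    asa: int = 2
    comorbidity_score: float = 0.0

    def as_dict(self) -> dict:
        return {
            "sex": self.sex,
            "age": self.age,
            "bmi": self.bmi,
            "duration_surgery": self.duration_surgery,
            "time_to_surgery": self.time_to_surgery,
            "specialty": self.specialty,
            "asa": self.asa,
            "comorbidity_score": self.comorbidity_score,
        }


@dataclass
class EffectEstimate:
    """A contrast between two exposure values on the outcome's ratio scale."""

    definition: str
    outcome: str
    point: float
    reference: float
    contrast: float  # odds ratio (mortality) or LOS ratio (metric outcomes)
    ci_low: float
    ci_high: float
    log_contrast: float
    se_log: float
    extrapolated: bool = False


def fit_best(
    estimation_half: pd.DataFrame,
    selection: SelectionResult,
    registry: list[IOHDefinition],
    settings: ModelSettings | None = None,
    shaping_ids: np.ndarray | None = None,
) -> tuple[models.FittedModel, ModelMatrix]:
    """Refit the selected definition's model on the estimation half.

    ``shaping_ids``, when given, guards the split: any overlap with the
    estimation half raises a 'split leakage' error.
    """
    if shaping_ids is not None:
        overlap = set(np.asarray(shaping_ids).tolist()) & set(
            estimation_half["patient_id"].tolist()
        )
        if overlap:
            raise ValueError(f"split leakage: {len(overlap)} patients in both halves")
    by_name = {d.name: d for d in registry}
    if selection.best not in by_name:
        raise ValueError(f"selected definition {selection.best!r} not in registry")
    definition = by_name[selection.best]
    if definition.name not in estimation_half.columns:
        raise ValueError(f"definition {definition.name!r} missing from estimation features")
    mm = build_model_matrix(estimation_half, definition, selection.outcome, settings)
    return models.fit_model(mm), mm


def effect_curve(
    fit: models.FittedModel,
    ref: ReferencePatient,
    exposure_grid: np.ndarray,
) -> pd.DataFrame:
    """Adjusted outcome curve over the exposure grid for the reference patient.

    Mortality curves are on the probability scale; LOS curves are
    back-transformed (exp of the log-scale prediction) to the original
    days/hours scale.  CIs are delta-method on the linear predictor, then
    transformed, so the point estimate always lies inside its own interval.
    Grid values beyond the winsorization cap are clipped with a flag.
    """
    grid = np.asarray(exposure_grid, dtype=float)
    cap = fit.meta["winsor_caps"][fit.meta["definition"]["name"]]
    clipped = grid > cap
    X = rows_for_patient(fit.meta, ref.as_dict(), grid, fit.params.index)
    Xa = X.to_numpy(float)
    eta = Xa @ fit.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xa, fit.cov.to_numpy(), Xa))
    lo, hi = eta - Z95 * se, eta + Z95 * se
    trans = special.expit if fit.link == "logit" else np.exp
    return pd.DataFrame(
        {
            "exposure": grid,
            "fit": trans(eta),
            "lo": trans(lo),
            "hi": trans(hi),
            "eta": eta,
            "se_eta": se,
            "clipped": clipped,
        }
    )


def effect_at_points(
    fit: models.FittedModel,
    ref: ReferencePatient,
    points: tuple[float, ...] | None = None,
    reference_exposure: float | None = None,
) -> list[EffectEstimate]:
    """Contrasts at the clinically relevant exposure values.

    Each contrast compares the evaluation point against the kind's
    reference exposure; because the adjustment covariates cancel, it
    reduces to a linear contrast over the exposure block with a
    delta-method CI.  Odds ratios for mortality, stay ratios for the
    metric outcomes; 1.0 exactly at the reference point.
    """
    kind = fit.meta["definition"]["kind"]
    name = fit.meta["definition"]["name"]
    if points is None:
        points = EVALUATION_POINTS[kind]
    if reference_exposure is None:
        reference_exposure = REFERENCE_EXPOSURE[kind]
    cap = fit.meta["winsor_caps"][name]
    rows = rows_for_patient(
        fit.meta, ref.as_dict(), np.r_[np.asarray(points, float), reference_exposure],
        fit.params.index,
    )
    Xa = rows.to_numpy(float)
    ref_row = Xa[-1]
    out = []
    beta = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    for i, pt in enumerate(points):
        c = Xa[i] - ref_row
        log_contrast = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        out.append(
            EffectEstimate(
                definition=name,
                outcome=fit.outcome,
                point=float(pt),
                reference=float(reference_exposure),
                contrast=float(np.exp(log_contrast)),
                ci_low=float(np.exp(log_contrast - Z95 * se)),
                ci_high=float(np.exp(log_contrast + Z95 * se)),
                log_contrast=log_contrast,
                se_log=se,
                extrapolated=bool(pt > cap),
            )
        )
    return out


@dataclass
class ContributionTable:
    """Leave-one-group-out increase in the cross-validated score."""

    outcome: str
    definition: str
    full_score: float
    rows: pd.DataFrame  # columns: group, score_without, delta

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "definition": self.definition,
            "full_score": self.full_score,
            "rows": self.rows.to_dict(orient="records"),
        }


def variable_contribution(
    mm: ModelMatrix, k: int = 10, reps: int = 40, seed: int = 0
) -> ContributionTable:
    """Score increase when each variable group is removed from the full model.

    All refits share the fold partitions (same seed) so the deltas are not
    confounded by partition noise.  The IOH block counts as one group, as
    does each adjustment variable.
    """
    full = cross_validate_matrix(mm, k=k, reps=reps, seed=seed)
    rows = []
    for group in mm.groups:
        if group == "intercept":
            continue
        reduced = ModelMatrix(
            outcome=mm.outcome,
            y=mm.y,
            X=mm.X[mm.columns_without(group)],
            groups={g: c for g, c in mm.groups.items() if g != group},
            patient_ids=mm.patient_ids,
            meta=mm.meta,
            exclusions=mm.exclusions,
        )
        score = cross_validate_matrix(reduced, k=k, reps=reps, seed=seed)
        rows.append(
            {"group": group, "score_without": score.mean, "delta": score.mean - full.mean}
        )
    table = pd.DataFrame(rows).sort_values("delta", ascending=False).reset_index(drop=True)
    return ContributionTable(
        outcome=mm.outcome,
        definition=mm.meta["definition"]["name"],
        full_score=full.mean,
        rows=table,
    )


def sensitivity_analysis(
    cohort_half: pd.DataFrame,
    registry: list[IOHDefinition],
    outcome: str,
    variants: list[dict],
    k: int = 10,
    reps: int = 40,
    seed: int = 0,
    settings: ModelSettings | None = None,
) -> dict[str, dict]:
    """Rerun the shaping stage under alternative analysis settings.

    Known variant keys: ``trim_fraction`` in {0.015, 0.02} and ``ioh_df`` = 4.
    Returns, per variant, the new ranking and how the baseline top
    definitions moved.
    """
    base_settings = settings or ModelSettings()
    baseline = select_best(
        cohort_half, registry, outcome, k=k, reps=reps, seed=seed, settings=base_settings
    )
    base_order = [s.definition for s in baseline.ranking]
    out: dict[str, dict] = {
        "baseline": {"ranking": base_order, "best": baseline.best}
    }
    for variant in variants:
        unknown = set(variant) - {"trim_fraction", "ioh_df"}
        if unknown:
            raise ValueError(f"unknown sensitivity variant keys: {sorted(unknown)}")
        vsettings = replace(base_settings, **variant)
        res = select_best(
            cohort_half, registry, outcome, k=k, reps=reps, seed=seed, settings=vsettings
        )
        order = [s.definition for s in res.ranking]
        label = ",".join(f"{kk}={vv}" for kk, vv in sorted(variant.items()))
        out[label] = {
            "ranking": order,
            "best": res.best,
            "rank_changes": {
                d: {"baseline": base_order.index(d), "variant": order.index(d)}
                for d in base_order[:3]
                if d in order
            },
        }
    return out
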