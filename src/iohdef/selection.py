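"""The shaping stage: cross-validated comparison of IOH definitions.

The cohort is randomly halved into a *shaping* dataset — used to pick the
best-fitting hypotension definition for each outcome — and an *estimation*
dataset held out for independent effect estimation.  On the shaping half,
every candidate definition's multivariable model is scored by 10-fold
cross-validation with 40 repetitions (Brier score for mortality, MSE on the
log scale for the stay outcomes) and ranked by the mean cross-validated
score.  Selection uncertainty is summarized by a 0.95 confidence set of
models built from Akaike weights of single full-half fits: sort weights in
decreasing order and accumulate until the cumulative weight first exceeds
0.95, including the model that crosses the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from sklearn.model_selection import KFold, StratifiedKFold

from . import models
from .design import ModelMatrix, ModelSettings, build_model_matrix
from .metrics import IOHDefinition


@dataclass
class SplitAssignment:
    """Disjoint, exhaustive allocation of patients to the two halves."""

    shaping_ids: np.ndarray
    estimation_ids: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        s, e = set(self.shaping_ids.tolist()), set(self.estimation_ids.tolist())
        if s & e:
            raise ValueError("split leakage: halves overlap")
        if abs(len(s) - len(e)) > 1:
            raise ValueError("halves differ in size by more than 1")


def split_cohort(patient_ids: np.ndarray | pd.Series, seed: int) -> SplitAssignment:
    """Random equal split of patients (sizes differ by at most one)."""
    ids = np.asarray(patient_ids)
    if ids.size < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n_shaping = (ids.size + 1) // 2
    return SplitAssignment(
        shaping_ids=np.sort(perm[:n_shaping]),
        estimation_ids=np.sort(perm[n_shaping:]),
        seed=seed,
    )


@dataclass
class CVScore:
    """Cross-validated score of one definition's model for one outcome."""

    definition: str
    outcome: str
    mean: float
    per_rep: list[float]
    k: int
    reps: int
    seed: int
    n: int
    n_params: int
    skipped_folds: int = 0
    separation: bool = False


def _fold_splitter(y: np.ndarray, outcome: str, k: int, rng_seed: int, stratified: bool):
    if outcome == "mortality" and stratified:
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed).split(
            np.zeros_like(y), y
        )
    return KFold(n_splits=k, shuffle=True, random_state=rng_seed).split(np.zeros_like(y))


def cross_validate_matrix(
    mm: ModelMatrix, k: int = 10, reps: int = 40, seed: int = 0, stratified: bool = True
) -> CVScore:
    """Repeated k-fold CV of one prepared model matrix.

    Each repetition draws a fresh random partition (stratified by outcome
    for the binary model), fits on k-1 folds with the parameterization
    already frozen in the matrix, and pools held-out predictions; the score
    is the mean over repetitions of the pooled Brier score or MSE.  Folds
    whose training part has no outcome variation are skipped and counted.
    """
    X_full, names, _ = models._drop_aliased(mm.X.to_numpy(float), list(mm.X.columns))
    y = mm.y
    logistic = mm.outcome == "mortality"
    per_rep: list[float] = []
    skipped = 0
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(reps) % (2**31 - 1)
    for r in range(reps):
        preds = np.full(y.size, np.nan)
        for train, test in _fold_splitter(y, mm.outcome, k, int(fold_seeds[r]), stratified):
            if logistic and (y[train].sum() == 0 or y[train].sum() == train.size):
                skipped += 1
                continue
            Xtr, ytr = X_full[train], y[train]
            if logistic:
                beta, _ = models.fit_logistic(Xtr, ytr)
                preds[test] = special.expit(X_full[test] @ beta)
            else:
                beta = models.fit_ols(Xtr, ytr)
                preds[test] = X_full[test] @ beta
        have = ~np.isnan(preds)
        score = (
            models.brier_score(preds[have], y[have])
            if logistic
            else models.mse(preds[have], y[have])
        )
        per_rep.append(score)
    return CVScore(
        definition=mm.meta["definition"]["name"],
        outcome=mm.outcome,
        mean=float(np.mean(per_rep)),
        per_rep=per_rep,
        k=k,
        reps=reps,
        seed=seed,
        n=mm.n,
        n_params=len(names),
        skipped_folds=skipped,
    )


def cross_validate(
    cohort_half: pd.DataFrame,
    definition: IOHDefinition,
    outcome: str,
    k: int = 10,
    reps: int = 40,
    seed: int = 0,
    settings: ModelSettings | None = None,
    stratified: bool = True,
) -> CVScore:
    """Build the definition's model matrix on the half, then repeated CV.

    Winsorization caps, knots and the trimmed outcome are computed once on
    the full half before cross-validation.
    """
    mm = build_model_matrix(cohort_half, definition, outcome, settings)
    return cross_validate_matrix(mm, k=k, reps=reps, seed=seed, stratified=stratified)


@dataclass
class SelectionResult:
    """Ranked definitions, the best one, and the Akaike confidence set."""

    outcome: str
    ranking: list[CVScore]
    best: str
    akaike_weights: dict[str, float]
    confidence_set: list[str]
    aics: dict[str, float]
    excluded: dict[str, str] = field(default_factory=dict)
    hl_pvalues: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "best": self.best,
            "ranking": [
                {"definition": s.definition, "score": s.mean, "n_params": s.n_params}
                for s in self.ranking
            ],
            "akaike_weights": self.akaike_weights,
            "confidence_set": self.confidence_set,
            "aics": self.aics,
            "excluded": self.excluded,
            "hl_pvalues": self.hl_pvalues,
            "cv": {
                "k": self.ranking[0].k if self.ranking else None,
                "reps": self.ranking[0].reps if self.ranking else None,
                "seed": self.ranking[0].seed if self.ranking else None,
            },
        }


def rank_definitions(
    scores: list[CVScore], registry: list[IOHDefinition] | None = None
) -> list[CVScore]:
    """Ascending by mean score; ties by fewer parameters, then registry order."""
    outcomes = {s.outcome for s in scores}
    if len(outcomes) > 1:
        raise ValueError(f"cannot rank across outcomes: {sorted(outcomes)}")
    schemes = {(s.k, s.reps, s.seed) for s in scores}
    if len(schemes) > 1:
        raise ValueError("cannot rank scores from different fold schemes")
    if registry is not None:
        order = {d.name: i for i, d in enumerate(registry)}
    else:
        order = {s.definition: i for i, s in enumerate(scores)}
    return sorted(scores, key=lambda s: (s.mean, s.n_params, order.get(s.definition, 1e9)))


def akaike_weights(aics: dict[str, float]) -> dict[str, float]:
    finite = {k: v for k, v in aics.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("no finite AIC values")
    if len(finite) < len(aics):
        warnings.warn("models with non-finite AIC excluded from the confidence set")
    amin = min(finite.values())
    raw = {k: np.exp(-(v - amin) / 2.0) for k, v in finite.items()}
    total = sum(raw.values())
    return {k: float(v / total) for k, v in raw.items()}


def akaike_confidence_set(
    aics: dict[str, float], level: float = 0.95
) -> tuple[list[str], dict[str, float]]:
    """Models accumulated by decreasing Akaike weight until the level is crossed.

    The model whose weight pushes the cumulative sum past the level is
    included; the set therefore always contains the maximum-weight model.
    """
    weights = akaike_weights(aics)
    ordered = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    members: list[str] = []
    cum = 0.0
    for name, w in ordered:
        members.append(name)
        cum += w
        if cum > level:
            break
    return members, weights


def select_best(
    cohort_half: pd.DataFrame,
    registry: list[IOHDefinition],
    outcome: str,
    k: int = 10,
    reps: int = 40,
    seed: int = 0,
    settings: ModelSettings | None = None,
    level: float = 0.95,
) -> SelectionResult:
    """Full shaping stage for one outcome.

    Cross-validates every registry definition, ranks by mean score, and
    derives the Akaike confidence set from single fits on the whole half.
    Fits with flagged quasi-separation are excluded from the ranking with a
    reason; Hosmer-Lemeshow p-values are recorded for the mortality models.
    """
    scores: list[CVScore] = []
    aics: dict[str, float] = {}
    excluded: dict[str, str] = {}
    hl: dict[str, float] = {}
    for definition in registry:
        mm = build_model_matrix(cohort_half, definition, outcome, settings)
        fit = models.fit_model(mm)
        if fit.separation_flag:
            excluded[definition.name] = "quasi-complete separation"
            continue
        aics[definition.name] = fit.aic
        if outcome == "mortality":
            _, pval = hosmer_lemeshow_safe(fit, mm)
            hl[definition.name] = pval
        scores.append(cross_validate_matrix(mm, k=k, reps=reps, seed=seed))
    if not scores:
        raise ValueError(
            "all candidate models excluded (quasi-separation); "
            "too few events for this outcome at this cohort size"
        )
    ranking = rank_definitions(scores, registry)
    members, weights = akaike_confidence_set(aics, level=level)
    return SelectionResult(
        outcome=outcome,
        ranking=ranking,
        best=ranking[0].definition,
        akaike_weights=weights,
        confidence_set=members,
        aics=aics,
        excluded=excluded,
        hl_pvalues=hl,
    )


def hosmer_lemeshow_safe(fit: models.FittedModel, mm: ModelMatrix) -> tuple[float, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return models.hosmer_lemeshow(fit.predict(mm.X), mm.y)
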