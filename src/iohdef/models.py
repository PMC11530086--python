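"""Outcome models and their scores.

Thirty-day mortality is modeled with maximum-likelihood logistic regression
(iteratively reweighted least squares, tolerance 1e-8, at most 100
iterations); the log-transformed length-of-stay outcomes with ordinary
least squares.  Both fits are closed-form deterministic, expose the
log-likelihood, AIC and the asymptotic covariance, and flag quasi-complete
separation.  Scoring uses the Brier score for the binary outcome, mean
squared error on the log scale for the metric outcomes, and the
Hosmer-Lemeshow Ĉ statistic on deciles of predicted risk as the
goodness-of-fit check for the mortality models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .design import ModelMatrix

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
#: |linear predictor| beyond which fitted probabilities are numerically
#: pinned at 0/1 and the fit is treated as quasi-separated.  A
#: standardized-coefficient cutoff misfires on collinear spline blocks
#: (large opposite-signed coefficients describing a modest function), so
#: the diagnostic operates on the fitted log-odds instead.
SEPARATION_ETA = 30.0


@dataclass
class FittedModel:
    """A fitted logistic or linear model with its fit statistics."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    aic: float
    n: int
    outcome: str
    link: str  # "logit" or "identity"
    converged: bool
    separation_flag: bool = False
    dropped_columns: list[str] = field(default_factory=list)
    scale: float | None = None  # residual variance (MLE) for identity link
    meta: dict = field(default_factory=dict)

    @property
    def k_params(self) -> int:
        """Estimated parameters: coefficients, plus sigma for linear models."""
        return len(self.params) + (1 if self.link == "identity" else 0)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Xa = X.reindex(columns=self.params.index, fill_value=0.0).to_numpy(float)
        return Xa @ self.params.to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(X)
        return special.expit(eta) if self.link == "logit" else eta


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop linearly dependent columns via pivoted QR, keeping leading ones."""
    if X.shape[1] == 0:
        return X, names, []
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank == X.shape[1]:
        return X, names, []
    keep = np.sort(piv[:rank])
    kept = [names[i] for i in keep]
    dropped = [names[i] for i in range(X.shape[1]) if i not in set(keep.tolist())]
    warnings.warn(f"rank-deficient design; dropping aliased columns {dropped}", stacklevel=3)
    return X[:, keep], kept, dropped


def fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """IRLS for the Bernoulli-logit likelihood.  Returns (beta, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    with warnings.catch_warnings():
        # near-separated fits produce ill-conditioned weighted normal
        # equations; the separation flag downstream handles those fits
        warnings.simplefilter("ignore", linalg.LinAlgWarning)
        for _ in range(IRLS_MAX_ITER):
            eta = X @ beta
            mu = special.expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            WX = X * w[:, None]
            try:
                beta_new = linalg.solve(X.T @ WX, WX.T @ z, assume_a="pos")
            except np.linalg.LinAlgError:
                beta_new = np.linalg.lstsq(X.T @ WX, WX.T @ z, rcond=None)[0]
            if np.max(np.abs(beta_new - beta)) < IRLS_TOL:
                return beta_new, True
            beta = beta_new
    return beta, False


def fit_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def fit_model(mm: ModelMatrix) -> FittedModel:
    """Fit the outcome-appropriate model on a model matrix.

    Logistic for the mortality outcome, OLS for the log-LOS outcomes.
    Aliased columns are dropped with a warning; quasi-complete separation
    (a standardized coefficient beyond 15 in absolute value) is flagged so
    the selection stage can exclude the fit from ranking.
    """
    names = list(mm.X.columns)
    X, names, dropped = _drop_aliased(mm.X.to_numpy(float), names)
    y = mm.y
    n, p = X.shape
    if mm.outcome == "mortality":
        beta, converged = fit_logistic(X, y)
        mu = special.expit(X @ beta)
        mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
        loglik = float(np.sum(y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        aic = 2 * p - 2 * loglik
        separation = bool(np.abs(X @ beta).max() > SEPARATION_ETA) or not converged
        fitted = FittedModel(
            params=pd.Series(beta, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            loglik=loglik,
            aic=aic,
            n=n,
            outcome=mm.outcome,
            link="logit",
            converged=converged,
            separation_flag=separation,
            dropped_columns=dropped,
            meta=mm.meta,
        )
    else:
        beta = fit_ols(X, y)
        resid = y - X @ beta
        rss = float(resid @ resid)
        sigma2_mle = rss / n
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_mle) + 1)
        # k counts the mean parameters plus the residual variance
        aic = 2 * (p + 1) - 2 * loglik
        sigma2 = rss / max(n - p, 1)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        fitted = FittedModel(
            params=pd.Series(beta, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            loglik=loglik,
            aic=aic,
            n=n,
            outcome=mm.outcome,
            link="identity",
            converged=True,
            dropped_columns=dropped,
            scale=sigma2_mle,
            meta=mm.meta,
        )
    return fitted


def brier_score(predicted_probs: np.ndarray, outcomes: np.ndarray) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predictions and outcomes differ in length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def mse(predictions: np.ndarray, outcomes: np.ndarray) -> float:
    """Mean squared residual (on the log scale the LOS models are fit on)."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predictions and outcomes differ in length")
    return float(np.mean((p - y) ** 2))


def hosmer_lemeshow(
    predicted_probs: np.ndarray, outcomes: np.ndarray, groups: int = 10
) -> tuple[float, float]:
    """Hosmer-Lemeshow Ĉ statistic on deciles of predicted risk.

    Ties in predicted risk stay in one group; if fewer than ``groups``
    distinct prediction levels exist the group count is reduced with a
    warning.  Returns ``(statistic, p_value)`` with ``df = groups - 2``.
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    distinct = np.unique(p).size
    g = groups
    if distinct < groups:
        g = max(distinct, 3)
        warnings.warn(
            f"only {distinct} distinct predictions; using {g} risk groups", stacklevel=2
        )
    bins = pd.qcut(p, q=g, duplicates="drop")
    frame = pd.DataFrame({"p": p, "y": y, "bin": bins})
    agg = frame.groupby("bin", observed=True).agg(n=("y", "size"), obs=("y", "sum"), exp=("p", "sum"))
    g_eff = len(agg)
    denom = agg["exp"] * (1 - agg["exp"] / agg["n"])
    denom = denom.replace(0, np.nan)
    stat = float((((agg["obs"] - agg["exp"]) ** 2) / denom).dropna().sum())
    df = max(g_eff - 2, 1)
    pval = float(stats.chi2.sf(stat, df))
    return stat, pval
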