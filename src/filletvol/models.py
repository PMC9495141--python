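"""Predictive modelling of fillet volume and yield.

Ordinary least squares (simple and multiple), greedy forward stepwise
selection scored by k-fold cross-validated RMSE, Pearson correlations with
t-test significance bands, and the two fillet-yield definitions (actual
weight ratio, and yield from the fillet volume predicted by the best
single-span model).

The selection criterion is the pooled k-fold CV-RMSE: folds are contiguous
blocks of one seeded shuffle, fixed across steps and candidates; at each
step the candidate with the lowest CV-RMSE enters if it improves the
current CV-RMSE by more than ``entry_tol`` (relative). Ties break toward
the earlier candidate in input order. Significance classes for
correlations come from the exact two-sided t test with df = n - 2, not
from tabulated bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

__all__ = [
    "RegressionFit",
    "StepwiseModel",
    "CorrelationResult",
    "DegeneratePredictorError",
    "fit_simple",
    "fit_multiple",
    "predict",
    "cv_rmse",
    "stepwise_forward_cv",
    "pearson_with_significance",
    "classify_correlation",
    "critical_r",
    "fillet_yield",
    "fillet_yield_v15",
]


class DegeneratePredictorError(ValueError):
    """Raised when a predictor (or the response pairing) has no variance."""


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit: intercept, per-predictor slopes, fit and CV error."""

    predictors: tuple[str, ...]
    intercept: float
    slopes: tuple[float, ...]
    r_squared: float
    rmse_resub: float
    n: int
    rmse_cv: float | None = None

    def __post_init__(self) -> None:
        if len(self.slopes) != len(self.predictors):
            raise ValueError("one slope per predictor required")

    def coef(self, name: str) -> float:
        return self.slopes[self.predictors.index(name)]


@dataclass(frozen=True)
class StepwiseModel:
    """Result of greedy forward selection under k-fold CV-RMSE."""

    selected: tuple[str, ...]
    fit: RegressionFit
    cv_trace: tuple[float, ...]   # CV-RMSE after each accepted step
    baseline_cv_rmse: float       # intercept-only CV-RMSE
    k: int
    seed: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    significance: str  # "ns", "p<0.05" or "p<0.01"


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(_design(X), y, rcond=None)
    return beta


def fit_multiple(
    X: pd.DataFrame | Mapping[str, Sequence[float]],
    y: Sequence[float],
    rmse_cv: float | None = None,
) -> RegressionFit:
    """OLS of y on the named columns of X."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y must have the same length")
    n = len(y)
    if n < len(X.columns) + 2:
        raise ValueError("not enough observations for the requested fit")
    mat = X.to_numpy(dtype=float)
    if np.any(np.ptp(mat, axis=0) == 0):
        raise DegeneratePredictorError("a predictor column is constant")
    beta = _ols(mat, y)
    resid = y - _design(mat) @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return RegressionFit(
        predictors=tuple(X.columns),
        intercept=float(beta[0]),
        slopes=tuple(float(b) for b in beta[1:]),
        r_squared=float(r2),
        rmse_resub=float(np.sqrt(sse / n)),
        n=n,
        rmse_cv=rmse_cv,
    )


def fit_simple(
    x: Sequence[float], y: Sequence[float], name: str = "x"
) -> RegressionFit:
    """Simple linear regression of y on one trait vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least three observations")
    return fit_multiple(pd.DataFrame({name: x}), y)


def predict(fit: RegressionFit, x) -> float | np.ndarray:
    """Evaluate a fit: intercept + sum of slope·value over its predictors.

    ``x`` may be a scalar (single-predictor fits only), a mapping of
    predictor name to value/vector, or a DataFrame containing the
    predictor columns.
    """
    if np.isscalar(x):
        if len(fit.predictors) != 1:
            raise KeyError("scalar input valid only for single-predictor fits")
        return fit.intercept + fit.slopes[0] * x
    if isinstance(x, pd.DataFrame):
        x = {c: x[c].to_numpy(float) for c in x.columns}
    out = fit.intercept
    for name, slope in zip(fit.predictors, fit.slopes):
        if name not in x:
            raise KeyError(f"missing predictor {name!r}")
        out = out + slope * np.asarray(x[name], dtype=float)
    return out


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Contiguous test blocks of one seeded shuffle (fixed across steps)."""
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]


def cv_rmse(
    X: pd.DataFrame | None,
    y: Sequence[float],
    k: int = 10,
    seed: int = 0,
    folds: Sequence[np.ndarray] | None = None,
) -> float:
    """Pooled k-fold cross-validated RMSE of an OLS model.

    ``X = None`` scores the intercept-only model (training-mean
    prediction), the stepwise baseline.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds is None:
        folds = _fold_indices(n, k, seed)
    sq = np.empty(n)
    mask = np.ones(n, dtype=bool)
    mat = None if X is None else pd.DataFrame(X).to_numpy(dtype=float)
    for test in folds:
        mask[:] = True
        mask[test] = False
        if mat is None:
            pred = np.full(len(test), y[mask].mean())
        else:
            beta = _ols(mat[mask], y[mask])
            pred = _design(mat[test]) @ beta
        sq[test] = (y[test] - pred) ** 2
    return float(np.sqrt(sq.mean()))


def stepwise_forward_cv(
    candidates: pd.DataFrame | Mapping[str, Sequence[float]],
    y: Sequence[float],
    k: int = 10,
    seed: int = 0,
    entry_tol: float = 1e-3,
) -> StepwiseModel:
    """Greedy forward selection scored by k-fold CV-RMSE.

    At each step every remaining candidate is tried as a one-variable
    addition; the one with the lowest CV-RMSE enters if it improves the
    incumbent CV-RMSE by more than ``entry_tol`` relative. Fold assignment
    is one seeded shuffle into contiguous blocks, reused for every
    candidate and step so scores are comparable.
    """
    candidates = pd.DataFrame(candidates)
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = _fold_indices(n, k, seed)
    names = list(candidates.columns)
    # constant candidates can never be fitted; drop them up front
    names = [c for c in names if np.ptp(candidates[c].to_numpy(float)) > 0]

    selected: list[str] = []
    baseline = cv_rmse(None, y, folds=folds)
    current = baseline
    trace: list[float] = []
    while len(selected) < len(names):
        best_name, best_score = None, np.inf
        for cand in names:
            if cand in selected:
                continue
            score = cv_rmse(candidates[selected + [cand]], y, folds=folds)
            if score < best_score:  # strict: ties keep the earlier candidate
                best_name, best_score = cand, score
        if best_name is None or (current - best_score) <= entry_tol * current:
            break
        selected.append(best_name)
        current = best_score
        trace.append(best_score)
    final = fit_multiple(candidates[selected], y, rmse_cv=current) if selected else None
    if final is None:
        # no candidate beat the intercept-only baseline
        final = RegressionFit(
            predictors=(),
            intercept=float(y.mean()),
            slopes=(),
            r_squared=0.0,
            rmse_resub=float(y.std()),
            n=n,
            rmse_cv=baseline,
        )
    return StepwiseModel(
        selected=tuple(selected),
        fit=final,
        cv_trace=tuple(trace),
        baseline_cv_rmse=baseline,
        k=k,
        seed=seed,
    )


def classify_correlation(r: float, n: int) -> tuple[float, str]:
    """Two-sided t test of a Pearson r at df = n - 2: (p, class)."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0, "p<0.01"
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if p < 0.01:
        return p, "p<0.01"
    if p < 0.05:
        return p, "p<0.05"
    return p, "ns"


def pearson_with_significance(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation with its significance class (t test, df=n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegeneratePredictorError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    p, cls = classify_correlation(r, len(x))
    return CorrelationResult(r=r, n=len(x), p_value=p, significance=cls)


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at level alpha for sample size n (df=n-2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    t = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(t * t + n - 2))


def fillet_yield(fillet_weight: float, body_weight: float):
    """Fillet yield in %: 100 · fillet_weight / body_weight."""
    body_weight = np.asarray(body_weight, dtype=float)
    if np.any(body_weight <= 0):
        raise ValueError("body_weight must be positive")
    out = 100.0 * np.asarray(fillet_weight, dtype=float) / body_weight
    return float(out) if out.ndim == 0 else out


def fillet_yield_v15(fit_v15: RegressionFit, v15, body_weight):
    """Yield computed from the fillet volume *predicted* from V1-5.

    The predicted-volume yield: 100 · predict(fit, V1-5) / body weight.
    The fit must be the single-predictor model on the V1-5 span.
    """
    if len(fit_v15.predictors) != 1:
        raise ValueError("fit must have exactly one predictor (the V1-5 span)")
    return fillet_yield(predict(fit_v15, {fit_v15.predictors[0]: v15}), body_weight)
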