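"""Nested cross-validated LASSO feature selection with fold-frequency stability.

The selection procedure is the glmnet-style workflow for an L1-penalised
logistic model:

* a descending log-spaced penalty grid from ``lambda_max`` (the smallest
  penalty that zeroes every coefficient, ``max |X'(y - ybar)| / n``) down to
  ``1e-3 * lambda_max``;
* k-fold cross-validated binomial deviance per penalty, with the one-standard-
  error rule: ``lambda_1se`` is the largest penalty whose mean CV error is
  within one standard error of the minimum;
* stability scores: the fraction of outer CV folds in which a feature enters
  the active set of the inner-CV-tuned model; features at or above a frequency
  threshold (default 50%) are retained.

The penalty convention matches the objective ``(1/n) sum loss + lambda |w|_1``
(an unpenalised intercept, features assumed pre-standardised upstream); the
per-fit solver is liblinear with ``C = 1 / (n * lambda)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LassoCVResult",
    "StabilityResult",
    "lasso_cv",
    "select_lambda_1se",
    "nested_stability_selection",
    "single_lasso_reference",
]

_EPS = 1e-12


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got classes {classes.tolist()}")
    return (y == classes[1]).astype(int)


def lambda_max(X: np.ndarray, y01: np.ndarray) -> float:
    """Smallest penalty at which the L1 logistic solution is all-zero."""
    n = len(y01)
    resid = y01 - y01.mean()
    return float(np.max(np.abs(X.T @ resid)) / n)


def default_lambda_grid(X: np.ndarray, y01: np.ndarray, n_lambda: int = 100) -> np.ndarray:
    lmax = lambda_max(X, y01)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, 1e-3 * lmax, n_lambda)


def _fit_l1(X: np.ndarray, y01: np.ndarray, lam: float) -> LogisticRegression:
    n = len(y01)
    C = 1.0 / max(n * lam, _EPS)
    model = LogisticRegression(
        l1_ratio=1, C=C, solver="liblinear", tol=1e-6, max_iter=2000,
        random_state=0,
    )
    model.fit(X, y01)
    return model


def _binomial_deviance(y01: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y01 * np.log(p) + (1 - y01) * np.log(1 - p)))


def select_lambda_1se(lambdas: np.ndarray, mean_errors: np.ndarray,
                      ses: np.ndarray) -> tuple[float, float]:
    """(lambda_min, lambda_1se) under the one-standard-error rule.

    ``lambda_min`` minimises the mean CV error (largest penalty on ties);
    ``lambda_1se`` is the largest penalty with mean error within one standard
    error of that minimum.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    mean_errors = np.asarray(mean_errors, dtype=float)
    order = np.argsort(lambdas)[::-1]  # descending
    lam_d, err_d, se_d = lambdas[order], mean_errors[order], np.asarray(ses)[order]
    i_min = int(np.argmin(err_d))  # first (= largest lambda) among ties
    bound = err_d[i_min] + se_d[i_min]
    i_1se = int(np.flatnonzero(err_d <= bound + _EPS)[0])
    return float(lam_d[i_min]), float(lam_d[i_1se])


@dataclass
class LassoCVResult:
    """Cross-validation summary of one penalised-logistic path."""

    lambdas: np.ndarray            # descending
    mean_errors: np.ndarray        # mean CV binomial deviance per lambda
    se_errors: np.ndarray          # SD across folds / sqrt(k)
    lambda_min: float
    lambda_1se: float
    active_1se: list[str]          # feature names active at lambda_1se (full refit)
    feature_names: list[str]
    active_sets: list[list[str]] | None = None  # per-lambda, if path requested

    def __post_init__(self) -> None:
        assert self.lambda_1se >= self.lambda_min - _EPS


def lasso_cv(
    X: np.ndarray,
    y,
    feature_names: list[str] | None = None,
    k: int = 5,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    seed: int = 0,
    path_active_sets: bool = False,
    max_fold_retries: int = 20,
) -> LassoCVResult:
    """k-fold cross-validated L1 logistic path with the 1-SE rule.

    A degenerate fold whose training part is single-class triggers a reshuffle
    of the fold assignment (with a warning); this can only occur for extreme
    class imbalance at small n.
    """
    X = np.asarray(X, dtype=float)
    y01 = _check_binary(y)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    if lambdas is None:
        lambdas = default_lambda_grid(X, y01, n_lambda)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    # fold assignment, retried if a training part degenerates
    for attempt in range(max_fold_retries):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(X, y01))
        ok = all(len(np.unique(y01[tr])) == 2 and len(np.unique(y01[te])) >= 1
                 for tr, te in splits)
        if ok:
            if attempt > 0:
                warnings.warn("resampled degenerate CV folds", UserWarning, stacklevel=2)
            break
    else:
        raise ValueError("could not build non-degenerate stratified folds")

    # walk the path from heavy to light penalty; once the CV error curve is
    # well past its minimum the remaining (overfitting) tail cannot move
    # lambda_min or lambda_1se, so it is not fitted (glmnet-style early exit)
    patience = 20
    errors = np.empty((k, len(lambdas)))
    n_used = len(lambdas)
    best_li = 0
    running = np.empty(len(lambdas))
    for li, lam in enumerate(lambdas):
        for fi, (tr, te) in enumerate(splits):
            model = _fit_l1(X[tr], y01[tr], lam)
            z = X[te] @ model.coef_[0] + model.intercept_[0]
            p = 1.0 / (1.0 + np.exp(-z))
            errors[fi, li] = _binomial_deviance(y01[te], p)
        running[li] = errors[:, li].mean()
        if running[li] < running[best_li]:
            best_li = li
        if li - best_li >= patience:
            n_used = li + 1
            break
    lambdas = lambdas[:n_used]
    errors = errors[:, :n_used]
    mean_errors = errors.mean(axis=0)
    se_errors = errors.std(axis=0, ddof=1) / np.sqrt(k)

    lam_min, lam_1se = select_lambda_1se(lambdas, mean_errors, se_errors)

    full_1se = _fit_l1(X, y01, lam_1se)
    active_1se = [feature_names[j] for j in np.flatnonzero(np.abs(full_1se.coef_[0]) > 1e-10)]

    active_sets = None
    if path_active_sets:
        active_sets = []
        for lam in lambdas:
            m = _fit_l1(X, y01, lam)
            active_sets.append(
                [feature_names[j] for j in np.flatnonzero(np.abs(m.coef_[0]) > 1e-10)]
            )

    return LassoCVResult(
        lambdas=lambdas, mean_errors=mean_errors, se_errors=se_errors,
        lambda_min=lam_min, lambda_1se=lam_1se, active_1se=active_1se,
        feature_names=list(feature_names), active_sets=active_sets,
    )


@dataclass
class StabilityResult:
    """Per-feature outer-fold selection frequencies and the retained set."""

    frequencies: dict[str, float]      # values in {0, 1/K, ..., 1}
    retained: list[str]
    threshold: float
    outer_k: int
    fold_active_sets: list[list[str]] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {"feature": f, "frequency": freq, "retained": f in self.retained}
            for f, freq in sorted(self.frequencies.items(), key=lambda kv: -kv[1])
        ]


def nested_stability_selection(
    X: np.ndarray,
    y,
    feature_names: list[str] | None = None,
    outer_k: int = 5,
    inner_k: int = 5,
    threshold: float = 0.5,
    seed: int = 0,
    n_lambda: int = 100,
) -> StabilityResult:
    """Outer-fold stability scores of inner-CV-tuned LASSO active sets.

    For each outer stratified fold, the inner CV tunes the penalty on the
    outer-training portion under the 1-SE rule and the active set of that
    model is recorded; a feature's stability score is the fraction of outer
    folds in which it was active, and features scoring at or above
    ``threshold`` are retained.
    """
    X = np.asarray(X, dtype=float)
    y01 = _check_binary(y)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    counts = np.bincount(y01)
    if counts.min() < outer_k:
        raise ValueError(f"each class needs >= outer_k={outer_k} members")

    skf = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    fold_sets: list[list[str]] = []
    for fi, (tr, _te) in enumerate(skf.split(X, y01)):
        res = lasso_cv(
            X[tr], y01[tr], feature_names=feature_names, k=inner_k,
            n_lambda=n_lambda, seed=seed * 1000 + fi,
        )
        fold_sets.append(res.active_1se)

    freqs = {
        f: sum(f in s for s in fold_sets) / outer_k for f in feature_names
    }
    retained = [f for f in feature_names if freqs[f] >= threshold]
    return StabilityResult(
        frequencies=freqs, retained=retained, threshold=threshold,
        outer_k=outer_k, fold_active_sets=fold_sets,
    )


def single_lasso_reference(
    X: np.ndarray,
    y,
    feature_names: list[str] | None = None,
    inner_k: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
) -> list[str]:
    """Active set of one 10-fold-CV LASSO run on the full training data.

    The comparison model ("LASSO + logistic") uses this set instead of the
    stability-selected one.
    """
    res = lasso_cv(X, y, feature_names=feature_names, k=inner_k,
                   n_lambda=n_lambda, seed=seed)
    return res.active_1se
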