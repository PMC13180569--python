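"""Multi-classifier benchmark under a three-level validation strategy.

Five model kinds are compared on the same standardized feature matrix:
logistic regression on the stability-selected features, random forest,
linear-kernel SVM (Platt-calibrated probabilities), gradient-boosted trees,
and logistic regression on a single-run LASSO feature set.  Hyperparameters
come from small documented grids tuned by inner stratified CV on AUC.

Validation has three levels: (1) stability — repeated stratified k-fold CV on
the training set (default 10 × 5, i.e. 50 fold AUCs per model); (2) robustness
— percentile intervals from stratified bootstrap resamples of the held-out
test predictions (resample indices are shared across models so post-hoc
pairwise tests are paired); (3) generalizability — a single evaluation on the
untouched test set, reported both at the Youden-optimal threshold and at the
conventional 0.5 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import SVC

from .roc import auc_mann_whitney, delong_ci, youden_cutoff

__all__ = [
    "MODEL_KINDS",
    "DEFAULT_GRIDS",
    "TrainedModel",
    "MetricSet",
    "ValidationSummary",
    "BenchmarkResult",
    "train_model",
    "metrics_at_best_threshold",
    "metrics_at_threshold",
    "metrics_from_rates",
    "three_level_validation",
    "summarize_logistic",
]

MODEL_KINDS = (
    "logistic", "random_forest", "svm_linear", "gradient_boosting", "lasso_logistic",
)

# Hyperparameter grids, frozen; logistic kinds have nothing to tune beyond
# their feature sets.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic": {},
    "lasso_logistic": {},
    "random_forest": {"n_estimators": [200, 500], "max_depth": [3, 5, None]},
    "svm_linear": {"estimator__C": [0.01, 0.1, 1.0, 10.0]},
    "gradient_boosting": {
        "learning_rate": [0.05, 0.1],
        "n_estimators": [100, 300],
        "max_depth": [2, 3],
    },
}


def _base_estimator(kind: str, seed: int):
    if kind in {"logistic", "lasso_logistic"}:
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if kind == "svm_linear":
        # Platt sigmoid calibration fit on internal CV folds
        return CalibratedClassifierCV(
            SVC(kernel="linear", random_state=seed), method="sigmoid", ensemble=False
        )
    if kind == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown model kind: {kind!r}")


@dataclass
class TrainedModel:
    kind: str
    estimator: object
    features: list[str]
    hyperparameters: dict
    positive_label: object

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        cols = X[self.features] if isinstance(X, pd.DataFrame) else X
        proba = self.estimator.predict_proba(cols)
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]


def _encode(y, positive_label) -> np.ndarray:
    y = np.asarray(y)
    return (y == positive_label).astype(int)


def train_model(
    kind: str,
    X: pd.DataFrame,
    y,
    features: list[str],
    positive_label,
    inner_k: int = 5,
    grid: dict | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one model kind on the given feature subset.

    Non-empty grids are tuned by inner stratified CV on AUC; the winning
    parameters are refit on all training rows.  Deterministic given
    (data, seed, grid).
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind: {kind!r}")
    if grid is None:
        grid = DEFAULT_GRIDS[kind]
    y01 = _encode(y, positive_label)
    Xf = X[features] if isinstance(X, pd.DataFrame) else np.asarray(X)
    est = _base_estimator(kind, seed)
    if grid:
        cv = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
        search = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, n_jobs=1)
        search.fit(Xf, y01)
        est = search.best_estimator_
        params = dict(search.best_params_)
    else:
        est.fit(Xf, y01)
        params = {}
    return TrainedModel(kind=kind, estimator=est, features=list(features),
                        hyperparameters=params, positive_label=positive_label)


# ---------------------------------------------------------------------------
# metric arithmetic
# ---------------------------------------------------------------------------

@dataclass
class MetricSet:
    """One operating point plus ranking metrics for a binary classifier."""

    auc: float
    auc_ci95: tuple[float, float]
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    youden: float
    threshold: float

    def __post_init__(self) -> None:
        # identities, not conventions
        assert abs(self.balanced_accuracy - (self.sensitivity + self.specificity) / 2) < 1e-12
        assert abs(self.youden - (self.sensitivity + self.specificity - 1)) < 1e-12


def _confusion_metrics(tp: float, fn: float, fp: float, tn: float) -> dict[str, float]:
    n = tp + fn + fp + tn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
        "f1": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0,
        "youden": sens + spec - 1.0,
    }


def metrics_from_rates(
    sensitivity: float, specificity: float,
    n_positive: int | None = None, n_negative: int | None = None,
) -> dict[str, float]:
    """Derive the full metric panel from (sensitivity, specificity) alone.

    Balanced accuracy and Youden's J need no class sizes; accuracy and F1 do
    and are reported only when both sizes are given (integer confusion cells
    by rounding rate x size).
    """
    out = {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "balanced_accuracy": (sensitivity + specificity) / 2.0,
        "youden": sensitivity + specificity - 1.0,
    }
    if n_positive is not None and n_negative is not None:
        tp = round(sensitivity * n_positive)
        fn = n_positive - tp
        tn = round(specificity * n_negative)
        fp = n_negative - tn
        cm = _confusion_metrics(tp, fn, fp, tn)
        out["accuracy"] = cm["accuracy"]
        out["f1"] = cm["f1"]
    return out


def metrics_at_threshold(probabilities, labels01, threshold: float) -> MetricSet:
    """Metric panel at a fixed probability threshold (predict positive if >=)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels01, dtype=int)
    if y.min() == y.max():
        raise ValueError("AUC undefined for single-class labels")
    pred = p >= threshold
    tp = float((pred & (y == 1)).sum())
    fn = float((~pred & (y == 1)).sum())
    fp = float((pred & (y == 0)).sum())
    tn = float((~pred & (y == 0)).sum())
    cm = _confusion_metrics(tp, fn, fp, tn)
    return MetricSet(
        auc=auc_mann_whitney(p, y), auc_ci95=delong_ci(p, y),
        accuracy=cm["accuracy"], balanced_accuracy=cm["balanced_accuracy"],
        sensitivity=cm["sensitivity"], specificity=cm["specificity"],
        f1=cm["f1"], youden=cm["youden"], threshold=float(threshold),
    )


def metrics_at_best_threshold(probabilities, labels01) -> MetricSet:
    """Metric panel at the Youden-optimal threshold (ties favour specificity)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels01, dtype=int)
    if y.min() == y.max():
        raise ValueError("AUC undefined for single-class labels")
    cut, _sens, _spec = youden_cutoff(p, y, orientation="high")
    return metrics_at_threshold(p, y, cut)


# ---------------------------------------------------------------------------
# three-level validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationSummary:
    kind: str
    cv_aucs: np.ndarray
    cv_mean: float
    cv_sd: float
    cv_coefficient: float
    bootstrap_ci95: tuple[float, float]
    bootstrap_aucs: np.ndarray
    holdout_best: MetricSet
    holdout_half: MetricSet

    def panel_row(self) -> dict:
        m = self.holdout_best
        return {
            "model": self.kind,
            "AUC": m.auc, "AUC_CI_low": m.auc_ci95[0], "AUC_CI_high": m.auc_ci95[1],
            "accuracy": m.accuracy, "balanced_accuracy": m.balanced_accuracy,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "F1": m.f1, "youden": m.youden, "best_threshold": m.threshold,
            "cv_mean_AUC": self.cv_mean, "cv_sd_AUC": self.cv_sd,
            "cv_coefficient": self.cv_coefficient,
            "bootstrap_CI_low": self.bootstrap_ci95[0],
            "bootstrap_CI_high": self.bootstrap_ci95[1],
        }


@dataclass
class BenchmarkResult:
    summaries: dict[str, ValidationSummary]
    fold_auc_matrix: pd.DataFrame      # models x (reps*k) fold AUCs
    bootstrap_matrix: pd.DataFrame     # models x B paired test-set bootstrap AUCs

    def panel(self) -> pd.DataFrame:
        return pd.DataFrame([s.panel_row() for s in self.summaries.values()])


def three_level_validation(
    model_specs: dict[str, list[str]],
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    positive_label,
    reps: int = 10,
    k: int = 5,
    boot_B: int = 1000,
    inner_k: int = 5,
    seed: int = 0,
) -> BenchmarkResult:
    """Benchmark each (kind -> feature set) spec on disjoint train/test data.

    Hyperparameters are tuned once on the full training set; repeated-CV
    refits clone those parameters per fold.  Test-set bootstrap resamples are
    stratified and shared across models.
    """
    y_tr = _encode(y_train, positive_label)
    y_te = _encode(y_test, positive_label)
    if y_te.min() == y_te.max():
        raise ValueError("test set must contain both classes")

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y_te == 1)
    neg_idx = np.flatnonzero(y_te == 0)
    boot_rows = [
        np.concatenate([
            rng.choice(pos_idx, size=len(pos_idx), replace=True),
            rng.choice(neg_idx, size=len(neg_idx), replace=True),
        ])
        for _ in range(boot_B)
    ]

    rskf = RepeatedStratifiedKFold(n_splits=k, n_repeats=reps, random_state=seed)
    splits = list(rskf.split(np.zeros(len(y_tr)), y_tr))

    summaries: dict[str, ValidationSummary] = {}
    fold_rows = {}
    boot_mat = {}
    for kind, features in model_specs.items():
        tuned = train_model(kind, X_train, y_tr, features, positive_label=1,
                            inner_k=inner_k, seed=seed)
        # level 1: repeated CV with the tuned hyperparameters
        cv_aucs = np.empty(len(splits))
        Xf = X_train[features].to_numpy()
        for i, (tr, te) in enumerate(splits):
            est = clone(tuned.estimator)
            est.fit(Xf[tr], y_tr[tr])
            pos_col = list(est.classes_).index(1)
            p = est.predict_proba(Xf[te])[:, pos_col]
            cv_aucs[i] = auc_mann_whitney(p, y_tr[te])
        cv_mean = float(cv_aucs.mean())
        cv_sd = float(cv_aucs.std(ddof=1))

        # levels 2 & 3: single fit on full training data, touch test once
        p_test = tuned.predict_proba(X_test)
        boot_aucs = np.array([
            auc_mann_whitney(p_test[rows], y_te[rows]) for rows in boot_rows
        ])
        lo, hi = np.percentile(boot_aucs, [2.5, 97.5])
        best = metrics_at_best_threshold(p_test, y_te)
        half = metrics_at_threshold(p_test, y_te, 0.5)

        summaries[kind] = ValidationSummary(
            kind=kind, cv_aucs=cv_aucs, cv_mean=cv_mean, cv_sd=cv_sd,
            cv_coefficient=cv_sd / cv_mean if cv_mean else float("nan"),
            bootstrap_ci95=(float(lo), float(hi)), bootstrap_aucs=boot_aucs,
            holdout_best=best, holdout_half=half,
        )
        fold_rows[kind] = cv_aucs
        boot_mat[kind] = boot_aucs

    fold_df = pd.DataFrame(fold_rows).T
    boot_df = pd.DataFrame(boot_mat).T
    return BenchmarkResult(summaries=summaries, fold_auc_matrix=fold_df,
                           bootstrap_matrix=boot_df)


# ---------------------------------------------------------------------------
# logistic coefficient table
# ---------------------------------------------------------------------------

def summarize_logistic(
    X: pd.DataFrame, y, features: list[str], positive_label,
) -> pd.DataFrame:
    """Wald summary of an unpenalised logistic fit on standardized features.

    Columns: coefficient B, SE, z = B/SE, two-sided p, OR = exp(B) and the
    95% CI exp(B ± 1.96 SE).  Quasi-separation (non-finite or exploding SEs)
    flags the row and suppresses its interval.
    """
    y01 = _encode(y, positive_label)
    design = sm.add_constant(X[features].to_numpy())
    names = ["Intercept"] + list(features)
    try:
        fit = sm.Logit(y01, design).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:  # perfect separation raises in statsmodels
        fit = None
        converged = False

    rows = []
    for i, name in enumerate(names):
        if fit is None:
            rows.append({"feature": name, "B": np.nan, "SE": np.nan, "z": np.nan,
                         "p": np.nan, "OR": np.nan, "CI_low": np.nan,
                         "CI_high": np.nan, "separation_flag": True})
            continue
        b = float(fit.params[i])
        se = float(fit.bse[i])
        flagged = (not converged) or (not np.isfinite(se)) or se > 50
        z = b / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({
            "feature": name, "B": b, "SE": se, "z": z, "p": p,
            "OR": float(np.exp(b)),
            "CI_low": np.nan if flagged else float(np.exp(b - 1.96 * se)),
            "CI_high": np.nan if flagged else float(np.exp(b + 1.96 * se)),
            "separation_flag": flagged,
        })
    return pd.DataFrame(rows)
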