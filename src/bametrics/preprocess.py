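"""Leakage-safe splitting and standardization.

The modelling contract is strict: the train/test split happens before any
feature selection, standardization moments come from training rows only and
are reused verbatim downstream, and all fold assignments are stratified and
replayable from (ids, seed).

Test-set sizes follow a largest-remainder allocation: the total test size is
the ceiling of ``test_fraction * n`` and per-stratum seats are the floors of
the stratum quotas topped up in decreasing-remainder order.  For a cohort of
112 + 50 at an 8:2 split this yields 23 + 10 = 33 test subjects against 129
for training.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SplitPlan",
    "FoldAssignment",
    "StandardizationParams",
    "SplitError",
    "stratified_split",
    "assign_folds",
    "fit_standardizer",
    "apply_standardizer",
]


class SplitError(ValueError):
    """Labels cannot support the requested split or fold structure."""


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    stratum_test_counts: dict
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "stratum_test_counts": {str(k): int(v) for k, v in self.stratum_test_counts.items()},
            "seed": int(self.seed),
        }


@dataclass
class FoldAssignment:
    folds: list[np.ndarray]  # test indices of each fold
    k: int
    seed: int

    def to_json_dict(self) -> dict:
        return {"k": self.k, "seed": int(self.seed), "folds": [f.tolist() for f in self.folds]}

    def iter_splits(self, n: int):
        """Yield (train_idx, test_idx) pairs in fold order."""
        all_idx = np.arange(n)
        for test in self.folds:
            mask = np.ones(n, dtype=bool)
            mask[test] = False
            yield all_idx[mask], test


def _largest_remainder_counts(counts: dict, fraction: float) -> dict:
    quotas = {k: fraction * n for k, n in counts.items()}
    total = int(math.ceil(sum(quotas.values()) - 1e-9))
    base = {k: int(math.floor(q)) for k, q in quotas.items()}
    extra = total - sum(base.values())
    # deterministic top-up: largest fractional remainder first, stratum size
    # then name as tie-breaks
    order = sorted(
        counts,
        key=lambda k: (-(quotas[k] - base[k]), -counts[k], str(k)),
    )
    out = dict(base)
    for k in order[:extra]:
        out[k] += 1
    return out


def stratified_split(labels, test_fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Stratified train/test split with largest-remainder test allocation.

    Per-stratum test counts are fixed by the allocation rule; which subjects
    fill them is random given ``seed``.
    """
    labels = np.asarray(labels)
    if not 0 < test_fraction < 1:
        raise SplitError(f"test_fraction must be in (0,1), got {test_fraction}")
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise SplitError("need at least 2 classes to stratify")
    count_map = dict(zip(values.tolist(), counts.tolist()))
    for k, n in count_map.items():
        if n < 2:
            raise SplitError(f"stratum {k!r} has fewer than 2 members")
    test_counts = _largest_remainder_counts(count_map, test_fraction)

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for k in values.tolist():
        members = np.flatnonzero(labels == k)
        chosen = rng.choice(members, size=test_counts[k], replace=False)
        test_idx.extend(chosen.tolist())
    test = np.array(sorted(test_idx), dtype=int)
    mask = np.ones(len(labels), dtype=bool)
    mask[test] = False
    train = np.flatnonzero(mask)
    return SplitPlan(train_idx=train, test_idx=test,
                     stratum_test_counts=test_counts, seed=seed)


def assign_folds(labels, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold partition; per-fold class counts differ by ≤ 1."""
    labels = np.asarray(labels)
    values, counts = np.unique(labels, return_counts=True)
    small = [str(v) for v, c in zip(values, counts) if c < k]
    if small:
        raise SplitError(f"classes smaller than k={k}: {small}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(labels)), labels)]
    return FoldAssignment(folds=folds, k=k, seed=seed)


@dataclass
class StandardizationParams:
    """Training-set column moments (ddof=1 SD) and dropped constant columns."""

    means: pd.Series
    sds: pd.Series
    dropped: list = field(default_factory=list)

    @property
    def columns(self) -> list:
        return list(self.means.index)


def fit_standardizer(train: pd.DataFrame) -> StandardizationParams:
    """Column-wise z-score parameters from training rows only.

    Missing cells are ignored in the moment estimates; all-missing columns are
    an error; zero-variance columns are dropped with a warning rather than
    given a unit SD — a constant feature carries no signal and destabilises
    penalised fits.
    """
    means = train.mean(axis=0, skipna=True)
    sds = train.std(axis=0, ddof=1, skipna=True)
    all_missing = [c for c in train.columns if train[c].notna().sum() == 0]
    if all_missing:
        raise SplitError(f"all-missing columns: {all_missing}")
    constant = [c for c in train.columns if not (sds[c] > 0)]
    if constant:
        warnings.warn(f"dropping zero-variance columns: {constant}", UserWarning,
                      stacklevel=2)
    keep = [c for c in train.columns if c not in constant]
    return StandardizationParams(means=means[keep], sds=sds[keep], dropped=constant)


def apply_standardizer(params: StandardizationParams, features: pd.DataFrame) -> pd.DataFrame:
    """Apply frozen training moments; never refit on the incoming data."""
    cols = params.columns
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise SplitError(f"features are missing standardized columns: {missing}")
    return (features[cols] - params.means) / params.sds
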