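"""Single-marker ROC machinery and resampling robustness.

The point estimate is the Mann–Whitney two-sample statistic (probability that
a random positive outscores a random negative, ties counting one half), the
interval is DeLong's placement-value (structural-component) normal interval,
and the operating point is the Youden-optimal cutoff.  Robustness wrappers
cover stratified bootstrap percentile intervals, an add-one-corrected label
permutation test, repeated stratified holdout, and repeated stratified k-fold
cross-validation of the raw marker.

Orientation is always an explicit input: ``orientation="high"`` means high
scores indicate the positive class, ``"low"`` the reverse (e.g. a suppressed
metabolite marking disease).  It is never auto-flipped to inflate the AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .preprocess import stratified_split, assign_folds

__all__ = [
    "ROCError",
    "MarkerInference",
    "auc_mann_whitney",
    "delong_ci",
    "youden_cutoff",
    "bootstrap_auc",
    "permutation_test",
    "repeated_holdout_auc",
    "repeated_kfold_auc",
    "marker_inference",
]


class ROCError(ValueError):
    """Scores/labels cannot support the requested ROC computation."""


def _prepare(scores, labels, orientation: str = "high") -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ROCError("scores and labels must align")
    y = _binary01(labels)
    if y.min() == y.max():
        raise ROCError("both classes must be present")
    if orientation not in {"high", "low"}:
        raise ROCError(f"orientation must be 'high' or 'low', got {orientation!r}")
    if orientation == "low":
        scores = -scores
    return scores, y


def _binary01(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    if len(classes) > 2:
        raise ROCError(f"labels must be binary, got {classes.tolist()}")
    if set(classes.tolist()) <= {0, 1}:
        return labels.astype(int)
    return (labels == classes[1]).astype(int)


def auc_mann_whitney(scores, labels, orientation: str = "high") -> float:
    """Tie-aware pair-counting AUC via the rank-sum identity."""
    s, y = _prepare(scores, labels, orientation)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _placements(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = s[y == 1]
    neg = s[y == 0]
    # V10_i = mean_j psi(pos_i, neg_j); psi = 1 if >, .5 if ==, else 0
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :]).astype(float)
    psi = gt + 0.5 * eq
    return psi.mean(axis=1), 1.0 - psi.mean(axis=0)  # V01_j = mean_i psi as seen from negatives


def delong_ci(scores, labels, orientation: str = "high",
              level: float = 0.95) -> tuple[float, float]:
    """Normal-theory AUC interval from the placement-value variance.

    Degenerate zero variance (e.g. perfect separation) collapses to a
    zero-width interval at the estimate; bounds are truncated to [0, 1].
    """
    s, y = _prepare(scores, labels, orientation)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ROCError("DeLong interval needs >= 2 members per class")
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return (float(max(auc - half, 0.0)), float(min(auc + half, 1.0)))


def youden_cutoff(scores, labels, orientation: str = "high"
                  ) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximising J = sens + spec - 1.

    Candidate cutoffs are midpoints of adjacent distinct observed values;
    ties in J break toward higher specificity.  The cutoff is reported in
    original marker units with the decision direction implied by orientation
    (``"high"``: predict positive when score >= cutoff; ``"low"``: <=).
    """
    raw = np.asarray(scores, dtype=float)
    s, y = _prepare(scores, labels, orientation)
    uniq = np.unique(s)
    if len(uniq) == 1:
        # single observed value: everything classified positive at that cutoff
        sens, spec = 1.0, 0.0
        cut = uniq[0] if orientation == "high" else -uniq[0]
        return float(cut), sens, spec
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n1 = y.sum()
    n0 = len(y) - n1
    best = None
    for c in candidates:
        pred = s >= c
        sens = float((pred & (y == 1)).sum() / n1)
        spec = float((~pred & (y == 0)).sum() / n0)
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _key, cut, sens, spec = best
    if orientation == "low":
        cut = -cut
    return float(cut), sens, spec


def _auc_from_rank_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUC for (B, n1) positive and (B, n0) negative score matrices."""
    gt = (pos[:, :, None] > neg[:, None, :]).sum(axis=(1, 2))
    eq = (pos[:, :, None] == neg[:, None, :]).sum(axis=(1, 2))
    return (gt + 0.5 * eq) / (pos.shape[1] * neg.shape[1])


def bootstrap_auc(scores, labels, B: int = 2000, stratified: bool = True,
                  seed: int = 0, orientation: str = "high"
                  ) -> tuple[float, float]:
    """Percentile 95% interval of the AUC under (stratified) resampling."""
    s, y = _prepare(scores, labels, orientation)
    rng = np.random.default_rng(seed)
    pos = s[y == 1]
    neg = s[y == 0]
    if stratified:
        pos_b = pos[rng.integers(0, len(pos), size=(B, len(pos)))]
        neg_b = neg[rng.integers(0, len(neg), size=(B, len(neg)))]
        aucs = _auc_from_rank_matrix(pos_b, neg_b)
    else:
        aucs = np.empty(B)
        n = len(s)
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() == yb.max():
                aucs[b] = np.nan
                continue
            sb = s[idx]
            aucs[b] = _auc_from_rank_matrix(sb[yb == 1][None, :], sb[yb == 0][None, :])[0]
        aucs = aucs[~np.isnan(aucs)]
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def permutation_test(scores, labels, B: int = 5000, seed: int = 0,
                     orientation: str = "high") -> float:
    """Add-one-corrected one-sided label-permutation p for the AUC.

    p = (1 + #{permuted AUC >= observed}) / (B + 1); the alternative is a
    larger-than-null AUC at the fixed orientation, so p is never exactly 0.
    """
    s, y = _prepare(scores, labels, orientation)
    rng = np.random.default_rng(seed)
    n = len(s)
    n1 = int(y.sum())
    n0 = n - n1
    ranks = stats.rankdata(s)
    obs = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # permuting labels = drawing a random n1-subset: vectorised via argsort
    u = rng.random((B, n))
    perm_pos = np.argsort(u, axis=1)[:, :n1]
    rank_sums = ranks[perm_pos].sum(axis=1)
    perm_auc = (rank_sums - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    exceed = int((perm_auc >= obs - 1e-12).sum())
    return float((1 + exceed) / (B + 1))


def repeated_holdout_auc(scores, labels, repeats: int = 1000,
                         test_fraction: float = 0.2, seed: int = 0,
                         orientation: str = "high") -> tuple[float, float]:
    """Percentile 2.5/97.5 range of the marker AUC over stratified holdouts."""
    s, y = _prepare(scores, labels, orientation)
    counts = np.bincount(y)
    if counts.min() < 5:
        raise ROCError("repeated holdout needs >= 5 members per class")
    aucs = np.empty(repeats)
    for r in range(repeats):
        plan = stratified_split(y, test_fraction=test_fraction, seed=seed + r)
        te = plan.test_idx
        aucs[r] = auc_mann_whitney(s[te], y[te])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def repeated_kfold_auc(scores, labels, k: int = 5, repetitions: int = 200,
                       seed: int = 0, orientation: str = "high"
                       ) -> tuple[float, float]:
    """Percentile interval of per-repetition mean fold AUCs.

    Each repetition draws a fresh stratified k-fold partition, computes the
    marker AUC within each fold, and records the mean of the k fold AUCs.
    """
    s, y = _prepare(scores, labels, orientation)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ROCError(f"repeated k-fold needs >= k={k} members per class")
    means = np.empty(repetitions)
    for r in range(repetitions):
        fa = assign_folds(y, k=k, seed=seed + r)
        fold_aucs = [auc_mann_whitney(s[f], y[f]) for f in fa.folds]
        means[r] = float(np.mean(fold_aucs))
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class MarkerInference:
    """Full robustness summary for one diagnostic marker."""

    marker: str
    orientation: str
    auc: float
    delong_ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    bootstrap_B: int
    bootstrap_ci95: tuple[float, float]
    permutation_B: int
    permutation_p: float
    holdout_repeats: int
    holdout_range95: tuple[float, float]
    kfold_repetitions: int
    kfold_interval95: tuple[float, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def marker_inference(
    scores, labels, marker: str = "marker", orientation: str = "high",
    bootstrap_B: int = 2000, permutation_B: int = 5000,
    holdout_repeats: int = 1000, kfold_repetitions: int = 200,
    kfold_k: int = 5, seed: int = 0,
) -> MarkerInference:
    """Run the full single-marker robustness suite with one seed."""
    auc = auc_mann_whitney(scores, labels, orientation)
    ci = delong_ci(scores, labels, orientation)
    cut, sens, spec = youden_cutoff(scores, labels, orientation)
    boot = bootstrap_auc(scores, labels, B=bootstrap_B, seed=seed,
                         orientation=orientation)
    perm = permutation_test(scores, labels, B=permutation_B, seed=seed + 1,
                            orientation=orientation)
    hold = repeated_holdout_auc(scores, labels, repeats=holdout_repeats,
                                seed=seed + 2, orientation=orientation)
    kf = repeated_kfold_auc(scores, labels, k=kfold_k,
                            repetitions=kfold_repetitions, seed=seed + 3,
                            orientation=orientation)
    return MarkerInference(
        marker=marker, orientation=orientation, auc=auc, delong_ci95=ci,
        cutoff=cut, sensitivity=sens, specificity=spec,
        youden=sens + spec - 1.0,
        bootstrap_B=bootstrap_B, bootstrap_ci95=boot,
        permutation_B=permutation_B, permutation_p=perm,
        holdout_repeats=holdout_repeats, holdout_range95=hold,
        kfold_repetitions=kfold_repetitions, kfold_interval95=kf,
    )
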