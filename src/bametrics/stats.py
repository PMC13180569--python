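"""Group-level descriptive statistics for bile-acid cohorts.

Thin, typed wrappers over the standard nonparametric toolkit — Kruskal–Wallis
across groups, Mann–Whitney for pairs, plain Pearson chi-squared for
categorical contrasts, Spearman rank correlation against clinical scores, and
correlation-matrix PCA of the standardized index table.  The per-index group
comparison table reports raw p-values first (the primary read-out) together
with Benjamini–Hochberg FDR across the catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "CorrelationResult",
    "PCAResult",
    "kruskal_wallis",
    "mann_whitney",
    "chi_squared_counts",
    "spearman",
    "pca_scores",
    "group_comparison_table",
]


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    df: int | None
    p: float
    groups: list[str]


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    pair: tuple[str, str] = ("x", "y")
    group: str | None = None


@dataclass
class PCAResult:
    loadings: np.ndarray                 # (n_features, n_components), orthonormal
    scores: np.ndarray                   # (n_subjects, n_components)
    explained_variance_ratio: np.ndarray


def kruskal_wallis(groups: dict[str, np.ndarray] | list) -> GroupTestResult:
    """Kruskal–Wallis H on mid-ranks with tie correction.

    All-tied data (zero rank variance) returns H = 0, p = 1 by convention.
    """
    if isinstance(groups, dict):
        names = list(groups.keys())
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        names = [f"group{i}" for i in range(len(groups))]
        samples = [np.asarray(v, dtype=float) for v in groups]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for nm, s in zip(names, samples):
        if len(s) == 0:
            raise ValueError(f"empty group: {nm}")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return GroupTestResult("kruskal_wallis", 0.0, len(samples) - 1, 1.0, names)
    stat, p = stats.kruskal(*samples)
    return GroupTestResult("kruskal_wallis", float(stat), len(samples) - 1, float(p), names)


def mann_whitney(x, y, names: tuple[str, str] = ("a", "b")) -> GroupTestResult:
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return GroupTestResult("mann_whitney", float(stat), None, float(p), list(names))


def chi_squared_counts(table: np.ndarray, names: list[str] | None = None) -> GroupTestResult:
    """Pearson chi-squared on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    stat, p, df, _exp = stats.chi2_contingency(table, correction=False)
    return GroupTestResult("chi_squared", float(stat), int(df), float(p),
                           names or [])


def spearman(x, y, pair: tuple[str, str] = ("x", "y"),
             group: str | None = None) -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(float("nan"), float("nan"), len(x), pair, group)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), len(x), pair, group)


def pca_scores(X: pd.DataFrame | np.ndarray, n_components: int = 2) -> PCAResult:
    """PCA of a centred/standardized matrix; components truncated to rank."""
    M = np.asarray(X, dtype=float)
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 features")
    rank = min(M.shape[0] - 1, M.shape[1])
    k = min(n_components, rank)
    if k < n_components:
        import warnings
        warnings.warn(f"n_components truncated to rank {k}", UserWarning, stacklevel=2)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(M)
    return PCAResult(loadings=pca.components_.T, scores=scores,
                     explained_variance_ratio=pca.explained_variance_ratio_)


def group_comparison_table(
    features: pd.DataFrame, labels: pd.Series, groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-index Kruskal–Wallis across groups, with BH-FDR across the catalogue.

    Missing cells are dropped pairwise per index; indices with an empty group
    after deletion are reported with NaN statistics.
    """
    if groups is None:
        groups = sorted(pd.unique(labels).tolist())
    rows = []
    for col in features.columns:
        samples = {}
        degenerate = False
        for g in groups:
            v = features.loc[labels == g, col].dropna().to_numpy()
            if len(v) == 0:
                degenerate = True
            samples[g] = v
        if degenerate:
            rows.append({"index": col, "H": np.nan, "p_raw": np.nan})
            continue
        res = kruskal_wallis(samples)
        rows.append({"index": col, "H": res.statistic, "p_raw": res.p})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_fdr"] = np.nan
    if ok.any():
        _rej, fdr, _a, _b = multipletests(out.loc[ok, "p_raw"], method="fdr_bh")
        out.loc[ok, "p_fdr"] = fdr
    return out
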