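"""Clinical-utility statistics: decision curves, reclassification, model ranking.

Decision-curve analysis evaluates the net benefit of acting on a model at a
decision threshold p_t,

    NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t),

against the treat-all and treat-none policies.  Reclassification against a
baseline model uses the category-free (continuous) NRI — no risk categories
are defined for this panel — and the IDI (change in mean discrimination
slope).  Global model comparison uses the Friedman rank test over a
model × block AUC matrix followed, when significant, by Holm-adjusted paired
t-tests on paired bootstrap AUC samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NetBenefitCurve",
    "ReclassificationResult",
    "ModelComparison",
    "decision_curve",
    "nri_continuous",
    "idi",
    "friedman_with_holm",
]


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "net_benefit": self.net_benefit,
            "treat_all": self.treat_all,
            "treat_none": self.treat_none,
        })


def decision_curve(probabilities, labels01, thresholds=None) -> NetBenefitCurve:
    """Net-benefit curve with the rule "positive if probability >= p_t".

    The default grid is 0.01 … 0.99 in steps of 0.01; p_t = 1 is excluded
    (the weight p_t/(1-p_t) diverges).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels01, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.00, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1.0) or np.any(thresholds <= 0.0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prevalence = float(y.mean())
    w = thresholds / (1.0 - thresholds)

    pred = p[None, :] >= thresholds[:, None]          # (T, n)
    tp = (pred & (y == 1)[None, :]).sum(axis=1) / n
    fp = (pred & (y == 0)[None, :]).sum(axis=1) / n
    nb = tp - fp * w
    treat_all = prevalence - (1.0 - prevalence) * w
    return NetBenefitCurve(thresholds=thresholds, net_benefit=nb,
                           treat_all=treat_all,
                           treat_none=np.zeros_like(thresholds),
                           prevalence=prevalence)


@dataclass
class ReclassificationResult:
    nri_overall: float
    nri_event: float
    nri_nonevent: float
    idi: float
    baseline: str = "baseline"
    comparator: str = "comparator"


def _check_reclass_inputs(old_probs, new_probs, labels01):
    old = np.asarray(old_probs, dtype=float)
    new = np.asarray(new_probs, dtype=float)
    y = np.asarray(labels01, dtype=int)
    if not (old.shape == new.shape == y.shape):
        raise ValueError("probability vectors and labels must align")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("need at least one event and one non-event")
    return old, new, y


def nri_continuous(old_probs, new_probs, labels01,
                   baseline: str = "baseline",
                   comparator: str = "comparator") -> ReclassificationResult:
    """Category-free NRI of ``new`` over ``old``.

    event NRI     = P(new > old | event)     - P(new < old | event)
    non-event NRI = P(new < old | non-event) - P(new > old | non-event)
    overall       = event NRI + non-event NRI   (each component in [-1, 1])
    """
    old, new, y = _check_reclass_inputs(old_probs, new_probs, labels01)
    up = new > old
    down = new < old
    ev = y == 1
    nev = y == 0
    nri_event = float(up[ev].mean() - down[ev].mean())
    nri_nonevent = float(down[nev].mean() - up[nev].mean())
    return ReclassificationResult(
        nri_overall=nri_event + nri_nonevent,
        nri_event=nri_event, nri_nonevent=nri_nonevent,
        idi=idi(old, new, y), baseline=baseline, comparator=comparator,
    )


def idi(old_probs, new_probs, labels01) -> float:
    """Integrated discrimination improvement: change in discrimination slope."""
    old, new, y = _check_reclass_inputs(old_probs, new_probs, labels01)
    ev, nev = y == 1, y == 0
    slope_new = new[ev].mean() - new[nev].mean()
    slope_old = old[ev].mean() - old[nev].mean()
    return float(slope_new - slope_old)


@dataclass
class ModelComparison:
    friedman_statistic: float
    friedman_p: float
    pairwise: pd.DataFrame | None  # columns: model_a, model_b, t, p_raw, p_holm
    alpha: float = 0.05


def friedman_with_holm(
    auc_matrix: pd.DataFrame,
    boot_pairs: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> ModelComparison:
    """Friedman rank test over a models × blocks AUC matrix, Holm post hoc.

    Rows are models, columns blocks (CV folds or bootstrap draws); ties take
    average ranks.  When the global test is significant, all pairwise paired
    t-tests are run on ``boot_pairs`` (models × paired bootstrap AUC samples;
    defaults to the AUC matrix itself) and Holm-adjusted.
    A constant matrix short-circuits to statistic 0, p 1, no post hoc.
    """
    M = np.asarray(auc_matrix, dtype=float)
    if M.shape[0] < 3:
        raise ValueError("Friedman test needs >= 3 models")
    if M.shape[1] < 2:
        raise ValueError("Friedman test needs >= 2 blocks")
    models = list(auc_matrix.index)

    if np.allclose(M, M[0:1, :]):
        return ModelComparison(0.0, 1.0, None, alpha)

    stat, p = stats.friedmanchisquare(*[M[i] for i in range(M.shape[0])])
    pairwise = None
    if p < alpha:
        source = boot_pairs if boot_pairs is not None else auc_matrix
        S = np.asarray(source, dtype=float)
        snames = list(source.index)
        rows = []
        for i in range(len(snames)):
            for j in range(i + 1, len(snames)):
                diff = S[i] - S[j]
                if np.allclose(diff, 0.0):
                    t, pr = 0.0, 1.0
                else:
                    t, pr = stats.ttest_rel(S[i], S[j])
                rows.append({"model_a": snames[i], "model_b": snames[j],
                             "t": float(t), "p_raw": float(pr)})
        pairwise = pd.DataFrame(rows)
        _rej, p_holm, _a, _b = multipletests(pairwise["p_raw"], method="holm")
        pairwise["p_holm"] = p_holm
    return ModelComparison(float(stat), float(p), pairwise, alpha)
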