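"""Imputation quality metrics: NRMSE, reference calls, confusion, ROC/AUC.

NRMSE is the root mean squared difference between imputed and true
values over the masked cells, normalized by the sample variance of the
true masked values, making it independent of the data scale. ROC/AUC
measures how well significance calls on an imputed dataset recover the
calls made on the complete data.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .matrix import IntensityMatrix
from .missingness import CellMask
from .stats import adjust_fdr, t_test_per_protein


def nrmse(complete: IntensityMatrix, imputed: IntensityMatrix, mask: CellMask) -> float:
    """sqrt(mean squared error / sample variance of true values), masked cells only.

    Returns NaN (undefined-result marker) when the true masked values
    have zero variance; raises with fewer than 2 masked cells.
    """
    if complete.shape != imputed.shape or mask.status.shape != complete.shape:
        raise ValueError("complete, imputed and mask must be congruent")
    cells = mask.missing_mask
    n = int(cells.sum())
    if n < 2:
        raise ValueError(f"NRMSE needs >= 2 masked cells, got {n}")
    truth = complete.values[cells]
    est = imputed.values[cells]
    var = float(truth.var(ddof=1))
    if var == 0.0:
        return float("nan")
    return float(np.sqrt(np.mean((est - truth) ** 2) / var))


def reference_calls(complete: IntensityMatrix, group_a: str, group_b: str,
                    fdr_threshold: float = 0.05) -> np.ndarray:
    """Significance labels from the complete data: BH-adjusted p <= threshold."""
    tt = t_test_per_protein(complete, group_a, group_b)
    p_adj = adjust_fdr(tt["p"].to_numpy())
    return p_adj <= fdr_threshold


def confusion_counts(reference: np.ndarray, imputed_calls: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) of imputed-data calls against reference labels."""
    ref = np.asarray(reference, dtype=bool)
    imp = np.asarray(imputed_calls, dtype=bool)
    if ref.shape != imp.shape:
        raise ValueError("label vectors must have equal length")
    tp = int((ref & imp).sum())
    fp = int((~ref & imp).sum())
    tn = int((~ref & ~imp).sum())
    fn = int((ref & ~imp).sum())
    return tp, fp, tn, fn


def roc_auc(reference: np.ndarray, scores: np.ndarray):
    """ROC points and AUC; higher score = more significant.

    AUC via the rank (Mann-Whitney) formulation with mid-rank tie
    handling; ROC points from a threshold sweep over the distinct
    scores. A single-class reference yields ``(points, nan)`` as an
    undefined-result marker.
    """
    ref = np.asarray(reference, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if ref.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int(ref.sum())
    n_neg = ref.size - n_pos

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    points = []
    for thr in thresholds:
        pred = s >= thr
        tp = int((ref & pred).sum())
        fp = int((~ref & pred).sum())
        fpr = fp / n_neg if n_neg else float("nan")
        tpr = tp / n_pos if n_pos else float("nan")
        points.append((float(thr), fpr, tpr))

    if n_pos == 0 or n_neg == 0:
        return points, float("nan")
    ranks = rankdata(s)  # mid-ranks for ties
    auc = (ranks[ref].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return points, float(auc)
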