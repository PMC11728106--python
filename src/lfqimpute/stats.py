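"""Differential-abundance statistics and transformations.

Log2 transform, minimum-presence filtering, per-protein two-sample
Student t-tests, Benjamini-Hochberg FDR adjustment, fold changes,
significance calls at FDR/fold-change thresholds, and a PCA-based group
separation score.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .matrix import LOG2, RAW, IntensityMatrix


# ---------------------------------------------------------------------------
# transforms and filters
# ---------------------------------------------------------------------------

def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """log2 of observed cells; missing cells stay missing."""
    if m.scale != RAW:
        raise ValueError("matrix is already on the log2 scale")
    bad = np.argwhere(~np.isnan(m.values) & (m.values <= 0))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"nonpositive observed value at row {i} ({m.protein_ids[i]}), "
            f"column {j} ({m.sample_ids[j]}): {m.values[i, j]}"
        )
    with np.errstate(invalid="ignore"):
        return m.with_values(np.log2(m.values), scale=LOG2)


def filter_min_presence(m: IntensityMatrix, min_fraction: float = 0.5) -> IntensityMatrix:
    """Keep proteins observed in at least ``ceil(min_fraction * n_samples)`` samples."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    need = math.ceil(min_fraction * m.n_samples)
    keep = np.flatnonzero((~m.missing_mask).sum(axis=1) >= need)
    return m.subset_rows(keep)


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def t_test_per_protein(m: IntensityMatrix, group_a: str, group_b: str,
                       equal_var: bool = True) -> pd.DataFrame:
    """Two-sided two-sample t-test per protein (pooled variance by default).

    Returns a DataFrame indexed by protein id with columns ``t``, ``p``
    and ``degenerate`` (True where the pooled variance is zero, in which
    case t=0, p=1).
    """
    if not m.is_complete:
        raise ValueError("t-test requires a complete (imputed) matrix")
    ia, ib = m.group_columns(group_a), m.group_columns(group_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both groups need >= 2 samples")
    a, b = m.values[:, ia], m.values[:, ib]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame({"t": t, "p": p, "degenerate": degenerate}, index=m.protein_ids)


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(m: IntensityMatrix, group_a: str, group_b: str) -> np.ndarray:
    """Per-protein log2 fold change of group_b relative to group_a.

    On the log2 scale: difference of group means. On the raw scale:
    log2 of the ratio of group means (errors if a group mean is
    nonpositive, which can happen after raw-scale imputation).
    """
    if not m.is_complete:
        raise ValueError("fold change requires a complete matrix")
    ia, ib = m.group_columns(group_a), m.group_columns(group_b)
    mean_a = m.values[:, ia].mean(axis=1)
    mean_b = m.values[:, ib].mean(axis=1)
    if m.scale == LOG2:
        return mean_b - mean_a
    bad = np.flatnonzero((mean_a <= 0) | (mean_b <= 0))
    if bad.size:
        raise ValueError(
            f"nonpositive raw-scale group mean for protein "
            f"{m.protein_ids[int(bad[0])]}; log2 fold change undefined"
        )
    return np.log2(mean_b / mean_a)


@dataclass
class DifferentialResult:
    """Per-protein differential-abundance table."""

    table: pd.DataFrame  # columns: t, p, p_adjusted, log2_fc, significant

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def call_significant(p_adjusted: np.ndarray, log2_fc: np.ndarray | None = None,
                     fdr_threshold: float = 0.05,
                     fc_threshold: float | None = None) -> np.ndarray:
    """Flag proteins at adjusted p <= FDR and, optionally, |log2FC| >= log2(FC)."""
    flags = np.asarray(p_adjusted) <= fdr_threshold
    if fc_threshold is not None:
        if log2_fc is None:
            raise ValueError("fc_threshold given but no fold changes supplied")
        flags = flags & (np.abs(np.asarray(log2_fc)) >= np.log2(fc_threshold))
    return flags


def differential_analysis(m: IntensityMatrix, group_a: str, group_b: str,
                          fdr_threshold: float = 0.05,
                          fc_threshold: float | None = None,
                          equal_var: bool = True) -> DifferentialResult:
    """t-test + BH adjustment + fold change + significance calls in one table."""
    tt = t_test_per_protein(m, group_a, group_b, equal_var=equal_var)
    p_adj = adjust_fdr(tt["p"].to_numpy())
    fc = fold_change(m, group_a, group_b)
    sig = call_significant(p_adj, fc, fdr_threshold, fc_threshold)
    table = pd.DataFrame(
        {
            "t": tt["t"].to_numpy(),
            "p": tt["p"].to_numpy(),
            "p_adjusted": p_adj,
            "log2_fc": fc,
            "significant": sig,
        },
        index=m.protein_ids,
    )
    return DifferentialResult(table)


# ---------------------------------------------------------------------------
# PCA separation
# ---------------------------------------------------------------------------

def pca_group_separation(m: IntensityMatrix, significant_rows: np.ndarray):
    """Silhouette score of the group labelling in the first two PCs.

    PCA is run on the column-standardized significant-protein submatrix
    with samples as points. Returns ``(coordinates, silhouette)``;
    silhouette lies in [-1, 1], higher = better group separation.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score
    from sklearn.preprocessing import StandardScaler

    significant_rows = np.asarray(significant_rows)
    if significant_rows.dtype == bool:
        significant_rows = np.flatnonzero(significant_rows)
    if significant_rows.size < 2:
        raise ValueError("need >= 2 significant proteins for PCA separation")
    if len(set(m.group_labels)) < 2:
        raise ValueError("need >= 2 groups for a separation score")
    if not m.is_complete:
        raise ValueError("PCA separation requires a complete matrix")

    sub = m.values[significant_rows]          # proteins x samples
    pts = sub.T                               # samples as points
    with np.errstate(invalid="ignore"):
        pts = StandardScaler().fit_transform(pts)
    pts = np.nan_to_num(pts)                  # zero-variance proteins -> 0
    coords = PCA(n_components=2, svd_solver="full").fit_transform(pts)
    score = float(silhouette_score(coords, m.group_labels))
    return coords, score
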