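"""Local-similarity imputers: kNN, LLS, LSA and iterative random forest.

All four exploit protein-protein (and, for LSA, sample-sample)
correlation: a missing cell is predicted from proteins whose intensity
profiles resemble the target's.
"""
from __future__ import annotations

import numpy as np

from ..matrix import IntensityMatrix
from .base import ImputationResult, ImputerConfig, finish, validate_input


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _pairwise_distances(X: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Partial Euclidean row distances, scaled by sqrt(p / n_shared).

    Distance is computed over the columns observed in both rows and
    inflated by the share of columns actually compared; rows with no
    shared observed column are infinitely far apart.
    """
    p = X.shape[1]
    A = np.where(obs, X, 0.0)
    M = obs.astype(float)
    sq = (A * A) @ M.T
    d2 = sq + sq.T - 2.0 * (A @ A.T)
    shared = M @ M.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(shared > 0, np.maximum(d2, 0.0) * p / shared, np.inf)
    return np.sqrt(d2)


def _corr_with_row(X: np.ndarray, obs: np.ndarray, i: int) -> np.ndarray:
    """Pairwise-complete Pearson correlation of row ``i`` with every row.

    NaN where fewer than 2 shared columns or either side has zero
    variance on the shared columns.
    """
    sh = obs & obs[i]
    cnt = sh.sum(axis=1).astype(float)
    Xi = np.where(sh, X[i], 0.0)
    Xr = np.where(sh, X, 0.0)
    si, sr = Xi.sum(axis=1), Xr.sum(axis=1)
    sii, srr = (Xi * Xi).sum(axis=1), (Xr * Xr).sum(axis=1)
    sir = (Xi * Xr).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sir - si * sr / cnt
        vi = sii - si * si / cnt
        vr = srr - sr * sr / cnt
        corr = cov / np.sqrt(vi * vr)
    corr[(cnt < 2) | ~np.isfinite(corr)] = np.nan
    return corr


# ---------------------------------------------------------------------------
# kNN
# ---------------------------------------------------------------------------

def impute_knn(m: IntensityMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    """Inverse-distance-weighted mean over the k nearest protein rows.

    Neighbours must have the target column observed; ties in distance
    are broken by row index; zero-distance neighbours dominate via a
    simple mean over them.
    """
    cfg = cfg or ImputerConfig()
    validate_input(m)
    k = cfg.resolved_k("knn")
    X = m.values
    obs = ~m.missing_mask
    filled = X.copy()
    if not m.missing_mask.any():
        return finish(m, filled, "kNN", cfg)

    D = _pairwise_distances(X, obs)
    np.fill_diagonal(D, np.inf)
    col_means = np.nansum(np.where(obs, X, 0.0), axis=0) / np.maximum(obs.sum(axis=0), 1)

    for i in np.flatnonzero(m.missing_mask.any(axis=1)):
        order = np.argsort(D[i], kind="stable")  # stable => ties by row index
        for j in np.flatnonzero(m.missing_mask[i]):
            cand = order[obs[order, j] & np.isfinite(D[i, order])]
            if cand.size == 0:
                filled[i, j] = col_means[j]
                continue
            chosen = cand[:k]
            d = D[i, chosen]
            if (d == 0).any():
                filled[i, j] = X[chosen[d == 0], j].mean()
            else:
                w = 1.0 / d
                filled[i, j] = float(np.dot(w, X[chosen, j]) / w.sum())
    return finish(m, filled, "kNN", cfg)


# ---------------------------------------------------------------------------
# LLS
# ---------------------------------------------------------------------------

def impute_lls(m: IntensityMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    """Local least squares on the k most-correlated protein rows.

    For each incomplete row, candidate neighbours (ranked by absolute
    pairwise-complete Pearson correlation) must be observed at the
    target's missing columns; the target's observed values are regressed
    on the neighbours' values at those columns (minimum-norm solution
    when rank-deficient, neighbour gaps pre-filled with row means) and
    the fit predicts the missing cells.
    """
    cfg = cfg or ImputerConfig()
    validate_input(m)
    k = cfg.resolved_k("lls")
    X = m.values
    obs = ~m.missing_mask
    filled = X.copy()
    if not m.missing_mask.any():
        return finish(m, filled, "LLS", cfg)

    row_means = np.nanmean(X, axis=1)
    design_full = np.where(obs, X, row_means[:, None])

    for i in np.flatnonzero(m.missing_mask.any(axis=1)):
        mis = np.flatnonzero(m.missing_mask[i])
        o = np.flatnonzero(obs[i])
        corr = _corr_with_row(X, obs, i)
        corr[i] = np.nan
        usable = np.flatnonzero(~np.isnan(corr) & obs[:, mis].all(axis=1))
        if usable.size == 0 or o.size == 0:
            filled[i, mis] = row_means[i]
            continue
        ranked = usable[np.argsort(-np.abs(corr[usable]), kind="stable")]
        neigh = ranked[: min(k, ranked.size)]
        D = design_full[neigh][:, o].T          # |o| x k design
        y = X[i, o]
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        filled[i, mis] = X[neigh][:, mis].T @ coef
    return finish(m, filled, "LLS", cfg)


# ---------------------------------------------------------------------------
# LSA
# ---------------------------------------------------------------------------

def _simple_fit(x: np.ndarray, z: np.ndarray) -> tuple[float, float] | None:
    """Least-squares line x ~ a + b z; None when degenerate."""
    if x.size < 2:
        return None
    vz = z.var()
    if vz == 0:
        return None
    b = float(np.cov(z, x, ddof=0)[0, 1] / vz)
    a = float(x.mean() - b * z.mean())
    return a, b


def _protein_estimates(X: np.ndarray, obs: np.ndarray,
                       cells: np.ndarray) -> np.ndarray:
    """Protein-based estimate for each (row, col) cell.

    Regression of the target row on its single most-correlated protein
    row that is observed at the cell's column; falls back to the target
    row's observed mean when no usable neighbour exists.
    """
    est = np.empty(len(cells))
    row_means = np.nanmean(np.where(obs, X, np.nan), axis=1)
    by_row: dict[int, list[int]] = {}
    for pos, (i, j) in enumerate(cells):
        by_row.setdefault(int(i), []).append(pos)
    for i, positions in by_row.items():
        corr = _corr_with_row(X, obs, i)
        corr[i] = np.nan
        valid = np.flatnonzero(~np.isnan(corr))
        ranked = valid[np.argsort(-np.abs(corr[valid]), kind="stable")]
        for pos in positions:
            j = int(cells[pos][1])
            est[pos] = row_means[i]
            for r in ranked:
                if not obs[r, j]:
                    continue
                both = obs[i] & obs[r]
                fit = _simple_fit(X[i, both], X[r, both])
                if fit is not None:
                    a, b = fit
                    est[pos] = a + b * X[r, j]
                break
            # only the best observed neighbour is consulted; degenerate
            # fits fall back to the row mean
    return est


def _sample_estimates(X: np.ndarray, obs: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Sample-based estimate: same procedure on the transposed matrix."""
    swapped = cells[:, ::-1] if len(cells) else cells
    return _protein_estimates(X.T, obs.T, swapped)


def impute_lsa(m: IntensityMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    """Adaptive least squares: mix protein- and sample-based estimates.

    Each missing cell gets a protein-based estimate g (regression on the
    most-correlated protein) and a sample-based estimate a (regression
    on the most-correlated sample). The global mixing weight w in [0, 1]
    of the returned w*g + (1-w)*a minimizes squared error on a seeded
    holdout of temporarily re-masked observed cells (default 5%).
    """
    cfg = cfg or ImputerConfig()
    validate_input(m)
    X = m.values
    obs = ~m.missing_mask
    filled = X.copy()
    if not m.missing_mask.any():
        return finish(m, filled, "LSA", cfg, details={"w": 0.5})

    rng = np.random.default_rng(cfg.seed)
    obs_cells = np.argwhere(obs)
    n_hold = max(1, int(round(cfg.holdout_fraction * len(obs_cells))))
    sel = rng.choice(len(obs_cells), size=min(n_hold, len(obs_cells)), replace=False)
    hold = obs_cells[sel]

    Xh = X.copy()
    Xh[hold[:, 0], hold[:, 1]] = np.nan
    # keep every row/column with >=1 observed cell in the holdout matrix
    obs_h = ~np.isnan(Xh)
    keep = np.ones(len(hold), dtype=bool)
    for idx, (i, j) in enumerate(hold):
        if obs_h[i].sum() == 0 or obs_h[:, j].sum() == 0:
            Xh[i, j] = X[i, j]
            obs_h = ~np.isnan(Xh)
            keep[idx] = False
    hold = hold[keep]

    w = 0.5
    if len(hold):
        g_h = _protein_estimates(Xh, obs_h, hold)
        a_h = _sample_estimates(Xh, obs_h, hold)
        truth = X[hold[:, 0], hold[:, 1]]
        den = float(((g_h - a_h) ** 2).sum())
        if den > 0:
            w = float(np.clip(((g_h - a_h) * (truth - a_h)).sum() / den, 0.0, 1.0))

    mis_cells = np.argwhere(m.missing_mask)
    g = _protein_estimates(X, obs, mis_cells)
    a = _sample_estimates(X, obs, mis_cells)
    filled[mis_cells[:, 0], mis_cells[:, 1]] = w * g + (1.0 - w) * a
    return finish(m, filled, "LSA", cfg, details={"w": w})


# ---------------------------------------------------------------------------
# RF (missForest-style)
# ---------------------------------------------------------------------------

def _rf_seed(seed: int, sweep: int, col: int) -> int:
    return int(np.random.SeedSequence((seed, sweep, col)).generate_state(1)[0] % (2**31))


def impute_rf(m: IntensityMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    """Iterative random-forest regression imputation.

    Missing cells start at column means; columns are visited in order of
    increasing missingness, each regressed on all other columns with a
    seeded random forest (``ntree`` trees) fitted on its observed rows.
    Full sweeps repeat until the normalized sum of squared changes in
    the imputed values first increases, at which point the previous
    sweep's matrix is returned (or until ``max_iter``).
    """
    from sklearn.ensemble import RandomForestRegressor

    cfg = cfg or ImputerConfig()
    validate_input(m)
    miss = m.missing_mask
    if not miss.any():
        return finish(m, m.values.copy(), "RF", cfg, n_iterations=0)

    X = m.values
    obs_counts = (~miss).sum(axis=0)
    col_means = np.where(obs_counts > 0,
                         np.nansum(np.where(miss, 0.0, X), axis=0) / np.maximum(obs_counts, 1),
                         0.0)
    cur = np.where(miss, col_means[None, :], X)
    cols = np.flatnonzero(miss.any(axis=0))
    cols = cols[np.argsort(miss.sum(axis=0)[cols], kind="stable")]

    prev_diff = np.inf
    n_sweeps = 0
    for sweep in range(1, cfg.max_iter + 1):
        before = cur.copy()
        for j in cols:
            train = ~miss[:, j]
            others = np.delete(np.arange(X.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=cfg.ntree,
                random_state=_rf_seed(cfg.seed, sweep, int(j)),
                n_jobs=1,
            )
            rf.fit(cur[train][:, others], X[train, j])
            cur[miss[:, j], j] = rf.predict(cur[miss[:, j]][:, others])
        n_sweeps = sweep
        num = float(((cur - before)[miss] ** 2).sum())
        den = float((cur[miss] ** 2).sum())
        diff = num / den if den > 0 else 0.0
        if diff > prev_diff:
            cur = before  # criterion rose: keep the previous sweep's result
            break
        if diff == 0.0:
            break
        prev_diff = diff
    return finish(m, cur, "RF", cfg, n_iterations=n_sweeps)
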