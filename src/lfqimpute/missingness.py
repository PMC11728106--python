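"""Controlled injection of missing values into complete intensity matrices.

Two mechanisms mimic how label-free proteomics data lose cells:

* ``hard_censor`` (default): the MNAR portion is the set of lowest-intensity
  cells of the whole matrix (deterministic left-censoring below an implied
  detection limit), the MAR portion is drawn uniformly from the remainder.
* ``probabilistic``: MNAR cells are sampled without replacement with
  probability proportional to exp(-gamma * r), r being the cell's intensity
  rank fraction, so low-abundance cells are strongly but not deterministically
  favoured.

Every masked cell is labelled MAR or MNAR so downstream evaluation can
stratify by mechanism. A row guard keeps at least ``min_observed_per_row``
cells per protein, redrawing offending assignments, because most imputers
cannot handle an all-missing protein.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import IntensityMatrix

OBSERVED = 0
MAR = 1
MNAR = 2

_MECHANISMS = ("hard_censor", "probabilistic")
STATUS_NAMES = {OBSERVED: "OBSERVED", MAR: "MAR", MNAR: "MNAR"}


@dataclass
class MissingnessSpec:
    """Total missing share ``alpha`` and MNAR share ``beta`` of the missing."""

    alpha: float
    beta: float
    mechanism: str = "hard_censor"
    min_observed_per_row: int = 1
    gamma: float = 10.0
    seed: int = 0
    max_retries: int = 100

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"mechanism must be one of {_MECHANISMS}")
        if self.min_observed_per_row < 0:
            raise ValueError("min_observed_per_row must be >= 0")


@dataclass
class CellMask:
    """Per-cell status grid: OBSERVED (0), MAR (1) or MNAR (2)."""

    status: np.ndarray

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if not np.isin(self.status, (OBSERVED, MAR, MNAR)).all():
            raise ValueError("mask status codes must be OBSERVED/MAR/MNAR")

    @property
    def missing_mask(self) -> np.ndarray:
        return self.status != OBSERVED

    @property
    def n_mar(self) -> int:
        return int((self.status == MAR).sum())

    @property
    def n_mnar(self) -> int:
        return int((self.status == MNAR).sum())

    @property
    def n_missing(self) -> int:
        return self.n_mar + self.n_mnar


@dataclass
class MaskedDataset:
    """Complete matrix, its mask, and the resulting observed matrix."""

    complete: IntensityMatrix
    mask: CellMask
    observed: IntensityMatrix
    spec: MissingnessSpec | None = None

    def __post_init__(self) -> None:
        if self.mask.status.shape != self.complete.shape:
            raise ValueError("mask shape must match matrix shape")
        miss = self.mask.missing_mask
        obs_vals = self.observed.values
        if not np.array_equal(np.isnan(obs_vals), miss):
            raise ValueError("observed matrix must be missing exactly at masked cells")
        if not np.array_equal(obs_vals[~miss], self.complete.values[~miss]):
            raise ValueError("observed matrix must equal complete at OBSERVED cells")


def _counts(alpha: float, beta: float, n_cells: int) -> tuple[int, int, int]:
    n_mis = int(round(alpha * n_cells))
    n_mnar = int(round(beta * n_mis))
    return n_mis, n_mnar, n_mis - n_mnar


def apply_missingness(complete: IntensityMatrix, spec: MissingnessSpec) -> MaskedDataset:
    """Mask ``round(alpha*N)`` cells of a complete matrix, labelling each MAR/MNAR.

    Deterministic given ``spec.seed``. Raises if the input already has
    missing cells or if ``alpha`` is infeasible under the row guard.
    """
    spec.validate()
    if not complete.is_complete:
        raise ValueError("input matrix already contains missing cells")

    n_rows, n_cols = complete.shape
    n_cells = n_rows * n_cols
    n_mis, n_mnar, n_mar = _counts(spec.alpha, spec.beta, n_cells)
    guard = spec.min_observed_per_row
    max_mask_per_row = n_cols - guard
    if max_mask_per_row < 0 or n_mis > n_rows * max_mask_per_row:
        raise ValueError(
            f"alpha={spec.alpha} cannot keep {guard} observed cell(s) in every row"
        )

    rng = np.random.default_rng(spec.seed)
    flat = complete.values.ravel()
    order = np.argsort(flat, kind="stable")  # ascending intensity, ties by index

    status = np.zeros(n_cells, dtype=np.int8)
    if spec.mechanism == "hard_censor":
        status[order[:n_mnar]] = MNAR
    else:
        ranks = np.empty(n_cells, dtype=float)
        ranks[order] = np.arange(n_cells)
        r = ranks / max(n_cells - 1, 1)
        w = np.exp(-spec.gamma * r)
        if n_mnar:
            idx = rng.choice(n_cells, size=n_mnar, replace=False, p=w / w.sum())
            status[idx] = MNAR
    if n_mar:
        remainder = np.flatnonzero(status == OBSERVED)
        status[rng.choice(remainder, size=n_mar, replace=False)] = MAR

    if guard > 0:
        status = _enforce_row_guard(status, flat, n_rows, n_cols, spec, rng)

    grid = status.reshape(n_rows, n_cols)
    observed_values = complete.values.copy()
    observed_values[grid != OBSERVED] = np.nan
    return MaskedDataset(
        complete=complete,
        mask=CellMask(grid),
        observed=complete.with_values(observed_values),
        spec=spec,
    )


def _enforce_row_guard(status: np.ndarray, flat: np.ndarray, n_rows: int,
                       n_cols: int, spec: MissingnessSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Redraw MAR/MNAR assignments for rows left with too few observed cells."""
    guard = spec.min_observed_per_row
    max_mask_per_row = n_cols - guard
    for _ in range(spec.max_retries):
        grid = status.reshape(n_rows, n_cols)
        obs_per_row = (grid == OBSERVED).sum(axis=1)
        bad_rows = np.flatnonzero(obs_per_row < guard)
        if bad_rows.size == 0:
            return status
        freed = {MAR: 0, MNAR: 0}
        for row in bad_rows:
            deficit = guard - obs_per_row[row]
            cols = np.arange(n_cols)
            # free MAR cells first (random), then MNAR cells of highest
            # intensity, to preserve the left-censored character
            mar_cols = cols[grid[row] == MAR]
            rng.shuffle(mar_cols)
            mnar_cols = cols[grid[row] == MNAR]
            mnar_cols = mnar_cols[np.argsort(-flat[row * n_cols + mnar_cols], kind="stable")]
            for col in np.concatenate([mar_cols, mnar_cols])[:deficit]:
                freed[int(grid[row, col])] += 1
                grid[row, col] = OBSERVED
        # reassign freed labels to eligible cells elsewhere, one at a time
        for label, n_free in ((MNAR, freed[MNAR]), (MAR, freed[MAR])):
            for _k in range(n_free):
                masked_per_row = (grid != OBSERVED).sum(axis=1)
                room = masked_per_row < max_mask_per_row
                eligible = np.flatnonzero(
                    (status == OBSERVED) & np.repeat(room, n_cols)
                )
                if eligible.size == 0:
                    raise ValueError(
                        f"row guard infeasible: cannot relocate a masked cell "
                        f"(first offending row {bad_rows[0]})"
                    )
                if label == MNAR and spec.mechanism == "hard_censor":
                    pick = eligible[np.argmin(flat[eligible])]
                elif label == MNAR:
                    w = np.exp(-spec.gamma * np.argsort(np.argsort(flat[eligible])) /
                               max(eligible.size - 1, 1))
                    pick = rng.choice(eligible, p=w / w.sum())
                else:
                    pick = rng.choice(eligible)
                status[pick] = label
    raise ValueError(
        f"row guard could not be satisfied within {spec.max_retries} retries "
        f"(first offending row {bad_rows[0]})"
    )


def summarize_mask(ds: MaskedDataset) -> dict:
    """Achieved rates and per-row/column missing counts of a masked dataset."""
    grid = ds.mask.status
    n_cells = grid.size
    n_missing = ds.mask.n_missing
    truth = ds.complete.values
    mnar_vals = truth[grid == MNAR]
    mar_vals = truth[grid == MAR]
    return {
        "n_cells": n_cells,
        "n_missing": n_missing,
        "n_mar": ds.mask.n_mar,
        "n_mnar": ds.mask.n_mnar,
        "achieved_alpha": n_missing / n_cells,
        "achieved_beta": ds.mask.n_mnar / n_missing if n_missing else 0.0,
        "missing_per_row": (grid != OBSERVED).sum(axis=1),
        "missing_per_column": (grid != OBSERVED).sum(axis=0),
        "mean_true_intensity_mnar": float(mnar_vals.mean()) if mnar_vals.size else np.nan,
        "mean_true_intensity_mar": float(mar_vals.mean()) if mar_vals.size else np.nan,
    }


def complete_case_subset(m: IntensityMatrix) -> IntensityMatrix:
    """Rows quantified in every sample, original order preserved."""
    keep = np.flatnonzero(~m.missing_mask.any(axis=1))
    if keep.size == 0:
        raise ValueError("no complete rows: every protein has at least one missing cell")
    return m.subset_rows(keep)
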