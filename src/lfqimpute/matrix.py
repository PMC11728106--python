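"""Protein-by-sample intensity matrix container.

The central data structure of the package: a proteins x samples grid of
positive abundances (MaxLFQ-like intensities) or their log2 transform,
with missing cells stored as NaN. Group labels assign every sample to a
comparison group (e.g. control vs treated).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

RAW = "raw"
LOG2 = "log2"
_SCALES = (RAW, LOG2)


@dataclass
class IntensityMatrix:
    """Proteins x samples abundance table.

    Parameters
    ----------
    values
        2-D float array, one row per protein, one column per sample.
        Missing cells are ``NaN``.
    protein_ids, sample_ids
        Unique row / column identifiers.
    group_labels
        One group name per sample.
    scale
        ``"raw"`` (strictly positive intensities) or ``"log2"``.
    """

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str]
    scale: str = RAW

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        self.group_labels = list(self.group_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if len(self.protein_ids) != n:
            raise ValueError(
                f"{len(self.protein_ids)} protein ids for {n} rows"
            )
        if len(self.sample_ids) != p:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {p} columns")
        if len(self.group_labels) != p:
            raise ValueError("one group label per sample required")
        if len(set(self.protein_ids)) != n:
            raise ValueError("protein ids must be unique")
        if len(set(self.sample_ids)) != p:
            raise ValueError("sample ids must be unique")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        obs = self.values[~np.isnan(self.values)]
        if np.any(np.isinf(obs)):
            raise ValueError("observed values must be finite")
        # Note: raw-scale *measured* intensities are strictly positive (the
        # generator and readers guarantee it) but imputed raw-scale matrices
        # may contain nonpositive estimates (e.g. normal-downshift draws or
        # low-rank reconstructions); positivity is therefore enforced where
        # it matters, in log2_transform.

    # -- basic geometry -------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- missingness ----------------------------------------------------
    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean grid, True where the cell is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    # -- groups ---------------------------------------------------------
    @property
    def groups(self) -> list[str]:
        """Group names in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g)
        return list(seen)

    def group_columns(self, group: str) -> np.ndarray:
        idx = np.array([i for i, g in enumerate(self.group_labels) if g == group])
        if idx.size == 0:
            raise KeyError(f"no samples in group {group!r}")
        return idx

    # -- manipulation ---------------------------------------------------
    def copy(self) -> "IntensityMatrix":
        return replace(self, values=self.values.copy())

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "IntensityMatrix":
        return replace(self, values=np.asarray(values, dtype=float),
                       scale=self.scale if scale is None else scale)

    def subset_rows(self, indices: Sequence[int] | np.ndarray) -> "IntensityMatrix":
        indices = np.asarray(indices, dtype=int)
        return replace(
            self,
            values=self.values[indices].copy(),
            protein_ids=[self.protein_ids[i] for i in indices],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)
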