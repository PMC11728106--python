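"""Shared configuration, result type and input validation for imputers."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..matrix import IntensityMatrix


@dataclass
class ImputerConfig:
    """Hyperparameters for all ten methods.

    ``k_neighbors`` and ``n_pcs`` default to ``None`` and are resolved per
    method: k = 6 (kNN) or 150 (LLS); nPCs = 4 (SVD, BPCA) or 1 (PPCA).
    """

    k_neighbors: int | None = None
    nd_shift: float = 2.2
    nd_width: float = 0.3
    nd_scope: str = "per_sample"  # or "global"
    ntree: int = 100
    n_pcs: int | None = None
    max_iter: int = 100
    tol: float = 1e-5
    holdout_fraction: float = 0.05  # LSA mixing-weight holdout
    seed: int = 0

    def resolved_k(self, method: str) -> int:
        if self.k_neighbors is not None:
            if self.k_neighbors < 1:
                raise ValueError("k_neighbors must be >= 1")
            return self.k_neighbors
        return {"knn": 6, "lls": 150}[method]

    def resolved_n_pcs(self, method: str, shape: tuple[int, int]) -> int:
        q = self.n_pcs if self.n_pcs is not None else {"svd": 4, "bpca": 4, "ppca": 1}[method]
        if q < 1:
            raise ValueError("n_pcs must be >= 1")
        if q >= min(shape):
            raise ValueError(f"n_pcs={q} must be < min(matrix dimensions)={min(shape)}")
        return q


@dataclass
class ImputationResult:
    """A fully populated matrix plus provenance of how it was produced."""

    imputed: IntensityMatrix
    method: str
    config: ImputerConfig
    runtime_seconds: float = 0.0
    n_iterations: int = 0
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.imputed.n_missing:
            raise ValueError("imputed matrix still contains missing cells")


def validate_input(m: IntensityMatrix) -> None:
    """Enforce the shared precondition: >=1 observed cell per row and column."""
    obs = ~m.missing_mask
    row_obs = obs.sum(axis=1)
    if (row_obs == 0).any():
        bad = int(np.flatnonzero(row_obs == 0)[0])
        raise ValueError(f"row {bad} ({m.protein_ids[bad]}) has no observed values")
    col_obs = obs.sum(axis=0)
    if (col_obs == 0).any():
        bad = int(np.flatnonzero(col_obs == 0)[0])
        raise ValueError(f"column {bad} ({m.sample_ids[bad]}) has no observed values")
    if np.isinf(m.values[obs]).any():
        raise ValueError("observed values must be finite")


def finish(m: IntensityMatrix, filled: np.ndarray, method: str,
           cfg: ImputerConfig, n_iterations: int = 0,
           details: dict | None = None) -> ImputationResult:
    """Assemble a result, re-imposing observed cells bit-exactly."""
    obs = ~m.missing_mask
    out = np.asarray(filled, dtype=float).copy()
    out[obs] = m.values[obs]
    return ImputationResult(
        imputed=m.with_values(out),
        method=method,
        config=cfg,
        n_iterations=n_iterations,
        details=details or {},
    )
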