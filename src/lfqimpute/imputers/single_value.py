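"""Single-value imputers: LOD, SampMin and the normal-downshift draw (ND).

These methods target left-censored missingness: a cell is assumed absent
because the protein fell below the detection limit, so it is replaced by
a low value — the global observed minimum (LOD), the protein's own
observed minimum (SampMin), or a random draw from a normal distribution
shifted into the left tail of the observed one (ND).
"""
from __future__ import annotations

import numpy as np

from ..matrix import IntensityMatrix
from .base import ImputationResult, ImputerConfig, finish, validate_input


def impute_lod(m: IntensityMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    """Every missing cell <- global minimum of all observed values."""
    cfg = cfg or ImputerConfig()
    validate_input(m)
    filled = m.values.copy()
    filled[np.isnan(filled)] = np.nanmin(m.values)
    return finish(m, filled, "LOD", cfg)


def impute_sampmin(m: IntensityMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    """Missing cell in row i <- minimum of row i's observed values."""
    cfg = cfg or ImputerConfig()
    validate_input(m)
    filled = m.values.copy()
    row_min = np.nanmin(m.values, axis=1)
    miss = np.isnan(filled)
    filled[miss] = np.broadcast_to(row_min[:, None], m.shape)[miss]
    return finish(m, filled, "SampMin", cfg)


def impute_nd(m: IntensityMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    """Random draws from a down-shifted, narrowed normal distribution.

    For each sample column (default scope), with mean mu_m and standard
    deviation sigma_m of the observed values, missing cells are drawn
    independently from Normal(mu_m - shift*sigma_m, (width*sigma_m)^2),
    with shift 2.2 and width 0.3 by default. ``cfg.nd_scope="global"``
    computes mu_m, sigma_m over the whole matrix instead. Seeded.
    """
    cfg = cfg or ImputerConfig()
    validate_input(m)
    rng = np.random.default_rng(cfg.seed)
    filled = m.values.copy()
    miss = np.isnan(filled)

    def _stats(vals: np.ndarray) -> tuple[float, float]:
        obs = vals[~np.isnan(vals)]
        mu = float(obs.mean())
        sigma = float(obs.std(ddof=1)) if obs.size > 1 else 0.0
        return mu, sigma

    if cfg.nd_scope == "global":
        mu, sigma = _stats(m.values)
        n = int(miss.sum())
        filled[miss] = rng.normal(mu - cfg.nd_shift * sigma, cfg.nd_width * sigma, size=n)
    elif cfg.nd_scope == "per_sample":
        for j in range(m.n_samples):
            col_miss = miss[:, j]
            if not col_miss.any():
                continue
            mu, sigma = _stats(m.values[:, j])
            filled[col_miss, j] = rng.normal(
                mu - cfg.nd_shift * sigma, cfg.nd_width * sigma, size=int(col_miss.sum())
            )
    else:
        raise ValueError("nd_scope must be 'per_sample' or 'global'")
    return finish(m, filled, "ND", cfg)
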