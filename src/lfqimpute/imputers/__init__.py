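"""Ten missing-value imputation methods behind one contract.

Three families, as conventionally grouped in label-free proteomics:

* single-value: LOD (global observed minimum), SampMin (per-protein
  minimum), ND (draws from a down-shifted, narrowed normal);
* local-similarity: kNN, LLS (local least squares), LSA (adaptive
  least-squares mixture), RF (iterative random-forest regression);
* global-similarity: SVD (iterative low-rank completion), PPCA
  (EM probabilistic PCA), BPCA (variational Bayesian PCA with ARD).

Contract shared by every method: the output has zero missing cells,
observed cells are preserved bit-exactly, and results are deterministic
for a fixed seed.
"""
from __future__ import annotations

import time

from .base import ImputationResult, ImputerConfig, validate_input
from .single_value import impute_lod, impute_nd, impute_sampmin
from .local import impute_knn, impute_lls, impute_lsa, impute_rf
from .lowrank import impute_bpca, impute_ppca, impute_svd

METHODS = ("LOD", "ND", "SampMin", "kNN", "LLS", "LSA", "RF", "SVD", "PPCA", "BPCA")

_DISPATCH = {
    "lod": impute_lod,
    "nd": impute_nd,
    "sampmin": impute_sampmin,
    "knn": impute_knn,
    "lls": impute_lls,
    "lsa": impute_lsa,
    "rf": impute_rf,
    "svd": impute_svd,
    "ppca": impute_ppca,
    "bpca": impute_bpca,
}


def impute(method: str, m, cfg: ImputerConfig | None = None) -> ImputationResult:
    """Dispatch to one of the ten methods by (case-insensitive) name.

    Records wall-clock runtime on the result.
    """
    key = method.lower()
    if key not in _DISPATCH:
        raise ValueError(
            f"unknown imputation method {method!r}; valid names: {', '.join(METHODS)}"
        )
    cfg = cfg or ImputerConfig()
    start = time.perf_counter()
    result = _DISPATCH[key](m, cfg)
    result.runtime_seconds = time.perf_counter() - start
    return result


__all__ = [
    "METHODS",
    "ImputerConfig",
    "ImputationResult",
    "impute",
    "impute_lod",
    "impute_nd",
    "impute_sampmin",
    "impute_knn",
    "impute_lls",
    "impute_lsa",
    "impute_rf",
    "impute_svd",
    "impute_ppca",
    "impute_bpca",
    "validate_input",
]
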