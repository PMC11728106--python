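"""Synthetic label-free quantification data generator.

Emulates the statistical structure of MaxLFQ-scale protein intensity
tables: log-normal abundances around a baseline near 2^25, two (or more)
comparison groups with replicates, a fraction of differentially expressed
proteins with a fixed |log2 fold change|, and protein-protein correlation
induced by latent factors. On the log2 scale the model is

    x_ij = b_i + sum_l lambda_il f_lj + delta_i * 1[group(j) = treated] + eps_ij

with b_i ~ N(baseline_mean, baseline_sd^2), lambda_il ~ N(0, factor_loading_sd^2),
f_lj ~ N(0, 1), eps_ij ~ N(0, noise_sd^2) and delta_i = +-log2_fc_magnitude for
differentially expressed proteins (random sign), 0 otherwise. The returned
matrix is 2^x on the raw scale, with no missing cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import RAW, IntensityMatrix


@dataclass
class SyntheticSpec:
    """Parameters of the generative model (log2 scale unless noted)."""

    n_proteins: int = 1000
    n_groups: int = 2
    replicates_per_group: int = 5
    de_fraction: float = 0.1
    log2_fc_magnitude: float = 1.0
    baseline_mean: float = 25.0
    baseline_sd: float = 3.0
    n_latent_factors: int = 5
    factor_loading_sd: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2 (t-test needs >= 2)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.log2_fc_magnitude <= 0:
            raise ValueError("log2_fc_magnitude must be positive")
        if self.baseline_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("baseline_sd and noise_sd must be positive")
        if self.n_latent_factors < 0 or self.factor_loading_sd < 0:
            raise ValueError("latent-factor settings must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.replicates_per_group

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_proteins))


@dataclass
class GroundTruth:
    """Which proteins are truly differentially expressed, and by how much."""

    de_flags: np.ndarray
    true_log2_fc: np.ndarray

    def __post_init__(self) -> None:
        self.de_flags = np.asarray(self.de_flags, dtype=bool)
        self.true_log2_fc = np.asarray(self.true_log2_fc, dtype=float)
        if self.de_flags.shape != self.true_log2_fc.shape:
            raise ValueError("de_flags and true_log2_fc must align")
        if not np.array_equal(self.de_flags, self.true_log2_fc != 0):
            raise ValueError("de_flags must be true exactly where true_log2_fc != 0")


def _sample_ids(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    if spec.n_groups == 2:
        names = ["control", "treated"]
    else:
        names = [f"group{g + 1}" for g in range(spec.n_groups)]
    labels, ids = [], []
    for g, name in enumerate(names):
        for r in range(spec.replicates_per_group):
            labels.append(name)
            ids.append(f"{name}_{r + 1}")
    return ids, labels


def generate_complete_matrix(spec: SyntheticSpec) -> tuple[IntensityMatrix, GroundTruth]:
    """Draw one complete (no missing cells) raw-scale intensity matrix.

    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_proteins, spec.n_samples

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    loadings = rng.normal(0.0, spec.factor_loading_sd, size=(n, spec.n_latent_factors))
    factors = rng.normal(0.0, 1.0, size=(spec.n_latent_factors, p))
    noise = rng.normal(0.0, spec.noise_sd, size=(n, p))

    de_idx = rng.choice(n, size=spec.n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=spec.n_de)
    delta = np.zeros(n)
    delta[de_idx] = signs * spec.log2_fc_magnitude

    sample_ids, group_labels = _sample_ids(spec)
    # DE shift applies to the second group ("treated"); any further groups
    # sit at baseline.
    treated = np.array([lab == group_labels[spec.replicates_per_group]
                        for lab in group_labels], dtype=float) if spec.n_groups >= 2 \
        else np.zeros(p)

    x = baseline[:, None] + loadings @ factors + np.outer(delta, treated) + noise

    matrix = IntensityMatrix(
        values=np.exp2(x),
        protein_ids=[f"P{i:05d}" for i in range(n)],
        sample_ids=sample_ids,
        group_labels=group_labels,
        scale=RAW,
    )
    truth = GroundTruth(de_flags=delta != 0, true_log2_fc=delta)
    return matrix, truth


def generate_observed_dataset(spec: SyntheticSpec, alpha: float = 0.5,
                              beta: float = 0.8, seed: int | None = None):
    """Complete matrix plus injected missingness in one call.

    Chains :func:`generate_complete_matrix` with
    :func:`lfqimpute.missingness.apply_missingness`; the default
    ``alpha=0.5, beta=0.8`` mimics a realistic LFQ experiment in which
    about half the cells are missing and low-abundance censoring
    dominates. ``seed`` controls the masking draw (defaults to
    ``spec.seed + 1`` so generation and masking streams differ).
    Returns ``(masked_dataset, ground_truth)``.
    """
    from .missingness import MissingnessSpec, apply_missingness

    complete, truth = generate_complete_matrix(spec)
    mask_seed = spec.seed + 1 if seed is None else seed
    ds = apply_missingness(complete, MissingnessSpec(alpha=alpha, beta=beta, seed=mask_seed))
    return ds, truth
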