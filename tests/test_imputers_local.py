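"""Local-similarity imputers: kNN, LLS, LSA, RF."""
import numpy as np
import pytest

from conftest import random_incomplete_matrix
from lfqimpute import ImputerConfig, IntensityMatrix
from lfqimpute.imputers import impute_knn, impute_lls, impute_lsa, impute_rf


def _mat(values, scale="log2"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    groups = ["a"] * (p - p // 2) + ["b"] * (p // 2)
    return IntensityMatrix(values, [f"P{i}" for i in range(n)],
                           [f"s{j}" for j in range(p)], groups, scale=scale)


# ---------------------------------------------------------------- kNN

def test_knn_identical_neighbors_reproduce_value():
    row = [10.0, 12.0, 14.0, 16.0]
    values = np.array([row] * 7, dtype=float)
    values[0, 2] = np.nan
    out = impute_knn(_mat(values), ImputerConfig(k_neighbors=6)).imputed.values
    assert out[0, 2] == pytest.approx(14.0)


def test_knn_k1_matches_bruteforce_nearest_row():
    rng = np.random.default_rng(10)
    for trial in range(5):
        m = random_incomplete_matrix(rng, n=20, p=5, missing_fraction=0.15)
        out = impute_knn(m, ImputerConfig(k_neighbors=1)).imputed.values
        X, obs = m.values, ~m.missing_mask
        p = X.shape[1]
        for i, j in np.argwhere(m.missing_mask):
            best, best_d = None, np.inf
            for r in range(X.shape[0]):
                if r == i or not obs[r, j]:
                    continue
                sh = obs[i] & obs[r]
                if not sh.any():
                    continue
                d = np.sqrt(((X[i, sh] - X[r, sh]) ** 2).sum() * p / sh.sum())
                if d < best_d:
                    best, best_d = r, d
            if best is not None:
                assert out[i, j] == pytest.approx(X[best, j]), (trial, i, j)


def test_knn_identity_when_complete():
    rng = np.random.default_rng(1)
    m = random_incomplete_matrix(rng, missing_fraction=0.0)
    assert np.array_equal(impute_knn(m).imputed.values, m.values)


# ---------------------------------------------------------------- LLS

def test_lls_recovers_exact_linear_combination():
    rng = np.random.default_rng(2)
    basis = rng.normal(size=(3, 8))
    coef = np.array([0.5, -1.2, 2.0])
    target = coef @ basis
    values = np.vstack([target, basis])  # the 3 basis rows are the neighbours
    values[0, 5] = np.nan
    out = impute_lls(_mat(values), ImputerConfig(k_neighbors=3)).imputed.values
    assert abs(out[0, 5] - (coef @ basis)[5]) < 1e-8


def test_lls_matches_normal_equations_oracle():
    rng = np.random.default_rng(3)
    for _ in range(5):
        values = rng.normal(20, 2, size=(10, 6))
        values[0, 4] = np.nan
        m = _mat(values)
        out = impute_lls(m, ImputerConfig(k_neighbors=3)).imputed.values
        # oracle: rank neighbours by |pearson r| over shared cols, solve
        # least squares via pinv of the normal equations
        obs_cols = np.array([0, 1, 2, 3, 5])
        corrs = []
        for r in range(1, 10):
            c = np.corrcoef(values[0, obs_cols], values[r, obs_cols])[0, 1]
            corrs.append((abs(c), -r))
        neigh = [-r for _, r in sorted(corrs, reverse=True)[:3]]
        D = values[np.array(neigh)][:, obs_cols].T
        y = values[0, obs_cols]
        coef = np.linalg.pinv(D.T @ D) @ D.T @ y
        expected = values[np.array(neigh), 4] @ coef
        assert out[0, 4] == pytest.approx(expected, rel=1e-6)


def test_lls_identity_when_complete():
    rng = np.random.default_rng(4)
    m = random_incomplete_matrix(rng, missing_fraction=0.0)
    assert np.array_equal(impute_lls(m).imputed.values, m.values)


# ---------------------------------------------------------------- LSA

def test_lsa_convex_combination_bounds():
    rng = np.random.default_rng(5)
    m = random_incomplete_matrix(rng, n=25, p=8, missing_fraction=0.15)
    res = impute_lsa(m, ImputerConfig(seed=1))
    assert 0.0 <= res.details["w"] <= 1.0
    assert res.imputed.n_missing == 0


def test_lsa_weight_favors_rows_under_row_correlation():
    """Strong protein-protein correlation, none between samples ->
    the protein-based estimate should dominate (w > 0.5)."""
    # rows come in near-duplicate pairs; pairs are mutually independent,
    # so no column predicts another but each row has a perfect twin
    rng = np.random.default_rng(6)
    n_pairs, p = 30, 10
    profiles = rng.normal(25, 2, size=(n_pairs, p))
    values = np.repeat(profiles, 2, axis=0) + rng.normal(0, 0.05, (2 * n_pairs, p))
    miss = rng.random(values.shape) < 0.15
    miss[:, 0] = False
    values[miss] = np.nan
    m = _mat(values)
    res = impute_lsa(m, ImputerConfig(seed=2))
    assert res.details["w"] > 0.5


def test_lsa_equal_estimates_any_weight():
    """When g == a at a cell, the mixture equals that value regardless of w."""
    values = np.array([
        [10.0, 20.0, 30.0],
        [10.0, 20.0, 30.0],
        [10.0, 20.0, np.nan],
        [10.0, 20.0, 30.0],
    ])
    out = impute_lsa(_mat(values), ImputerConfig(seed=0)).imputed.values
    assert out[2, 2] == pytest.approx(30.0, abs=1e-8)


# ---------------------------------------------------------------- RF

def test_rf_identity_when_complete():
    rng = np.random.default_rng(7)
    m = random_incomplete_matrix(rng, missing_fraction=0.0)
    res = impute_rf(m, ImputerConfig(ntree=10, seed=0))
    assert np.array_equal(res.imputed.values, m.values)
    assert res.n_iterations == 0


def test_rf_deterministic_given_seed():
    rng = np.random.default_rng(8)
    m = random_incomplete_matrix(rng, n=40, p=6, missing_fraction=0.2)
    a = impute_rf(m, ImputerConfig(ntree=20, seed=3)).imputed.values
    b = impute_rf(m, ImputerConfig(ntree=20, seed=3)).imputed.values
    assert np.array_equal(a, b)


def test_rf_beats_column_mean_on_correlated_data():
    """Median NRMSE over 10 seeds on latent-factor data (alpha=0.25,
    beta=0) is no worse for RF than for plain column-mean imputation."""
    from lfqimpute import (MissingnessSpec, SyntheticSpec, apply_missingness,
                           generate_complete_matrix, log2_transform, nrmse)

    rf_scores, mean_scores = [], []
    for seed in range(10):
        m, _ = generate_complete_matrix(SyntheticSpec(n_proteins=80, seed=seed))
        ds = apply_missingness(m, MissingnessSpec(0.25, 0.0, seed=seed + 100))
        obs_log = log2_transform(ds.observed)
        com_log = log2_transform(m)
        rf = impute_rf(obs_log, ImputerConfig(ntree=50, seed=seed))
        rf_scores.append(nrmse(com_log, rf.imputed, ds.mask))
        col_means = np.nanmean(obs_log.values, axis=0)
        filled = np.where(np.isnan(obs_log.values), col_means[None, :], obs_log.values)
        mean_scores.append(nrmse(com_log, obs_log.with_values(filled), ds.mask))
    assert np.median(rf_scores) <= np.median(mean_scores)
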