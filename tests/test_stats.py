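"""Transforms, t-tests, BH adjustment, fold change, significance, PCA."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfqimpute import (IntensityMatrix, SyntheticSpec, adjust_fdr,
                       call_significant, complete_case_subset, filter_min_presence,
                       fold_change, generate_complete_matrix, log2_transform,
                       pca_group_separation, t_test_per_protein)


def _mat(values, groups=None, scale="raw"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    groups = groups or ["a"] * (p - p // 2) + ["b"] * (p // 2)
    return IntensityMatrix(values, [f"P{i}" for i in range(n)],
                           [f"s{j}" for j in range(p)], groups, scale=scale)


# --------------------------------------------------------------- log2

def test_log2_basic_and_missing_preserved():
    m = _mat([[8.0, np.nan], [2.0, 4.0]])
    out = log2_transform(m)
    assert out.values[0, 0] == 3.0
    assert np.isnan(out.values[0, 1])
    assert out.scale == "log2"
    assert np.allclose(np.exp2(out.values[1]), m.values[1], rtol=1e-12)


def test_log2_nonpositive_reports_coordinates():
    m = _mat([[8.0, 1.0], [-2.0, 4.0]])
    with pytest.raises(ValueError, match="row 1"):
        log2_transform(m)


# --------------------------------------------------------------- filter

def test_min_presence_boundary():
    values = np.full((2, 10), 5.0)
    values[0, 5:] = np.nan          # 5 of 10 observed -> kept
    values[1, 4:] = np.nan          # 4 of 10 observed -> dropped
    groups = ["a"] * 5 + ["b"] * 5
    out = filter_min_presence(_mat(values, groups), 0.5)
    assert out.protein_ids == ["P0"]


def test_min_presence_one_equals_complete_case():
    rng = np.random.default_rng(0)
    for seed in range(5):
        values = rng.normal(20, 2, size=(30, 8))
        values[rng.random((30, 8)) < 0.3] = np.nan
        values[0] = rng.normal(20, 2, size=8)  # guarantee a complete row
        keep_rows = ~np.isnan(values).all(axis=1)
        values = values[keep_rows]
        m = _mat(values, ["a"] * 4 + ["b"] * 4, scale="log2")
        assert filter_min_presence(m, 1.0).protein_ids == \
            complete_case_subset(m).protein_ids


# --------------------------------------------------------------- t-test

def test_pooled_t_frozen_example():
    m = _mat([[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]],
             groups=["a", "a", "a", "b", "b", "b"], scale="log2")
    tt = t_test_per_protein(m, "a", "b")
    assert tt["t"].iloc[0] == pytest.approx(-1.2247448, abs=1e-6)
    assert tt["p"].iloc[0] == pytest.approx(0.288, abs=2e-3)


def test_identical_groups_degenerate():
    m = _mat([[5.0, 5.0, 5.0, 5.0]], groups=["a", "a", "b", "b"], scale="log2")
    tt = t_test_per_protein(m, "a", "b")
    assert tt["t"].iloc[0] == 0.0
    assert tt["p"].iloc[0] == 1.0
    assert bool(tt["degenerate"].iloc[0])


def test_swapping_groups_negates_t():
    rng = np.random.default_rng(1)
    m = _mat(rng.normal(20, 2, size=(15, 8)), ["a"] * 4 + ["b"] * 4, scale="log2")
    ab = t_test_per_protein(m, "a", "b")
    ba = t_test_per_protein(m, "b", "a")
    assert np.allclose(ab["t"], -ba["t"])
    assert np.allclose(ab["p"], ba["p"])


def test_null_p_values_uniform():
    """Global null: KS statistic of per-protein p-values vs U(0,1) < 0.05."""
    from scipy.stats import kstest
    spec = SyntheticSpec(n_proteins=2000, de_fraction=0.0, n_latent_factors=0,
                         seed=17)
    m, _ = generate_complete_matrix(spec)
    tt = t_test_per_protein(log2_transform(m), "control", "treated")
    ks = kstest(tt["p"], "uniform").statistic
    assert ks < 0.05


# --------------------------------------------------------------- BH

def _bh_oracle(p):
    """From-definition step-up rule."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(p[idx] * n / rank_from_top, prev)
        q[idx] = val
        prev = val
    return np.minimum(q, 1.0)


def test_bh_hand_example():
    adj = adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged():
    assert adjust_fdr(np.array([0.3]))[0] == pytest.approx(0.3)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
def test_bh_matches_definition_and_is_monotone(ps):
    p = np.array(ps)
    adj = adjust_fdr(p)
    assert np.allclose(adj, _bh_oracle(p), atol=1e-12)
    assert (adj >= p - 1e-12).all()
    assert ((0 <= adj) & (adj <= 1)).all()


def test_bh_invariant_under_permutation():
    rng = np.random.default_rng(2)
    p = rng.random(40)
    perm = rng.permutation(40)
    assert np.allclose(adjust_fdr(p)[perm], adjust_fdr(p[perm]))


# --------------------------------------------------------------- fold change

def test_fold_change_definitions():
    raw = _mat([[1.0, 1.0, 4.0, 4.0]], groups=["a", "a", "b", "b"])
    assert fold_change(raw, "a", "b")[0] == pytest.approx(2.0)
    equal = _mat([[3.0, 3.0, 3.0, 3.0]], groups=["a", "a", "b", "b"])
    assert fold_change(equal, "a", "b")[0] == pytest.approx(0.0)


def test_fold_change_scale_conventions_differ_on_skewed_data():
    """Raw scale: log2 of ratio of arithmetic means. Log2 scale:
    difference of log-means (= log of geometric-mean ratio). They differ
    on skewed rows and each matches its documented formula."""
    vals = np.array([[1.0, 1000.0, 2.0, 2.0]])
    groups = ["a", "a", "b", "b"]
    raw = _mat(vals, groups)
    fc_raw = fold_change(raw, "a", "b")[0]
    assert fc_raw == pytest.approx(np.log2(2.0 / 500.5))
    logm = log2_transform(raw)
    fc_log = fold_change(logm, "a", "b")[0]
    assert fc_log == pytest.approx(np.log2(vals[0, 2:]).mean() - np.log2(vals[0, :2]).mean())
    assert fc_raw != pytest.approx(fc_log)


def test_fold_change_raw_nonpositive_mean_errors():
    m = _mat([[-5.0, -5.0, 2.0, 2.0]], groups=["a", "a", "b", "b"])
    with pytest.raises(ValueError, match="nonpositive"):
        fold_change(m, "a", "b")


# --------------------------------------------------------------- calls

def test_call_significant_combinations():
    p_adj = np.array([0.01, 0.2, 0.01])
    fc = np.array([2.0, 2.0, 0.5])
    flags = call_significant(p_adj, fc, fdr_threshold=0.05, fc_threshold=2)
    assert flags.tolist() == [True, False, False]
    flags_no_fc = call_significant(p_adj, fdr_threshold=0.05)
    assert flags_no_fc.tolist() == [True, False, True]


# --------------------------------------------------------------- PCA

def test_pca_separation_strong_shift():
    rng = np.random.default_rng(3)
    n, p = 40, 10
    values = rng.normal(20, 0.5, size=(n, p))
    values[:, 5:] += 8.0  # group shift far beyond noise
    m = _mat(values, ["a"] * 5 + ["b"] * 5, scale="log2")
    _, score = pca_group_separation(m, np.arange(n))
    assert score > 0.5


def test_pca_separation_null_near_zero():
    rng = np.random.default_rng(4)
    scores = []
    for _ in range(10):
        values = rng.normal(20, 1, size=(30, 10))
        m = _mat(values, ["a"] * 5 + ["b"] * 5, scale="log2")
        _, s = pca_group_separation(m, np.arange(30))
        scores.append(abs(s))
    assert np.median(scores) < 0.2


def test_pca_separation_degenerate_inputs():
    rng = np.random.default_rng(5)
    single_group = IntensityMatrix(rng.normal(20, 1, (10, 4)),
                                   [f"P{i}" for i in range(10)],
                                   [f"s{j}" for j in range(4)],
                                   ["a"] * 4, scale="log2")
    with pytest.raises(ValueError):
        pca_group_separation(single_group, np.arange(10))
    two_groups = _mat(rng.normal(20, 1, (10, 4)), ["a", "a", "b", "b"],
                      scale="log2")
    with pytest.raises(ValueError):
        pca_group_separation(two_groups, np.array([3]))
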