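"""Global-similarity imputers: iterative SVD, probabilistic PCA, Bayesian PCA.

All three treat protein rows as observations in sample space (dimension =
number of samples) and reconstruct missing cells from a low-dimensional
latent representation of the whole matrix:

* SVD: alternate between rank-q truncated SVD of the (column-centered)
  current matrix and re-filling the missing cells from the low-rank
  reconstruction.
* PPCA: EM for the probabilistic PCA model x = mu + W z + eps with
  isotropic noise; the E-step conditions on the observed coordinates of
  each row, missing cells are filled with the posterior predictive mean.
* BPCA: variational Bayesian PCA with an automatic-relevance-determination
  (ARD) prior on the factor loadings, which prunes superfluous components;
  missing cells are iteratively re-filled from the current reconstruction.
"""
from __future__ import annotations

import numpy as np

from ..matrix import IntensityMatrix
from .base import ImputationResult, ImputerConfig, finish, validate_input


# ---------------------------------------------------------------------------
# iterative truncated SVD
# ---------------------------------------------------------------------------

def impute_svd(m: IntensityMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    cfg = cfg or ImputerConfig()
    validate_input(m)
    miss = m.missing_mask
    if not miss.any():
        return finish(m, m.values.copy(), "SVD", cfg, n_iterations=0)
    q = cfg.resolved_n_pcs("svd", m.shape)

    X = m.values
    row_means = np.nanmean(X, axis=1)
    cur = np.where(miss, row_means[:, None], X)

    n_iter = 0
    rel_change = np.inf
    for n_iter in range(1, cfg.max_iter + 1):
        center = cur.mean(axis=0)
        U, s, Vt = np.linalg.svd(cur - center, full_matrices=False)
        recon = (U[:, :q] * s[:q]) @ Vt[:q] + center
        new_mis = recon[miss]
        old_mis = cur[miss]
        denom = float(np.linalg.norm(old_mis))
        rel_change = float(np.linalg.norm(new_mis - old_mis)) / max(denom, 1e-12)
        cur[miss] = new_mis
        if rel_change < cfg.tol:
            break
    return finish(m, cur, "SVD", cfg, n_iterations=n_iter,
                  details={"final_rel_change": rel_change})


# ---------------------------------------------------------------------------
# PPCA (EM with missing data)
# ---------------------------------------------------------------------------

def ppca_em(values: np.ndarray, q: int, seed: int = 0, tol: float = 1e-5,
            max_iter: int = 100) -> tuple[np.ndarray, dict]:
    """EM for probabilistic PCA on a matrix with missing entries.

    Rows are observations, columns variables. Returns the matrix with
    missing entries replaced by the posterior predictive mean, plus an
    info dict containing the observed-data log-likelihood trajectory
    (nondecreasing, as EM guarantees).
    """
    X = np.asarray(values, dtype=float)
    N, d = X.shape
    obs = ~np.isnan(X)
    rng = np.random.default_rng(seed)

    mu = np.nansum(np.where(obs, X, 0.0), axis=0) / obs.sum(axis=0)
    W = rng.normal(scale=0.1, size=(d, q))
    sigma2 = 1.0

    # group rows by missingness pattern for vectorized E-steps
    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(obs, axis=0):
        patterns[key.tobytes()] = np.flatnonzero((obs == key).all(axis=1))

    loglik_trace: list[float] = []
    Ez_store: dict[bytes, np.ndarray] = {}
    Sz_store: dict[bytes, np.ndarray] = {}

    def e_step_and_ll(W, mu, sigma2):
        ll = 0.0
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            do = int(o.sum())
            Wo = W[o]
            Xo = X[np.ix_(rows, o)] - mu[o]
            Sz = np.linalg.inv(np.eye(q) + Wo.T @ Wo / sigma2)
            Ez = Xo @ Wo @ Sz / sigma2
            Ez_store[key], Sz_store[key] = Ez, Sz
            C = Wo @ Wo.T + sigma2 * np.eye(do)
            sign, logdet = np.linalg.slogdet(C)
            sol = np.linalg.solve(C, Xo.T)
            quad = float((Xo.T * sol).sum())
            ll += -0.5 * (len(rows) * (do * np.log(2 * np.pi) + logdet) + quad)
        return ll

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll = e_step_and_ll(W, mu, sigma2)
        loglik_trace.append(ll)
        if len(loglik_trace) > 1:
            prev = loglik_trace[-2]
            if abs(ll - prev) / max(abs(prev), 1e-12) < tol:
                break

        # ECM M-step: mu first, then W, then sigma2 (each maximizes the
        # expected complete-data log-likelihood given the E-step stats)
        sum_Ex_minus_WEz = np.zeros(d)
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            mno = ~o
            Ez = Ez_store[key]
            Ex = np.empty((len(rows), d))
            Ex[:, o] = X[np.ix_(rows, o)]
            Ex[:, mno] = mu[mno] + Ez @ W[mno].T
            sum_Ex_minus_WEz += (Ex - Ez @ W.T).sum(axis=0)
        mu_new = sum_Ex_minus_WEz / N

        S1 = np.zeros((d, q))
        S2 = np.zeros((q, q))
        pattern_Ex: dict[bytes, np.ndarray] = {}
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            mno = ~o
            Ez, Sz = Ez_store[key], Sz_store[key]
            Ex = np.empty((len(rows), d))
            Ex[:, o] = X[np.ix_(rows, o)]
            Ex[:, mno] = mu[mno] + Ez @ W[mno].T  # predictive mean under old params
            pattern_Ex[key] = Ex
            S1 += (Ex - mu_new).T @ Ez
            S1[mno] += len(rows) * (W[mno] @ Sz)   # Cov(x_m, z) correction
            S2 += len(rows) * Sz + Ez.T @ Ez
        W_new = np.linalg.solve(S2.T, S1.T).T

        total = 0.0
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            mno = ~o
            Ez, Sz = Ez_store[key], Sz_store[key]
            Ex = pattern_Ex[key]
            A = Ex - mu_new - Ez @ W_new.T
            total += float((A * A).sum())
            n_pat = len(rows)
            if mno.any():
                Wm = W[mno]
                total += n_pat * (sigma2 * int(mno.sum())
                                  + float(np.einsum("ij,jk,ik->", Wm, Sz, Wm)))
                total += -2.0 * n_pat * float(
                    np.einsum("ij,ij->", W_new[mno], Wm @ Sz))
            total += n_pat * float(np.einsum("ij,jk,ik->", W_new, Sz, W_new))
        sigma2_new = max(total / (N * d), 1e-12)

        mu, W, sigma2 = mu_new, W_new, sigma2_new

    # final E-step with converged parameters -> posterior predictive fill
    e_step_and_ll(W, mu, sigma2)
    filled = X.copy()
    for key, rows in patterns.items():
        o = np.frombuffer(key, dtype=bool)
        mno = ~o
        if not mno.any():
            continue
        Ez = Ez_store[key]
        filled[np.ix_(rows, mno)] = mu[mno] + Ez @ W[mno].T
    info = {"loglik_trace": loglik_trace, "n_iterations": n_iter,
            "W": W, "mu": mu, "sigma2": sigma2}
    return filled, info


def impute_ppca(m: IntensityMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    cfg = cfg or ImputerConfig()
    validate_input(m)
    q = cfg.resolved_n_pcs("ppca", m.shape)
    if not m.missing_mask.any():
        return finish(m, m.values.copy(), "PPCA", cfg, n_iterations=0)
    filled, info = ppca_em(m.values, q, seed=cfg.seed, tol=cfg.tol, max_iter=cfg.max_iter)
    return finish(m, filled, "PPCA", cfg, n_iterations=info["n_iterations"],
                  details={"loglik_trace": info["loglik_trace"]})


# ---------------------------------------------------------------------------
# BPCA (variational Bayes with ARD)
# ---------------------------------------------------------------------------

def bpca_fill(values: np.ndarray, q: int, seed: int = 0, tol: float = 1e-5,
              max_iter: int = 100) -> tuple[np.ndarray, dict]:
    """Variational Bayesian PCA with ARD priors on the loading columns.

    Missing entries are re-filled each iteration from the current
    reconstruction mu + z W^T; the ARD precisions alpha_k drive the
    loadings of superfluous components towards zero. Convergence on the
    relative change of the noise precision tau.
    """
    X = np.asarray(values, dtype=float)
    N, d = X.shape
    obs = ~np.isnan(X)
    mu = np.nansum(np.where(obs, X, 0.0), axis=0) / obs.sum(axis=0)
    y = np.where(obs, X, mu[None, :])

    yc = y - mu
    U, s, Vt = np.linalg.svd(yc, full_matrices=False)
    W = Vt[:q].T * (s[:q] / np.sqrt(N))
    resid_var = max(float((yc * yc).sum() / (N * d) - (s[:q] ** 2).sum() / (N * d)), 1e-8)
    tau = 1.0 / resid_var
    alpha = d / np.maximum((W * W).sum(axis=0), 1e-12)

    Sw = np.linalg.inv(tau * N * np.eye(q) + np.diag(alpha))  # init; refined each iteration
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # posterior over scores given current loadings (and their uncertainty)
        Sz = np.linalg.inv(np.eye(q) + tau * (W.T @ W + d * Sw))
        Z = tau * (y - mu) @ W @ Sz
        recon = mu + Z @ W.T
        y = np.where(obs, X, recon)

        mu = (y - Z @ W.T).mean(axis=0)
        yc = y - mu
        Ezz = N * Sz + Z.T @ Z
        Sw = np.linalg.inv(tau * Ezz + np.diag(alpha))
        W = tau * (yc.T @ Z) @ Sw

        resid = float(((yc - Z @ W.T) ** 2).sum())
        resid += N * float(np.einsum("ij,jk,ik->", W, Sz, W))
        resid += d * float(np.trace(Sw @ Ezz))
        tau_new = N * d / max(resid, 1e-12)
        alpha = d / np.maximum((W * W).sum(axis=0) + d * np.diag(Sw), 1e-12)

        rel = abs(tau_new - tau) / max(tau, 1e-12)
        tau = tau_new
        if rel < tol:
            break

    Sz = np.linalg.inv(np.eye(q) + tau * (W.T @ W))
    Z = tau * (y - mu) @ W @ Sz
    filled = X.copy()
    filled[~obs] = (mu + Z @ W.T)[~obs]
    info = {"n_iterations": n_iter, "W": W, "alpha": alpha, "tau": tau,
            "loading_norms": np.sqrt((W * W).sum(axis=0))}
    return filled, info


def impute_bpca(m: IntensityMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    cfg = cfg or ImputerConfig()
    validate_input(m)
    q = cfg.resolved_n_pcs("bpca", m.shape)
    if not m.missing_mask.any():
        return finish(m, m.values.copy(), "BPCA", cfg, n_iterations=0)
    filled, info = bpca_fill(m.values, q, seed=cfg.seed, tol=cfg.tol, max_iter=cfg.max_iter)
    return finish(m, filled, "BPCA", cfg, n_iterations=info["n_iterations"],
                  details={"loading_norms": info["loading_norms"]})
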