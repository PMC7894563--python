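"""Compiled inner loop of the Gibbs sampler.

Pure-numerical kernels, jitted with numba: the statistical structure and
all prior bookkeeping live in :mod:`phenomatch.mcmc`; this module only
executes the per-iteration updates fast.  Rows must arrive ordered with
all binomial observations before all Gaussian ones.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _solve_lower(L, b):
    n = L.shape[0]
    x = np.empty(n)
    for i in range(n):
        s = b[i]
        for j in range(i):
            s -= L[i, j] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=False)
def _solve_upper(U, b):
    n = U.shape[0]
    x = np.empty(n)
    for i in range(n - 1, -1, -1):
        s = b[i]
        for j in range(i + 1, n):
            s -= U[i, j] * x[j]
        x[i] = s / U[i, i]
    return x


@njit(cache=False)
def _try_cholesky(A, L):
    """In-place lower Cholesky; returns False on a non-positive pivot."""
    n = A.shape[0]
    for i in range(n):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0 or not np.isfinite(s):
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, n):
            L[i, j] = 0.0
    return True


@njit(cache=False)
def _cholesky_jitter(A):
    """Cholesky with escalating diagonal jitter for near-singular cases."""
    n = A.shape[0]
    L = np.empty((n, n))
    if _try_cholesky(A, L):
        return L
    tr = 0.0
    for i in range(n):
        tr += abs(A[i, i])
    jitter = 1e-12 * max(tr / n, 1e-300)
    for _ in range(30):
        B = A.copy()
        for i in range(n):
            B[i, i] += jitter
        if _try_cholesky(B, L):
            return L
        jitter *= 10.0
    # give up: return a scaled identity so the chain can continue
    for i in range(n):
        for j in range(n):
            L[i, j] = 0.0
        L[i, i] = np.sqrt(max(abs(A[i, i]), 1e-300))
    return L


@njit(cache=False)
def _softplus(x):
    # log(1 + exp(x)) without overflow
    if x > 0.0:
        return x + np.log1p(np.exp(-x))
    return np.log1p(np.exp(x))


@njit(cache=False)
def _inv_wishart(rng, df, S):
    """Bartlett-decomposition draw from InvWishart(df, S)."""
    q = S.shape[0]
    Ls = _cholesky_jitter(S)
    eye = np.eye(q)
    Linv = np.empty((q, q))
    for j in range(q):
        Linv[:, j] = _solve_lower(Ls, eye[:, j])
    A = np.zeros((q, q))
    for i in range(q):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    F = Linv.T @ A
    Finv = np.linalg.inv(F)
    return Finv.T @ Finv


@njit(cache=False)
def run_chain(rng, Wb, Wg, Ub, Ug, yidx_b, yidx_g, yb, trials, yg,
              p, q, K, n_iter, burn, thin,
              fixed_prec, alpha_prec, nu0, V0, resid_nu, resid_V,
              out_fixed, out_cov, out_u, out_resid):
    """Run the full Gibbs chain; fills the ``out_*`` arrays in place.

    Returns the overall latent-update acceptance rate.
    """
    n_bin = Wb.shape[0]
    n_gau = Wg.shape[0]
    dim = p + K * q

    Xb = np.ascontiguousarray(Wb[:, :p])
    Xg = np.ascontiguousarray(Wg[:, :p])
    G_bin = Wb.T @ Wb
    if n_gau > 0:
        G_gau = Wg.T @ Wg
        a_gau = Wg.T @ yg
    else:
        G_gau = np.zeros((dim, dim))
        a_gau = np.zeros(dim)

    # state
    l = np.empty(n_bin)
    sp_l = np.empty(n_bin)
    for i in range(n_bin):
        l[i] = np.log((yb[i] + 0.5) / (trials[i] - yb[i] + 0.5))
        sp_l[i] = _softplus(l[i])
    theta = np.zeros(dim)
    v = np.zeros((K, q))
    alpha = np.ones(q)
    psi = V0.copy()
    if n_gau > 0:
        m = yg.mean()
        resid_var = 0.0
        for i in range(n_gau):
            resid_var += (yg[i] - m) ** 2
        resid_var = resid_var / max(n_gau - 1, 1)
        if resid_var <= 0.0:
            resid_var = 1.0
    else:
        resid_var = 1.0

    step = 1.8
    acc_win = 0
    win_n = 0
    acc_glob = 0
    scale = np.ones(dim)
    keep = 0
    n_ret = out_fixed.shape[0]

    for it in range(n_iter):
        for k in range(K):
            for j in range(q):
                scale[p + k * q + j] = alpha[j]

        # ---- 1. latent MH for binomial rows -----------------------------
        eta_b = Wb @ (scale * theta)
        for i in range(n_bin):
            prop = l[i] + step * rng.standard_normal()
            sp_prop = _softplus(prop)
            logratio = (yb[i] * (prop - l[i])
                        - trials[i] * (sp_prop - sp_l[i])
                        - 0.5 * ((prop - eta_b[i]) ** 2
                                 - (l[i] - eta_b[i]) ** 2))
            if np.log(rng.random()) < logratio:
                l[i] = prop
                sp_l[i] = sp_prop
                acc_win += 1
                acc_glob += 1
        win_n += n_bin
        if it < burn and (it + 1) % 100 == 0:
            rate = acc_win / max(win_n, 1)
            step = step * np.exp(0.66 * (rate - 0.44))
            if step < 0.1:
                step = 0.1
            elif step > 10.0:
                step = 10.0
            acc_win = 0
            win_n = 0

        # ---- 2. joint (beta, v) draw ------------------------------------
        psi_inv = np.linalg.inv(psi)
        A = np.empty((dim, dim))
        if n_gau > 0:
            for i in range(dim):
                for j in range(dim):
                    A[i, j] = scale[i] * scale[j] * (
                        G_bin[i, j] + G_gau[i, j] / resid_var)
        else:
            for i in range(dim):
                for j in range(dim):
                    A[i, j] = scale[i] * scale[j] * G_bin[i, j]
        for i in range(p):
            A[i, i] += fixed_prec[i]
        for k in range(K):
            s0 = p + k * q
            for i in range(q):
                for j in range(q):
                    A[s0 + i, s0 + j] += psi_inv[i, j]
        b = Wb.T @ l
        if n_gau > 0:
            b = b + a_gau / resid_var
        b = scale * b
        L = _cholesky_jitter(A)
        m1 = _solve_lower(L, b)
        m2 = _solve_upper(L.T.copy(), m1)
        z = rng.standard_normal(dim)
        theta = m2 + _solve_upper(L.T.copy(), z)
        beta = theta[:p]
        v = theta[p:].reshape(K, q).copy()

        # ---- 3. working scale alpha -------------------------------------
        P = np.zeros((q, q))
        bb = np.zeros(q)
        xb_b = Xb @ beta
        for i in range(n_bin):
            ri = l[i] - xb_b[i]
            for a in range(q):
                ca = Ub[i, a] * v[yidx_b[i], a]
                bb[a] += ca * ri
                for c in range(q):
                    P[a, c] += ca * Ub[i, c] * v[yidx_b[i], c]
        if n_gau > 0:
            xb_g = Xg @ beta
            wgt = 1.0 / resid_var
            for i in range(n_gau):
                ri = yg[i] - xb_g[i]
                for a in range(q):
                    ca = Ug[i, a] * v[yidx_g[i], a]
                    bb[a] += ca * ri * wgt
                    for c in range(q):
                        P[a, c] += ca * Ug[i, c] * v[yidx_g[i], c] * wgt
        for a in range(q):
            P[a, a] += alpha_prec
        La = _cholesky_jitter(P)
        ma = _solve_upper(La.T.copy(), _solve_lower(La, bb))
        alpha = ma + _solve_upper(La.T.copy(), rng.standard_normal(q))

        # ---- 4. working covariance Psi ----------------------------------
        S = V0 + v.T @ v
        psi = _inv_wishart(rng, nu0 + K, S)

        # ---- 5. Gaussian residual variance ------------------------------
        if n_gau > 0:
            for k in range(K):
                for j in range(q):
                    scale[p + k * q + j] = alpha[j]
            eta_g = Wg @ (scale * theta)
            ssr = 0.0
            for i in range(n_gau):
                ssr += (yg[i] - eta_g[i]) ** 2
            shape = 0.5 * (resid_nu + n_gau)
            rate_ = 0.5 * (resid_nu * resid_V + ssr)
            resid_var = rate_ / rng.gamma(shape, 1.0)
            if resid_var < 1e-10:
                resid_var = 1e-10

        # ---- store ------------------------------------------------------
        if it >= burn and (it - burn) % thin == 0 and keep < n_ret:
            for i in range(p):
                out_fixed[keep, i] = beta[i]
            for i in range(q):
                for j in range(q):
                    out_cov[keep, i, j] = alpha[i] * psi[i, j] * alpha[j]
            for k in range(K):
                for j in range(q):
                    out_u[keep, k, j] = v[k, j] * alpha[j]
            out_resid[keep] = resid_var
            keep += 1

    return acc_glob / max(n_bin * n_iter, 1)
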