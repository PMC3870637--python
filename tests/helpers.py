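"""Independent oracles used across the test suite.

Everything here deliberately avoids the package's low-rank code paths:
marginal densities come from brute-force Gauss-Hermite integration of
the full joint over (intercept, span coefficients), and covariance
algebra goes through dense numpy routines.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from gsgprobit.model import GammaVector, log_prior_c


def dense_sigma(X: np.ndarray, sel, c: float, h: float) -> np.ndarray:
    """Dense I + h 11' + c X_sel (X_sel' X_sel)^+ X_sel' (oracle route)."""
    n = X.shape[0]
    S = np.eye(n) + h * np.ones((n, n))
    sel = np.asarray(sel, dtype=int)
    if sel.size:
        Xs = X[:, sel]
        # rcond matches the package's numerical-rank convention so both
        # routes agree on which near-zero Gram eigenvalues are noise
        S = S + c * (Xs @ np.linalg.pinv(Xs.T @ Xs, rcond=1e-10) @ Xs.T)
    return S


def dense_log_marginal(z: np.ndarray, X: np.ndarray, sel, c: float, h: float,
                       pi: np.ndarray) -> float:
    """Dense-route evaluation of the marginalized log-density."""
    S = dense_sigma(X, sel, c, h)
    sign, logdet = np.linalg.slogdet(S)
    assert sign > 0
    quad = float(z @ np.linalg.solve(S, z))
    p = X.shape[1]
    gam = np.zeros(p)
    gam[list(sel)] = 1
    logprior_gamma = float(np.sum(gam * np.log(pi) + (1 - gam) * np.log1p(-pi)))
    return -0.5 * logdet - 0.5 * quad + logprior_gamma + log_prior_c(c, X.shape[0])


def gauss_hermite_marginal(z: np.ndarray, X: np.ndarray, sel, c: float, h: float,
                           pi: np.ndarray, n_nodes: int = 120) -> float:
    """Brute-force marginal density of Z by integrating the full joint.

    Integrates N(z; alpha 1 + X_sel beta, I) against the N(0, h)
    intercept prior and the degenerate N(0, c (X_sel'X_sel)^+) prior
    (over its span) with tensorized Gauss-Hermite quadrature, then
    multiplies the gamma-prior and normalized c-prior terms. Returns
    the density including the (2 pi)^(-n/2) Gaussian constant.
    """
    n, p = X.shape
    sel = np.asarray(sel, dtype=int)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    # probabilists' Hermite: integrates f against standard normal, weight sum sqrt(2 pi)
    weights = weights / math.sqrt(2 * math.pi)

    if sel.size:
        Xs = X[:, sel]
        G = Xs.T @ Xs
        w, V = np.linalg.eigh(G)
        keep = w > 1e-10 * w.max()
        lamG = w[keep]
        B = Xs @ V[:, keep]            # n x m map from span coordinates
        sds = np.sqrt(c / lamG)        # prior sd of each span coordinate
    else:
        B = np.zeros((n, 0))
        sds = np.zeros(0)

    dims = [math.sqrt(h)] + list(sds)  # alpha then span coords
    grids = [nodes * s for s in dims]
    total = 0.0
    for combo in itertools.product(*(range(n_nodes) for _ in dims)):
        wgt = 1.0
        mean = np.zeros(n)
        for d, ci in enumerate(combo):
            wgt *= weights[ci]
            if d == 0:
                mean = mean + grids[0][ci]
            else:
                mean = mean + B[:, d - 1] * (grids[d][ci] / 1.0)
        resid = z - mean
        total += wgt * math.exp(-0.5 * float(resid @ resid))
    total *= (2 * math.pi) ** (-n / 2.0)

    gam = np.zeros(p)
    gam[sel] = 1
    logprior_gamma = float(np.sum(gam * np.log(pi) + (1 - gam) * np.log1p(-pi)))
    return total * math.exp(logprior_gamma + log_prior_c(c, n))


def gauss_hermite_marginal_fast(z: np.ndarray, X: np.ndarray, sel, c: float,
                                h: float, pi: np.ndarray, n_nodes: int = 120) -> float:
    """Vectorized version of :func:`gauss_hermite_marginal` (<= 2 dims)."""
    n, p = X.shape
    sel = np.asarray(sel, dtype=int)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / math.sqrt(2 * math.pi)

    if sel.size:
        Xs = X[:, sel]
        G = Xs.T @ Xs
        w, V = np.linalg.eigh(G)
        keep = w > 1e-10 * w.max()
        lamG = w[keep]
        B = Xs @ V[:, keep]
        sds = np.sqrt(c / lamG)
    else:
        B = np.zeros((n, 0))
        sds = np.zeros(0)
    m = B.shape[1]
    assert m <= 2, "fast oracle supports at most 2 span dimensions"

    alphas = nodes * math.sqrt(h)                  # (Q,)
    if m == 0:
        means = alphas[:, None] * np.ones(n)       # Q x n
        resid2 = np.sum((z - means) ** 2, axis=1)
        total = float(weights @ np.exp(-0.5 * resid2))
    elif m == 1:
        th = nodes * sds[0]
        mean = alphas[:, None, None] + np.multiply.outer(th, B[:, 0])[None, :, :]
        resid2 = np.sum((z - mean) ** 2, axis=2)   # Q x Q
        total = float(weights @ np.exp(-0.5 * resid2) @ weights)
    else:
        th0 = nodes * sds[0]
        th1 = nodes * sds[1]
        mean = (alphas[:, None, None, None]
                + np.multiply.outer(th0, B[:, 0])[None, :, None, :]
                + np.multiply.outer(th1, B[:, 1])[None, None, :, :])
        resid2 = np.sum((z - mean) ** 2, axis=3)   # Q x Q x Q
        total = float(np.einsum("i,ijk,j,k->", weights, np.exp(-0.5 * resid2),
                                weights, weights))
    total *= (2 * math.pi) ** (-n / 2.0)

    gam = np.zeros(p)
    gam[sel] = 1
    logprior_gamma = float(np.sum(gam * np.log(pi) + (1 - gam) * np.log1p(-pi)))
    return total * math.exp(logprior_gamma + log_prior_c(c, n))


def enumerate_gamma_distribution(z: np.ndarray, ds, c: float, cfg) -> dict:
    """Exact conditional distribution over all 2^p gamma configurations."""
    from gsgprobit.model import log_marginal

    p = ds.p
    logps = {}
    for bits in itertools.product([0, 1], repeat=p):
        gv = GammaVector(np.array(bits))
        logps[bits] = log_marginal(z, gv, c, ds, cfg)
    mx = max(logps.values())
    Z = sum(math.exp(v - mx) for v in logps.values())
    return {k: math.exp(v - mx) / Z for k, v in logps.items()}


def c_conditional_cdf_grid(eng, lo: float = 1e-6, hi: float = 1e6,
                           n_grid: int = 40001):
    """Quadrature CDF of the c full conditional on a log-spaced grid."""
    grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))
    lp = np.array([eng.log_cond_c(ci) for ci in grid])
    wts = np.exp(lp - lp.max())
    cdf = np.concatenate([[0.0], np.cumsum((wts[1:] + wts[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    return grid, cdf


def ks_distance(samples: np.ndarray, grid: np.ndarray, cdf: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance of samples against a gridded CDF."""
    s = np.sort(np.asarray(samples, dtype=float))
    F = np.interp(s, grid, cdf)
    n = len(s)
    ranks = np.arange(1, n + 1) / n
    return float(np.max(np.maximum(np.abs(F - ranks), np.abs(F - (ranks - 1.0 / n)))))
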