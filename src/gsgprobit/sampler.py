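"""Three-block MCMC for the latent-probit gsg-prior selection model.

One iteration performs:

Step 1 — a systematic Gibbs sweep over the latent utilities Z_i, each
drawn from its univariate N(0, Sigma_gamma) conditional truncated to
the half-line dictated by the observed label Y_i;

Step 2 — a systematic Gibbs sweep over the inclusion indicators
gamma_i (i = 1..p), each set to 1 with the closed-form conditional
probability (1 + ((1-pi_i)/pi_i) rho_i)^{-1}, where rho_i is the ratio
of marginal Gaussian densities with gene i in versus out;

Step 3 — a Metropolis-Hastings update of the g-prior scale c using an
independence-style proposal centered at the conditional mode c_opt
(found by bounded scalar optimization on log c), with a truncated
normal perturbation whose scale comes from a Laplace approximation.

All Sigma_gamma algebra runs through the low-rank projector
representation (see :mod:`gsgprobit.model`): a gamma sweep touches only
scalar projections (1'Pz, z'Pz, 1'P1) which are updated by rank-one
basis extensions for "add gene" proposals and a thin re-factorization
for removals. The dense route survives as the test oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, ndtr, ndtri

from .model import (
    DEFAULT_RTOL,
    GammaVector,
    ModelConfig,
    SigmaOperator,
    build_sigma,
    orthonormal_column_basis,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChainState",
    "MHProposalConfig",
    "ChainResult",
    "update_Z",
    "gamma_flip_prob",
    "update_gamma",
    "update_c",
    "run_chain",
]

_LOGC_LO, _LOGC_HI = math.log(1e-3), math.log(1e6)


@dataclass
class ChainState:
    """One MCMC state (Z, gamma, c)."""

    Z: np.ndarray
    gamma: GammaVector
    c: float
    iteration: int = 0


@dataclass
class MHProposalConfig:
    """Mode-centered proposal for the c update.

    The workhorse move proposes c* = c_opt + eps with eps ~
    N(mu, sigma^2) truncated to (lower, upper); the default
    configuration (built at run time when none is supplied) uses
    mu = 0, a Laplace-based sigma and (lower, upper) =
    (-c_opt + 1e-6, inf) so the proposal support is all of
    (1e-6, inf).

    With probability ``heavy_weight`` the proposal instead draws c*
    directly from the IG(1/2, n/2) hyperprior. The c full
    conditional inherits the hyperprior's polynomial right tail, so a
    purely Gaussian independence proposal has lighter tails than its
    target and can stick in the tail for astronomically long runs;
    mixing in the prior bounds the importance weights (the likelihood
    factor in c is bounded) and restores uniform ergodicity. Set
    ``heavy_weight = 0`` for the pure truncated-normal scheme.
    """

    mu: float = 0.0
    sigma: float = 1.0
    lower: float = -math.inf
    upper: float = math.inf
    heavy_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("proposal sigma must be > 0")
        if not self.lower < self.upper:
            raise ValueError("proposal requires lower < upper")
        if not 0.0 <= self.heavy_weight < 1.0:
            raise ValueError("heavy_weight must lie in [0, 1)")

    def _log_tn(self, eps: float) -> float:
        """Normalized truncated-normal log-density of the perturbation."""
        if not (self.lower < eps < self.upper):
            return -math.inf
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        mass = float(ndtr(-a)) if b == math.inf else float(ndtr(b) - ndtr(a))
        if mass <= 0:
            return -math.inf
        return (-0.5 * ((eps - self.mu) / self.sigma) ** 2
                - math.log(self.sigma) - 0.5 * math.log(2 * math.pi)
                - math.log(mass))

    def log_q(self, c_star: float, c_opt: float, n: int) -> float:
        """Log proposal density at c_star (c-space, mixture form)."""
        from .model import log_prior_c

        terms = []
        lt = self._log_tn(c_star - c_opt)
        if lt > -math.inf and self.heavy_weight < 1.0:
            terms.append(math.log1p(-self.heavy_weight) + lt)
        if self.heavy_weight > 0.0 and c_star > 0.0:
            terms.append(math.log(self.heavy_weight) + log_prior_c(c_star, n))
        if not terms:
            return -math.inf
        m = max(terms)
        return m + math.log(sum(math.exp(t - m) for t in terms))


@dataclass
class ChainResult:
    """Post burn-in, thinned draws plus the run's provenance."""

    draws: list
    burn_in: int
    thin: int
    seed: int
    acceptance_rate_c: float
    n_iter: int = 0
    gene_ids: list = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.draws)

    def gamma_matrix(self) -> np.ndarray:
        """M x p binary matrix of retained inclusion indicators."""
        return np.array([st.gamma.gamma for st in self.draws], dtype=np.int8)

    def c_values(self) -> np.ndarray:
        return np.array([st.c for st in self.draws])

    def p_gammas(self) -> np.ndarray:
        return np.array([st.gamma.p_gamma for st in self.draws])

    def save_trace(self, path, bitmask_path=None) -> None:
        """CSV trace: iteration, c, p_gamma, selected gene IDs.

        With ``bitmask_path``, also writes the full gamma draws as a
        0/1 matrix (one row per retained draw, one column per gene).
        """
        import pandas as pd

        ids = self.gene_ids
        rows = []
        for st in self.draws:
            sel = st.gamma.selected
            names = ";".join(ids[j] if ids else str(j) for j in sel)
            rows.append((st.iteration, st.c, st.gamma.p_gamma, names))
        pd.DataFrame(rows, columns=["iteration", "c", "p_gamma", "selected_gene_ids"]).to_csv(
            path, index=False
        )
        if bitmask_path is not None:
            np.savetxt(bitmask_path, self.gamma_matrix(), fmt="%d", delimiter="\t")


# ---------------------------------------------------------------------------
# truncated-normal scalar sampling

def _std_truncnorm_lower(rng, alpha: float) -> float:
    """Standard normal conditioned on X > alpha."""
    if alpha < -10.0:
        # truncation essentially inactive
        while True:
            x = rng.standard_normal()
            if x > alpha:
                return x
    tail = float(ndtr(-alpha))
    if tail > 1e-300:
        for _ in range(100):
            u = rng.random()
            s = u * tail
            if s > 0.0:
                x = -float(ndtri(s))
                if x > alpha:
                    return x
    # extreme tail: Robert's exponential rejection
    lam = 0.5 * (alpha + math.sqrt(alpha * alpha + 4.0))
    while True:
        x = alpha - math.log1p(-rng.random()) / lam
        if math.log(rng.random()) <= -0.5 * (x - lam) ** 2:
            return x


def _truncnorm_sign(rng, mean: float, sd: float, positive: bool) -> float:
    """N(mean, sd^2) conditioned on the sign of the draw."""
    if positive:
        return mean + sd * _std_truncnorm_lower(rng, -mean / sd)
    return -(-mean + sd * _std_truncnorm_lower(rng, mean / sd))


def _truncnorm_interval(rng, mu: float, sigma: float, lower: float, upper: float) -> float:
    """N(mu, sigma^2) truncated to (lower, upper)."""
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    if b == math.inf:
        return mu + sigma * _std_truncnorm_lower(rng, a)
    if a == -math.inf:
        return mu - sigma * _std_truncnorm_lower(rng, -b)
    Fa, Fb = float(ndtr(a)), float(ndtr(b))
    if Fb - Fa > 1e-12:
        u = rng.random()
        return mu + sigma * float(ndtri(Fa + u * (Fb - Fa)))
    while True:  # thin slab: rejection from the nearer tail
        x = _std_truncnorm_lower(rng, a)
        if x < b:
            return mu + sigma * x


# ---------------------------------------------------------------------------
# low-rank scalar algebra for Sigma = I + h 11' + c P

def _logdet_quad(m, q11, qzz, qz1, sumz, zz, h, c, n):
    """(log|Sigma|, z'Sigma^{-1}z) from scalar projections onto col(P)."""
    d = 1.0 + c
    sig = 1.0 + h * n - h * c * q11 / d
    logdet = m * math.log(d) + math.log(sig)
    quad = zz - c * qzz / d - (h / sig) * (sumz - c * qz1 / d) ** 2
    return logdet, quad


class _Engine:
    """Mutable chain state with incrementally maintained projections.

    Tracks an orthonormal basis U of the selected columns' span, the
    residual matrix R = X - U U'X of every gene on that span, and the
    scalar projections needed by the closed-form density formulas.
    """

    REFRESH_EVERY = 128  # periodic full refactorization (drift hygiene)

    def __init__(self, X, Y, cfg: ModelConfig, rtol: float = DEFAULT_RTOL):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.Y = np.asarray(Y, dtype=np.int64)
        self.n, self.p = self.X.shape
        self.h = float(cfg.h)
        self.rtol = rtol
        pi = cfg.pi_vector(self.p)
        self.log_odds_out = np.log1p(-pi) - np.log(pi)  # log((1-pi)/pi)
        self.colnorm2 = np.einsum("ij,ij->j", self.X, self.X)
        self._updates_since_refresh = 0

    def set_state(self, z: np.ndarray, selected, c: float) -> None:
        self.z = np.array(z, dtype=float)
        self.sel = set(int(j) for j in selected)
        self.c = float(c)
        self._refactorize()
        self.refresh_z()

    # -- basis management ---------------------------------------------------
    def _refactorize(self) -> None:
        sel = np.array(sorted(self.sel), dtype=int)
        self.U = orthonormal_column_basis(self.X[:, sel], rtol=self.rtol)
        self.m = self.U.shape[1]
        self._recompute_residuals()
        s = self.U.sum(axis=0)  # U' 1
        self.q11 = float(s @ s)
        self._s = s
        self._updates_since_refresh = 0

    def _recompute_residuals(self) -> None:
        if self.m:
            self.R = self.X - self.U @ (self.U.T @ self.X)
        else:
            self.R = self.X.copy()
        self.rn2 = np.einsum("ij,ij->j", self.R, self.R)
        self.r1 = self.R.sum(axis=0)

    def refresh_z(self) -> None:
        """Recompute every z-dependent projection (after a Z sweep)."""
        z = self.z
        self.sumz = float(z.sum())
        self.zz = float(z @ z)
        t = self.U.T @ z if self.m else np.zeros(0)
        self._t = t
        self.qzz = float(t @ t)
        self.qz1 = float(self._s @ t)
        self.rz = self.R.T @ z

    def scalars(self):
        return self.m, self.q11, self.qzz, self.qz1, self.sumz, self.zz

    def logdet_quad(self, c: Optional[float] = None):
        c = self.c if c is None else c
        return _logdet_quad(self.m, self.q11, self.qzz, self.qz1,
                            self.sumz, self.zz, self.h, c, self.n)

    # -- gamma sweep ---------------------------------------------------------
    def _removed_scalars(self, j: int):
        """Projection scalars for the support without gene j."""
        others = np.array(sorted(self.sel - {j}), dtype=int)
        U0 = orthonormal_column_basis(self.X[:, others], rtol=self.rtol)
        m0 = U0.shape[1]
        if m0 == self.m:  # span unchanged: gene j was linearly dependent
            return self.m, self.q11, self.qzz, self.qz1, None
        s0 = U0.sum(axis=0)
        t0 = U0.T @ self.z
        return m0, float(s0 @ s0), float(t0 @ t0), float(s0 @ t0), U0

    def _added_scalars(self, j: int):
        """Projection scalars with gene j added to the support."""
        nu = self.rn2[j]
        if nu <= self.rtol * max(self.colnorm2[j], 1e-300):
            return self.m, self.q11, self.qzz, self.qz1, None  # dependent
        inv = 1.0 / math.sqrt(nu)
        u1 = self.r1[j] * inv
        uz = self.rz[j] * inv
        return (self.m + 1, self.q11 + u1 * u1, self.qzz + uz * uz,
                self.qz1 + u1 * uz, (u1, uz))

    def gamma_sweep(self, rng) -> None:
        h, c, n = self.h, self.c, self.n
        ld_cur, q_cur = _logdet_quad(self.m, self.q11, self.qzz, self.qz1,
                                     self.sumz, self.zz, h, c, n)
        for j in range(self.p):
            in_model = j in self.sel
            if in_model:
                m0, q11_0, qzz_0, qz1_0, U0 = self._removed_scalars(j)
                ld1, qd1 = ld_cur, q_cur
                ld0, qd0 = _logdet_quad(m0, q11_0, qzz_0, qz1_0,
                                        self.sumz, self.zz, h, c, n)
            else:
                m1, q11_1, qzz_1, qz1_1, add = self._added_scalars(j)
                ld0, qd0 = ld_cur, q_cur
                ld1, qd1 = _logdet_quad(m1, q11_1, qzz_1, qz1_1,
                                        self.sumz, self.zz, h, c, n)
            log_rho = 0.5 * (ld1 - ld0) + 0.5 * (qd1 - qd0)
            if not math.isfinite(log_rho):
                raise FloatingPointError(f"non-finite flip log-ratio for gene {j}")
            p1 = float(expit(-(self.log_odds_out[j] + log_rho)))
            take = rng.random() < p1
            if take == in_model:
                continue
            # state change
            if take:
                self.sel.add(j)
                if add is not None:
                    self._extend_basis(j, add)
                ld_cur, q_cur = ld1, qd1
            else:
                self.sel.discard(j)
                if U0 is not None:
                    self._shrink_basis(U0)
                ld_cur, q_cur = ld0, qd0
        self._updates_since_refresh += 1
        if self._updates_since_refresh >= self.REFRESH_EVERY:
            self._refactorize()
            self.refresh_z()

    def _extend_basis(self, j: int, add) -> None:
        u1, uz = add
        nu = self.rn2[j]
        u = self.R[:, j] / math.sqrt(nu)
        self.U = np.hstack([self.U, u[:, None]])
        self.m += 1
        self._s = np.append(self._s, u1)
        self._t = np.append(self._t, uz)
        self.q11 += u1 * u1
        self.qzz += uz * uz
        self.qz1 += u1 * uz
        w = u @ self.R
        self.R -= u[:, None] * w
        self.rn2 = np.maximum(self.rn2 - w * w, 0.0)
        self.rz -= w * uz  # uz == u'z since u is the normalized residual
        self.r1 -= w * u1

    def _shrink_basis(self, U0: np.ndarray) -> None:
        self.U = U0
        self.m = U0.shape[1]
        self._recompute_residuals()
        self._s = self.U.sum(axis=0)
        self.q11 = float(self._s @ self._s)
        t = self.U.T @ self.z if self.m else np.zeros(0)
        self._t = t
        self.qzz = float(t @ t)
        self.qz1 = float(self._s @ t)
        self.rz = self.R.T @ self.z

    # -- Z sweep --------------------------------------------------------------
    def z_sweep(self, rng) -> None:
        A = self._precision_factor()
        _z_gibbs_sweep(self.z, A, self.Y, rng)
        self.refresh_z()

    def _precision_factor(self) -> np.ndarray:
        W = np.empty((self.n, self.m + 1))
        W[:, 0] = math.sqrt(self.h)
        if self.m:
            W[:, 1:] = math.sqrt(self.c) * self.U
        K = np.eye(self.m + 1) + W.T @ W
        L = np.linalg.cholesky(K)
        return np.linalg.solve(L, W.T).T  # A with Sigma^{-1} = I - A A'

    # -- c update ---------------------------------------------------------------
    def log_cond_c(self, c: float) -> float:
        """log p(c | Y, X, Z, gamma) up to a constant."""
        ld, qd = self.logdet_quad(c)
        return -0.5 * ld - 0.5 * qd - 1.5 * math.log(c) - self.n / (2.0 * c)


def _z_gibbs_sweep(z: np.ndarray, A: np.ndarray, Y: np.ndarray, rng) -> None:
    """In-place systematic sweep of truncated-normal Z conditionals.

    With precision Lambda = I - A A', the conditional of Z_i given the
    rest of a N(0, Sigma) vector is N(Z_i - (Lambda Z)_i / Lambda_ii,
    1 / Lambda_ii), truncated to (0, inf) when Y_i = 1 and (-inf, 0]
    when Y_i = 0.
    """
    n = z.shape[0]
    lam = 1.0 - np.einsum("ij,ij->i", A, A)
    if np.any(lam <= 0):
        raise FloatingPointError("non-positive conditional precision in Z sweep")
    g = A.T @ z
    for i in range(n):
        ai = A[i]
        zi = z[i]
        r = zi - float(ai @ g)
        li = lam[i]
        mean = zi - r / li
        sd = math.sqrt(1.0 / li)
        znew = _truncnorm_sign(rng, mean, sd, Y[i] == 1)
        g += ai * (znew - zi)
        z[i] = znew


# ---------------------------------------------------------------------------
# public single-step operations (spec surface; the chain uses _Engine)

def update_Z(state: ChainState, sigma_op: SigmaOperator, Y: np.ndarray, rng) -> np.ndarray:
    """One full Gibbs sweep over the latent vector Z; returns the new Z."""
    z = np.array(state.Z, dtype=float)
    A = sigma_op.precision_factor()
    _z_gibbs_sweep(z, A, np.asarray(Y), rng)
    return z


def gamma_flip_prob(i: int, state: ChainState, ds, cfg: ModelConfig,
                    rtol: float = DEFAULT_RTOL) -> float:
    """Conditional probability that gamma_i = 1 given everything else.

    Evaluates rho = |Sigma_1 Sigma_0^{-1}|^{1/2}
    exp{Z'(Sigma_1^{-1} - Sigma_0^{-1})Z / 2} in log space and returns
    (1 + ((1-pi_i)/pi_i) rho)^{-1}.
    """
    if state.c <= 0:
        raise ValueError("c must be > 0")
    g1 = state.gamma.flipped(i, 1)
    g0 = state.gamma.flipped(i, 0)
    s1 = build_sigma(g1, state.c, ds.X, cfg.h, rtol=rtol)
    s0 = build_sigma(g0, state.c, ds.X, cfg.h, rtol=rtol)
    z = np.asarray(state.Z, dtype=float)
    log_rho = 0.5 * (s1.logdet - s0.logdet) + 0.5 * (s1.quad(z) - s0.quad(z))
    if not math.isfinite(log_rho):
        raise FloatingPointError(f"non-finite flip log-ratio for gene {i}")
    pi = cfg.pi_vector(state.gamma.p)[i]
    return float(expit(-(math.log1p(-pi) - math.log(pi) + log_rho)))


def update_gamma(state: ChainState, ds, cfg: ModelConfig, rng,
                 rtol: float = DEFAULT_RTOL) -> GammaVector:
    """One systematic sweep over genes 1..p; returns the new gamma."""
    eng = _Engine(ds.X, ds.Y, cfg, rtol=rtol)
    eng.set_state(state.Z, state.gamma.selected, state.c)
    eng.gamma_sweep(rng)
    return GammaVector.from_selected(sorted(eng.sel), eng.p)


def _default_proposal(eng: _Engine) -> tuple[float, MHProposalConfig]:
    """Mode-centered truncated-normal proposal for c.

    c_opt maximizes the c full conditional over log c in
    [1e-3, 1e6]; the perturbation scale is the Laplace standard
    deviation at the mode (floored at 0.1 c_opt), and the truncation
    keeps the proposal support equal to (1e-6, inf).
    """
    res = minimize_scalar(lambda lc: -eng.log_cond_c(math.exp(lc)),
                          bounds=(_LOGC_LO, _LOGC_HI), method="bounded",
                          options={"xatol": 1e-8})
    c_opt = float(math.exp(res.x))
    dc = 1e-4 * c_opt
    f0 = eng.log_cond_c(c_opt)
    fpp = (eng.log_cond_c(c_opt + dc) - 2.0 * f0 + eng.log_cond_c(c_opt - dc)) / (dc * dc)
    if fpp < 0 and math.isfinite(fpp):
        sd = 1.0 / math.sqrt(-fpp)
    else:
        sd = c_opt
    sd = max(sd, 0.1 * c_opt)
    return c_opt, MHProposalConfig(mu=0.0, sigma=sd, lower=-c_opt + 1e-6, upper=math.inf)


def _mh_c_step(eng: _Engine, rng, proposal: Optional[MHProposalConfig] = None):
    """One MH update of c given the engine's current (Z, gamma)."""
    try:
        if proposal is None:
            c_opt, q = _default_proposal(eng)
        else:
            q = proposal
            # still center the perturbation on the conditional mode
            res = minimize_scalar(lambda lc: -eng.log_cond_c(math.exp(lc)),
                                  bounds=(_LOGC_LO, _LOGC_HI), method="bounded",
                                  options={"xatol": 1e-8})
            c_opt = float(math.exp(res.x))
    except Exception as exc:  # optimizer failure: keep the current value
        logger.warning("c_opt optimization failed (%s); keeping c = %g", exc, eng.c)
        return eng.c, False
    n = eng.n
    if q.heavy_weight > 0.0 and rng.random() < q.heavy_weight:
        # prior-refresh component: c* ~ IG(1/2, n/2)
        c_new = (0.5 * n) / rng.gamma(0.5)
    else:
        c_new = c_opt + _truncnorm_interval(rng, q.mu, q.sigma, q.lower, q.upper)
    if not (c_new > 0 and math.isfinite(c_new)):
        return eng.c, False
    log_q_new = q.log_q(c_new, c_opt, n)
    log_q_old = q.log_q(eng.c, c_opt, n)
    if log_q_old == -math.inf:
        # reverse move has zero proposal density: auto-reject
        return eng.c, False
    log_r = (eng.log_cond_c(c_new) - eng.log_cond_c(eng.c)) + (log_q_old - log_q_new)
    if log_r >= 0 or math.log(rng.random()) < log_r:
        return c_new, True
    return eng.c, False


def update_c(state: ChainState, ds, cfg: ModelConfig, rng,
             proposal: Optional[MHProposalConfig] = None):
    """Metropolis-Hastings update of c; returns (new_c, accepted)."""
    if cfg.fixed_c is not None:
        raise ValueError("update_c called with cfg.fixed_c set")
    eng = _Engine(ds.X, ds.Y, cfg)
    eng.set_state(state.Z, state.gamma.selected, state.c)
    c_new, acc = _mh_c_step(eng, rng, proposal)
    return c_new, acc


# ---------------------------------------------------------------------------

def run_chain(ds, cfg: ModelConfig, n_iter: int, burn_in: int = 12000,
              thin: int = 30, seed: int = 0, init: Optional[ChainState] = None,
              fixed_gamma: Optional[GammaVector] = None,
              proposal: Optional[MHProposalConfig] = None,
              rtol: float = DEFAULT_RTOL, verbose: int = 0) -> ChainResult:
    """Run the three-block chain and return thinned post burn-in draws.

    Parameters
    ----------
    ds : ExpressionDataset
        Standardized training data; both classes must be present.
    cfg : ModelConfig
        Priors (h, pi, optional fixed c).
    n_iter, burn_in, thin : int
        Total sweeps, discarded prefix, and retention stride. The
        defaults (12000 burn-in, every 30th draw) follow the protocol
        used throughout the package's reference analyses; the number
        retained is floor((n_iter - burn_in) / thin).
    seed : int
        Single seed driving all three blocks in a fixed call order;
        identical inputs and seed give bit-identical results.
    init : ChainState, optional
        Starting state. Default: gamma empty (or ``fixed_gamma``),
        c = n (the prior scale), Z_i = +/- 0.5 matching Y_i.
    fixed_gamma : GammaVector, optional
        Hold the selection fixed (used when classifying with an
        already-chosen gene set); skips the gamma sweep.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if not ds.both_classes_present():
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n, p = ds.X.shape
    eng = _Engine(ds.X, ds.Y, cfg, rtol=rtol)

    if init is not None:
        z0, sel0, c0 = np.array(init.Z, float), init.gamma.selected, float(init.c)
    else:
        z0 = np.where(ds.Y == 1, 0.5, -0.5).astype(float)
        sel0 = fixed_gamma.selected if fixed_gamma is not None else []
        c0 = cfg.fixed_c if cfg.fixed_c is not None else float(n)
    if fixed_gamma is not None:
        sel0 = fixed_gamma.selected
    eng.set_state(z0, sel0, c0)

    import time as _time

    draws: list[ChainState] = []
    n_acc = 0
    n_c_updates = 0
    t_start = _time.perf_counter()
    for t in range(1, n_iter + 1):
        eng.z_sweep(rng)
        if fixed_gamma is None:
            eng.gamma_sweep(rng)
        if cfg.fixed_c is None:
            c_new, acc = _mh_c_step(eng, rng, proposal)
            eng.c = c_new
            n_acc += acc
            n_c_updates += 1
        if not (math.isfinite(eng.zz) and math.isfinite(eng.c)):
            raise FloatingPointError(f"non-finite chain state at iteration {t}")
        if t > burn_in and (t - burn_in) % thin == 0:
            draws.append(ChainState(Z=eng.z.copy(),
                                    gamma=GammaVector.from_selected(sorted(eng.sel), p),
                                    c=eng.c, iteration=t))
        if verbose and t % max(1, n_iter // 10) == 0:
            elapsed = _time.perf_counter() - t_start
            logger.info("iteration %d/%d: p_gamma=%d c=%.3g (%.1f ms/sweep, "
                        "c acceptance %.2f)", t, n_iter, len(eng.sel), eng.c,
                        1e3 * elapsed / t, n_acc / max(n_c_updates, 1))
    rate = n_acc / n_c_updates if n_c_updates else 0.0
    if verbose:
        logger.info("c acceptance rate: %.3f", rate)
    return ChainResult(draws=draws, burn_in=burn_in, thin=thin, seed=seed,
                       acceptance_rate_c=rate, n_iter=n_iter,
                       gene_ids=list(getattr(ds, "gene_ids", [])))
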