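"""Predictive classification built on the chain output.

For a new sample the latent utilities (Z, Z_new) are jointly Gaussian
N(0, Sigma_ext) under the marginalized model, with Sigma_ext built on
the (n+1)-row stacked design; each retained draw contributes the exact
Gaussian conditional probability P(Z_new > 0 | Z), and the posterior
predictive is the average of these over draws. The internal
leave-one-out estimate uses the same conditional for Z_i given Z_(-i)
combined through the harmonic-mean identity. The external
leave-one-out protocol redoes the t-statistic prescreen and the
Bayesian selection inside every split, so gene selection never sees
the held-out sample. A classical t-test + maximum-likelihood probit
pipeline is provided as the single-marker-style baseline, consuming
identical splits and seeds so comparisons are paired.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp, ndtr

from .data_io import ExpressionDataset, t_prescreen
from .inference import inclusion_probabilities, select_top
from .model import GammaVector, ModelConfig, orthonormal_column_basis
from .sampler import ChainResult, run_chain

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionResult",
    "predict_proba",
    "loocv_estimate",
    "internal_loocv",
    "external_loocv",
    "ttest_probit_baseline",
]


@dataclass
class PredictionResult:
    """Per-sample predictive probabilities and hard labels.

    ``labels[k]`` is 1 iff ``probabilities[k] >= 0.5`` (an exact tie
    at 0.5 classifies as 1).
    """

    probabilities: np.ndarray
    labels: np.ndarray
    sample_ids: list = field(default_factory=list)

    def to_dataframe(self, truth: Optional[np.ndarray] = None):
        import pandas as pd

        d = {"sample_id": self.sample_ids or list(range(len(self.labels))),
             "probability": self.probabilities, "label": self.labels}
        if truth is not None:
            d["truth"] = np.asarray(truth)
        return pd.DataFrame(d)


def _predictive_draw_probs(res: ChainResult, ds_train: ExpressionDataset,
                           X_new: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """M x n_new matrix of per-draw probabilities P(Y_new=1 | draw)."""
    X = ds_train.X
    n = X.shape[0]
    h = cfg.h
    M = res.M
    Zmat = np.array([st.Z for st in res.draws])     # M x n
    cs = res.c_values()
    sumZ = Zmat.sum(axis=1)
    n_new = X_new.shape[0]
    out = np.empty((M, n_new))

    groups: dict[tuple, list[int]] = {}
    for t, st in enumerate(res.draws):
        groups.setdefault(tuple(st.gamma.selected.tolist()), []).append(t)

    sqrt_h = math.sqrt(h)
    for sel, idx in groups.items():
        sel = np.array(sel, dtype=int)
        Zsub = Zmat[idx]                             # Ms x n
        for k in range(n_new):
            stacked = np.vstack([X[:, sel], X_new[k, sel][None, :]]) if sel.size \
                else np.zeros((n + 1, 0))
            Uext = orthonormal_column_basis(stacked)
            m = Uext.shape[1]
            U1, u2 = Uext[:n], Uext[n]
            s1 = U1.sum(axis=0)
            G1 = U1.T @ U1
            UTZ = (U1.T @ Zsub.T) if m else np.zeros((0, len(idx)))  # m x Ms
            for a, t in enumerate(idx):
                c = cs[t]
                sc = math.sqrt(c)
                # K1 = I + W1'W1 for W1 = [sqrt(h) 1_n, sqrt(c) U1]
                K1 = np.empty((m + 1, m + 1))
                K1[0, 0] = 1.0 + h * n
                K1[0, 1:] = sqrt_h * sc * s1
                K1[1:, 0] = K1[0, 1:]
                K1[1:, 1:] = np.eye(m) + c * G1
                w2 = np.concatenate(([sqrt_h], sc * u2))
                b = np.concatenate(([sqrt_h * sumZ[t]], sc * UTZ[:, a]))
                sol = np.linalg.solve(K1, np.column_stack([b, w2]))
                mean = float(w2 @ sol[:, 0])
                var = 1.0 + float(w2 @ sol[:, 1])
                out[t, k] = float(ndtr(mean / math.sqrt(var)))
    return out


def predict_proba(res: ChainResult, ds_train: ExpressionDataset, X_new,
                  cfg: ModelConfig, sample_ids: Optional[list] = None) -> PredictionResult:
    """Posterior predictive P(Y_new = 1) for held-out expression rows.

    ``X_new`` must already be on the training genes' standardized
    scale, with columns in the training gene order (an
    ``ExpressionDataset`` is accepted and its gene IDs are checked).
    Each retained draw (Z, gamma, c) contributes the exact Gaussian
    conditional P(Z_new > 0 | Z) under the stacked-design covariance;
    the reported probability is the draw average.
    """
    if isinstance(X_new, ExpressionDataset):
        if X_new.gene_ids != ds_train.gene_ids:
            raise ValueError("gene IDs of new data do not match training data")
        sample_ids = sample_ids or list(X_new.sample_ids)
        X_new = X_new.X
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != ds_train.p:
        raise ValueError(
            f"new data has {X_new.shape[1]} genes, training data {ds_train.p}")
    if res.M < 1:
        raise ValueError("empty draw set")
    per_draw = _predictive_draw_probs(res, ds_train, X_new, cfg)
    probs = per_draw.mean(axis=0)
    labels = (probs >= 0.5).astype(np.int64)
    return PredictionResult(probabilities=probs, labels=labels,
                            sample_ids=sample_ids or [f"new{k}" for k in range(len(probs))])


def loocv_estimate(per_draw_probs) -> float:
    """Harmonic mean M / sum_t 1/p_t, computed in log space.

    The importance-sampling identity behind leave-one-out predictive
    probabilities: the reciprocal of the posterior mean of reciprocal
    per-draw predictive probabilities. Any zero entry makes the
    estimate collapse; we return 0 with a warning in that case.
    """
    p = np.asarray(per_draw_probs, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one per-draw probability")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero per-draw probability; harmonic-mean estimate is 0")
        return 0.0
    return float(np.exp(math.log(p.size) - logsumexp(-np.log(p))))


def internal_loocv(res: ChainResult, ds: ExpressionDataset, cfg: ModelConfig):
    """Leave-one-out predictive probabilities from a single chain.

    For each draw, P(Y_i | Y_(-i)) is the probability that Z_i falls
    on the observed side of zero under its Gaussian conditional given
    Z_(-i); draws are combined with the harmonic-mean estimator.

    Returns
    -------
    (error_rate, accuracy, probs) where ``probs[i]`` estimates
    p(Y_i = observed | Y_(-i), X).
    """
    from .model import build_sigma

    n = ds.n
    M = res.M
    per_draw = np.empty((M, n))
    for t, st in enumerate(res.draws):
        op = build_sigma(st.gamma, st.c, ds.X, cfg.h)
        A = op.precision_factor()
        lam = 1.0 - np.einsum("ij,ij->i", A, A)
        z = st.Z
        lz = z - A @ (A.T @ z)          # Lambda z
        mean = z - lz / lam
        sd = np.sqrt(1.0 / lam)
        p1 = ndtr(mean / sd)
        per_draw[t] = np.where(ds.Y == 1, p1, 1.0 - p1)
    probs = np.array([loocv_estimate(per_draw[:, i]) for i in range(n)])
    # correct iff the observed label keeps predictive mass > 1/2;
    # an exact tie classifies as label 1
    correct = np.where(probs > 0.5, True, np.where(probs < 0.5, False, ds.Y == 1))
    error = 1.0 - correct.mean()
    return float(error), float(correct.mean()), probs


_DEFAULT_SPLIT_CHAIN = dict(n_iter=12000, burn_in=2000, thin=10)
_DEFAULT_REFIT_CHAIN = dict(n_iter=3500, burn_in=1000, thin=5)


def external_loocv(ds: ExpressionDataset, cfg: ModelConfig, p_star: int,
                   prescreen_k: int = 50, chain_params: Optional[dict] = None,
                   seed: int = 0, refit_params: Optional[dict] = None):
    """External leave-one-out protocol with in-split gene screening.

    For every sample: (i) remove it; (ii) rank genes by |t| on the
    remaining samples and keep the top ``prescreen_k`` as the starting
    set; (iii) run the selection chain and keep the ``p_star`` genes
    with the highest inclusion probabilities; (iv) classify the
    removed sample with those genes via the Bayesian predictive.
    The per-split chains use shorter defaults (burn-in 2000, thin 10,
    1000 retained draws) than a full analysis; override through
    ``chain_params``.

    Returns
    -------
    (error_rate, accuracy, records) with one dict per sample.
    """
    if ds.n < 3:
        raise ValueError("need n >= 3 for leave-one-out")
    chain_params = {**_DEFAULT_SPLIT_CHAIN, **(chain_params or {})}
    refit_params = {**_DEFAULT_REFIT_CHAIN, **(refit_params or {})}
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=(ds.n, 2))
    records = []
    n_err = 0
    for i in range(ds.n):
        keep = np.r_[0:i, i + 1:ds.n]
        train = ds.subset_samples(keep)
        if not train.both_classes_present():
            raise ValueError(f"leaving out sample {i} empties one class")
        k = min(prescreen_k, train.p)
        screen = t_prescreen(train, k)
        ds_k = train.subset_genes(screen)
        res = run_chain(ds_k, cfg, seed=int(seeds[i, 0]), **chain_params)
        ranking = inclusion_probabilities(res)
        top_local = select_top(ranking, min(p_star, ds_k.p))
        genes = screen[top_local]
        ds_sel = train.subset_genes(genes)
        res2 = run_chain(ds_sel, cfg, seed=int(seeds[i, 1]),
                         fixed_gamma=GammaVector.from_selected(range(len(genes)), len(genes)),
                         **refit_params)
        pred = predict_proba(res2, ds_sel, ds.X[i:i + 1, genes], cfg,
                             sample_ids=[ds.sample_ids[i]])
        wrong = int(pred.labels[0]) != int(ds.Y[i])
        n_err += wrong
        records.append({
            "sample_id": ds.sample_ids[i],
            "truth": int(ds.Y[i]),
            "probability": float(pred.probabilities[0]),
            "label": int(pred.labels[0]),
            "selected_genes": [ds.gene_ids[j] for j in genes],
        })
    error = n_err / ds.n
    return float(error), float(1.0 - error), records


def _fit_probit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ML probit coefficients (with intercept), ridge fallback.

    Uses the standard maximum-likelihood fit; on perfect separation or
    non-convergence, falls back to a lightly L2-penalized fit so a
    usable decision rule always comes back.
    """
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Probit(y, Xc).fit(disp=0, maxiter=200)
            if fit.mle_retvals.get("converged", False) and np.all(np.isfinite(fit.params)) \
                    and np.max(np.abs(fit.params)) < 1e4:
                return np.asarray(fit.params)
        except Exception:
            pass
    logger.warning("probit ML fit failed or separated; using ridge-stabilized fit")
    return _ridge_probit(Xc, y)


def _ridge_probit(Xc: np.ndarray, y: np.ndarray, alpha: float = 1e-2) -> np.ndarray:
    from scipy.optimize import minimize
    from scipy.stats import norm

    q = 2.0 * y - 1.0

    def nll(beta):
        eta = np.clip(q * (Xc @ beta), -30, 30)
        return -np.sum(norm.logcdf(eta)) + 0.5 * alpha * beta @ beta

    res = minimize(nll, np.zeros(Xc.shape[1]), method="BFGS",
                   options={"maxiter": 500})
    return res.x


def ttest_probit_baseline(ds: ExpressionDataset, p_star: int,
                          test: Optional[ExpressionDataset] = None,
                          loocv: bool = False, equal_var: bool = True):
    """Single-marker-style baseline: top-|t| genes into an ML probit.

    Selects the ``p_star`` genes with the largest two-sample |t|,
    fits a maximum-likelihood probit on them, and classifies at
    probability 0.5. With ``loocv`` the screen and fit are redone
    inside every leave-one-out split; with ``test`` the fit from the
    full training data classifies the test set; otherwise
    training-resubstitution error is reported.

    Returns (error_rate, accuracy).
    """
    import statsmodels.api as sm

    if loocv:
        if test is not None:
            raise ValueError("choose either loocv or a test set, not both")
        n_err = 0
        for i in range(ds.n):
            keep = np.r_[0:i, i + 1:ds.n]
            train = ds.subset_samples(keep)
            genes = t_prescreen(train, p_star, equal_var=equal_var)
            beta = _fit_probit(train.X[:, genes], train.Y)
            eta = beta[0] + ds.X[i, genes] @ beta[1:]
            label = int(ndtr(eta) >= 0.5)
            n_err += label != int(ds.Y[i])
        error = n_err / ds.n
        return float(error), float(1.0 - error)

    genes = t_prescreen(ds, p_star, equal_var=equal_var)
    beta = _fit_probit(ds.X[:, genes], ds.Y)
    target = test if test is not None else ds
    if test is not None and test.gene_ids != ds.gene_ids:
        raise ValueError("gene IDs of test data do not match training data")
    eta = beta[0] + target.X[:, genes] @ beta[1:]
    labels = (ndtr(eta) >= 0.5).astype(np.int64)
    error = float(np.mean(labels != target.Y))
    return error, 1.0 - error
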