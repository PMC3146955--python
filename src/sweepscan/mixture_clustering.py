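"""Univariate normal mixture models for locus-wise F_ST posterior means.

A K-component mixture is fitted by expectation-maximization, restarted from
jittered quantile-based initializations, and the number of components is
chosen by the Akaike information criterion with 3K - 1 free parameters
(K means, K variances, K - 1 weights):

    AIC = 2 (3K - 1) - 2 loglik.

Components are reported sorted by decreasing mean, so "the first cluster" is
the fraction of loci with the largest F_ST values.  A variance floor guards
against the degenerate spike-likelihood divergence of Gaussian mixtures.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm


@dataclasses.dataclass
class MixtureFit:
    K: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    aic: float
    n: int
    assignments: np.ndarray          # MAP component per observation
    responsibilities: np.ndarray     # (n, K) posterior membership
    loglik_trace: list[float]
    converged: bool
    identifiable: bool = True


def _log_density(x: np.ndarray, w, mu, var) -> np.ndarray:
    """(n, K) matrix of log w_k + log N(x | mu_k, var_k)."""
    return np.log(w)[None, :] + norm.logpdf(x[:, None], mu[None, :],
                                            np.sqrt(var)[None, :])


def _em_once(x: np.ndarray, w, mu, var, tol: float, max_iter: int,
             var_floor: float):
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        log_r = _log_density(x, w, mu, var)
        ll_obs = logsumexp(log_r, axis=1)
        ll = float(ll_obs.sum())
        if trace and ll < trace[-1] - 1e-8:
            raise RuntimeError("EM log-likelihood decreased")  # must not happen
        trace.append(ll)
        r = np.exp(log_r - ll_obs[:, None])
        nk = r.sum(axis=0)
        w = nk / x.size
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
        if prev > -np.inf and abs(ll - prev) <= tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = ll
    log_r = _log_density(x, w, mu, var)
    ll = float(logsumexp(log_r, axis=1).sum())
    trace.append(max(ll, trace[-1]))
    return w, mu, var, trace, converged


def em_fit(values, K: int, seed: int = 0, n_restarts: int = 10,
           tol: float = 1e-8, max_iter: int = 500,
           var_floor: float = 1e-6) -> MixtureFit:
    """Maximum-likelihood K-component normal mixture via EM, best of
    ``n_restarts`` jittered quantile initializations."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    if x.size < 3 * K:
        raise ValueError(f"need n >= 3K observations (n={x.size}, K={K})")
    identifiable = True
    if np.ptp(x) == 0 and K > 1:
        identifiable = False
        warnings.warn("all values identical; K > 1 mixture is not identifiable")

    rng = np.random.default_rng(seed)
    sd = x.std() if x.std() > 0 else 1.0
    best = None
    for _ in range(max(1, n_restarts)):
        q = np.linspace(0, 1, K + 2)[1:-1]
        mu0 = np.quantile(x, q) + rng.normal(0, 0.1 * sd, size=K)
        var0 = np.full(K, max(x.var() / K, var_floor))
        w0 = np.full(K, 1.0 / K)
        w, mu, var, trace, conv = _em_once(x, w0, mu0, var0, tol, max_iter,
                                           var_floor)
        if best is None or trace[-1] > best[3][-1]:
            best = (w, mu, var, trace, conv)
    w, mu, var, trace, conv = best

    order = np.argsort(-mu)  # canonical: decreasing mean
    w, mu, var = w[order], mu[order], var[order]
    log_r = _log_density(x, w, mu, var)
    resp = np.exp(log_r - logsumexp(log_r, axis=1)[:, None])
    ll = float(logsumexp(log_r, axis=1).sum())
    k_free = 3 * K - 1
    return MixtureFit(K=K, weights=w, means=mu, variances=var, loglik=ll,
                      aic=2.0 * k_free - 2.0 * ll, n=x.size,
                      assignments=resp.argmax(axis=1), responsibilities=resp,
                      loglik_trace=trace, converged=conv,
                      identifiable=identifiable)


def aic(fit: MixtureFit) -> float:
    """Akaike information criterion with 3K - 1 free parameters."""
    return 2.0 * (3 * fit.K - 1) - 2.0 * fit.loglik


def select_K(values, K_max: int = 7, seed: int = 0,
             **em_kwargs) -> tuple[MixtureFit, "np.ndarray"]:
    """Fit K = 1..K_max and return the minimum-AIC fit plus the AIC table
    (columns K, loglik, aic).  AIC ties break toward smaller K."""
    import pandas as pd

    x = np.asarray(values, dtype=float)
    if x.size < 3 * K_max:
        K_max = max(1, x.size // 3)
        warnings.warn(f"too few observations; lowering K_max to {K_max}")
    fits = [em_fit(x, K, seed=seed + K, **em_kwargs)
            for K in range(1, K_max + 1)]
    table = pd.DataFrame({"K": [f.K for f in fits],
                          "loglik": [f.loglik for f in fits],
                          "aic": [f.aic for f in fits]})
    best = min(fits, key=lambda f: (f.aic, f.K))
    return best, table


def first_cluster_count(fit: MixtureFit) -> int:
    """Number of observations MAP-assigned to the highest-mean component."""
    count = int((fit.assignments == 0).sum())  # components sorted by mean desc
    if count == 0:
        warnings.warn("highest-mean component is empty after MAP assignment")
    return count
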