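"""Two-replicate reproducibility model: Gaussian copula mixture EM.

Replicate p-values are converted to scores (-log p), rank-transformed to
pseudo-normal values through the current mixture marginal, and fit with a
two-component bivariate normal mixture: an independent standard-normal
noise component and a correlated signal component with mean (mu, mu),
shared sd sigma and correlation rho. The local irreproducible discovery
rate of a feature is the posterior probability of the noise component; the
global rate at rank r is the running mean of the top-r local values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.stats import rankdata

log = logging.getLogger(__name__)


@dataclass
class IdrParams:
    pi1: float  # reproducible fraction
    mu: float
    sigma: float
    rho: float
    converged: bool
    n_iter: int
    degenerate: bool = False


@dataclass
class IdrResult:
    feature_id: str
    bait: str
    local_idr: float
    global_idr: float
    params: IdrParams = field(repr=False, default=None)


def _pseudo_values(u: np.ndarray, pi1: float, mu: float, sigma: float) -> np.ndarray:
    """Invert the mixture marginal CDF at the ECDF values."""
    lo = min(-6.0, mu - 6.0 * sigma)
    hi = max(6.0, mu + 6.0 * sigma)
    grid = np.linspace(lo, hi, 4096)
    cdf = (1.0 - pi1) * stats.norm.cdf(grid) + pi1 * stats.norm.cdf(
        (grid - mu) / sigma
    )
    return np.interp(u, cdf, grid)


def _loglik_terms(z1, z2, pi1, mu, sigma, rho):
    f0 = stats.norm.logpdf(z1) + stats.norm.logpdf(z2)
    s2 = sigma**2
    det = s2**2 * (1 - rho**2)
    d1, d2 = z1 - mu, z2 - mu
    quad = (d1**2 - 2 * rho * d1 * d2 + d2**2) / (s2 * (1 - rho**2))
    f1 = -np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * quad
    return f0, f1


def fit_idr(
    pvalues_rep1: np.ndarray,
    pvalues_rep2: np.ndarray,
    feature_ids: Optional[Sequence[str]] = None,
    bait: str = "",
    max_iter: int = 500,
    tol: float = 1e-6,
) -> Dict[str, IdrResult]:
    """Fit the copula mixture to two replicates' p-values.

    Scores are -log p (larger = stronger); the fit depends on the scores
    only through their ranks (ties get average rank). Returns one result
    per feature keyed by feature id.
    """
    p1 = np.asarray(pvalues_rep1, dtype=float)
    p2 = np.asarray(pvalues_rep2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("replicate p-value vectors differ in length")
    n = p1.size
    if feature_ids is None:
        feature_ids = [str(i) for i in range(n)]
    s1 = -np.log(np.maximum(p1, 1e-300))
    s2 = -np.log(np.maximum(p2, 1e-300))
    if np.ptp(s1) == 0 or np.ptp(s2) == 0:
        raise ValueError("degenerate input: all scores tied in a replicate")
    u1 = rankdata(s1, method="average") / (n + 1)
    u2 = rankdata(s2, method="average") / (n + 1)

    def em_step(z1, z2, pi1, mu, sigma, rho):
        f0, f1 = _loglik_terms(z1, z2, pi1, mu, sigma, rho)
        log_w1 = np.log(pi1) + f1
        log_w0 = np.log(1 - pi1) + f0
        m = np.maximum(log_w0, log_w1)
        gamma = np.exp(log_w1 - m) / (np.exp(log_w0 - m) + np.exp(log_w1 - m))
        g = gamma.sum()
        new_pi1 = float(np.clip(g / n, 1e-4, 1 - 1e-4))
        new_mu = float((gamma * (z1 + z2)).sum() / (2 * g))
        d1, d2 = z1 - new_mu, z2 - new_mu
        new_s2 = float((gamma * (d1**2 + d2**2)).sum() / (2 * g))
        new_sigma = float(np.sqrt(max(new_s2, 1e-6)))
        new_rho = float(
            np.clip((gamma * d1 * d2).sum() / (g * new_s2), -0.999, 0.999)
        )
        return new_pi1, new_mu, new_sigma, new_rho

    pi1, mu, sigma, rho = 0.5, 1.0, 1.0, 0.5
    converged = False
    total_iter = 0
    outer_tol = max(tol, 1e-4)
    for _ in range(50):  # outer: refresh pseudo-values at current marginal
        z1 = _pseudo_values(u1, pi1, mu, sigma)
        z2 = _pseudo_values(u2, pi1, mu, sigma)
        prev_outer = (pi1, mu, sigma, rho)
        inner_converged = False
        while total_iter < max_iter:  # inner: EM at fixed pseudo-values
            total_iter += 1
            new = em_step(z1, z2, pi1, mu, sigma, rho)
            delta = max(abs(a - b) for a, b in zip(new, (pi1, mu, sigma, rho)))
            pi1, mu, sigma, rho = new
            if delta < tol:
                inner_converged = True
                break
        outer_delta = max(
            abs(a - b) for a, b in zip((pi1, mu, sigma, rho), prev_outer)
        )
        if inner_converged and outer_delta < outer_tol:
            converged = True
            break
        if total_iter >= max_iter:
            break
    it = total_iter
    if not converged:
        log.warning("IDR EM did not converge after %d iterations", total_iter)

    # A "reproducible" component that is uncorrelated (or unshifted) is
    # indistinguishable from noise: the fit found no reproducible signal.
    degenerate = rho < 0.2 or mu < 0.2
    if degenerate:
        log.warning(
            "IDR fit degenerate (mu=%.3f, rho=%.3f); no reproducible signal",
            mu, rho,
        )
        local = np.ones(n)
    else:
        z1 = _pseudo_values(u1, pi1, mu, sigma)
        z2 = _pseudo_values(u2, pi1, mu, sigma)
        f0, f1 = _loglik_terms(z1, z2, pi1, mu, sigma, rho)
        log_w1 = np.log(pi1) + f1
        log_w0 = np.log(1 - pi1) + f0
        m = np.maximum(log_w0, log_w1)
        local = np.exp(log_w0 - m) / (np.exp(log_w0 - m) + np.exp(log_w1 - m))

    order = np.argsort(local, kind="mergesort")
    global_sorted = np.cumsum(local[order]) / np.arange(1, n + 1)
    glob = np.empty(n)
    glob[order] = global_sorted

    params = IdrParams(pi1, mu, sigma, rho, converged, it, degenerate)
    return {
        fid: IdrResult(fid, bait, float(local[i]), float(glob[i]), params)
        for i, fid in enumerate(feature_ids)
    }
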