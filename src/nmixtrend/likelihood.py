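"""The binomial mixture probability kernel.

The hierarchy at one site-year: a latent super-population size
N ~ Poisson(lambda), and, conditional on N, each of J replicate visits
records y_j ~ Binomial(N, p_j) independently.  The marginal likelihood of
the observed visit vector sums N out from max(y) to a truncation bound K:

    L = sum_{N=max(y)}^{K} Poisson(N; lambda) * prod_j Binomial(y_j; N, p_j)

lambda uses a log link, detection a logit link.  All sums run in log space
(log-sum-exp) and pmfs go through log-gamma, so counts in the observed range
(0-51) and K around 150 are far from underflow.

:func:`site_marginal_loglik` is a transparent NumPy reference used in tests
and small computations; :func:`dataset_loglik` routes through the compiled
kernels in :mod:`nmixtrend._kernels` for fitting.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, logsumexp

from . import _kernels
from .design import DesignMatrices

__all__ = [
    "expected_abundance",
    "detection_prob",
    "site_marginal_loglik",
    "dataset_loglik",
    "default_truncation",
    "TruncationError",
]

_P_EPS = 1e-12

#: default truncation margin above the maximum observed count
DEFAULT_K_MARGIN = 100


class TruncationError(ValueError):
    """K is below an observed count, or the Poisson sum cannot be truncated."""


def default_truncation(max_count: int, margin: int = DEFAULT_K_MARGIN) -> int:
    """Default upper summation bound K = max observed count + margin."""
    return int(max_count) + int(margin)


def expected_abundance(beta: np.ndarray, x_row: np.ndarray) -> float | np.ndarray:
    """Expected super-population size lambda = exp(x . beta); log link.

    Accepts a single design row or a 2-d array of rows.
    """
    x = np.asarray(x_row, dtype=float)
    with np.errstate(over="ignore"):
        lam = np.exp(x @ np.asarray(beta, dtype=float))
    if not np.all(np.isfinite(lam)):
        raise OverflowError("expected abundance overflowed; check coefficients/design scale")
    return lam


def detection_prob(alpha: np.ndarray, w_row: np.ndarray) -> float | np.ndarray:
    """Per-visit detection probability p = logistic(w . alpha), clamped off 0/1."""
    w = np.asarray(w_row, dtype=float)
    p = expit(w @ np.asarray(alpha, dtype=float))
    return np.clip(p, _P_EPS, 1.0 - _P_EPS)


def site_marginal_loglik(lam: float, p: np.ndarray, y: np.ndarray, K: int) -> float:
    """Log marginal likelihood of one site-year's visit vector.

    Parameters
    ----------
    lam : Poisson mean of the latent abundance (> 0).
    p : per-visit detection probabilities; entries for missing visits may be
        anything as long as the matching ``y`` entry is ``np.nan``.
    y : per-visit counts; ``np.nan`` marks a missing visit, which simply
        drops out of the binomial product.
    K : truncation bound; must be >= max observed count.
    """
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), _P_EPS, 1.0 - _P_EPS)
    obs = ~np.isnan(y)
    yo = y[obs].astype(int)
    po = p[obs]
    ymax = int(yo.max()) if yo.size else 0
    if ymax > K:
        raise TruncationError(f"max observed count {ymax} exceeds K={K}; increase K")
    if lam <= 0:
        raise ValueError("lam must be > 0")

    n = np.arange(ymax, K + 1)
    log_pois = n * np.log(lam) - lam - gammaln(n + 1)
    log_binom = np.zeros_like(log_pois)
    for yj, pj in zip(yo, po):
        log_binom += (
            gammaln(n + 1)
            - gammaln(yj + 1)
            - gammaln(n - yj + 1)
            + yj * np.log(pj)
            + (n - yj) * np.log1p(-pj)
        )
    return float(logsumexp(log_pois + log_binom))


def _prepare_arrays(y: np.ndarray, mask: np.ndarray, K: int):
    """Shared precomputation for the compiled kernels."""
    ymax = np.where(mask, y, 0).max(axis=1).astype(np.int64)
    if ymax.max(initial=0) > K:
        raise TruncationError(f"max observed count {ymax.max()} exceeds K={K}; increase K")
    lgam = gammaln(np.arange(K + 2, dtype=float))
    binco = _kernels.precompute_binco(
        np.ascontiguousarray(y, dtype=np.int64),
        np.ascontiguousarray(mask, dtype=np.bool_),
        ymax,
        lgam,
        K,
    )
    return ymax, lgam, binco


class MarginalLikelihood:
    """Reusable marginal-likelihood evaluator bound to one dataset layout.

    Precomputes the count-only tables once, then evaluates the total log
    likelihood for any (beta, alpha) pair — and optionally transect random
    effects — via the compiled kernels.
    """

    def __init__(self, dm: DesignMatrices, y: np.ndarray, mask: np.ndarray, K: int):
        self.dm = dm
        self.K = int(K)
        self.y = np.ascontiguousarray(y, dtype=np.int64)
        self.mask = np.ascontiguousarray(mask, dtype=np.bool_)
        self.ymax, self.lgam, self.binco = _prepare_arrays(self.y, self.mask, self.K)
        self._site_ll = np.empty(y.shape[0])
        self._c0 = np.empty(y.shape[0])
        self._c1 = np.empty(y.shape[0])

    def loglik(self, beta: np.ndarray, alpha: np.ndarray, b_site: np.ndarray | None = None) -> float:
        """Total log likelihood; ``b_site`` is an optional per-site-year offset."""
        eta = self.dm.X @ beta
        if b_site is not None:
            eta = eta + b_site
        wlin = np.einsum("sjq,q->sj", self.dm.W, alpha)
        _kernels.det_consts(wlin, self.y, self.mask, self._c0, self._c1)
        total = _kernels.site_logliks(
            np.ascontiguousarray(eta, dtype=float),
            self._c0,
            self._c1,
            self.ymax,
            self.binco,
            self.lgam,
            self.K,
            self._site_ll,
        )
        return float(total)

    def site_logliks(self, beta, alpha, b_site=None) -> np.ndarray:
        self.loglik(beta, alpha, b_site)
        return self._site_ll.copy()


def dataset_loglik(theta: np.ndarray, dm: DesignMatrices, y: np.ndarray, mask: np.ndarray, K: int) -> float:
    """Total log likelihood of a dataset under packed parameters.

    ``theta`` concatenates the abundance coefficients (matching
    ``dm.x_columns``) and detection coefficients (matching ``dm.w_columns``).
    Sites enter independently, so the value is the sum of per-site marginals.
    """
    px = len(dm.x_columns)
    ml = MarginalLikelihood(dm, y, mask, K)
    return ml.loglik(np.asarray(theta[:px], float), np.asarray(theta[px:], float))
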