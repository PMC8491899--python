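"""Zero-inflated log-normal feature marginals.

Each microbial feature's (unobserved) absolute abundance follows a
zero-inflated log-normal law: the feature is absent (exactly zero) with
probability ``pi`` and, when present, its log abundance is Normal(mu, sigma^2).
This module holds the parameter container and the vectorised CDF / quantile /
density primitives that everything else (copula mapping, likelihood, EM)
is built from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

__all__ = [
    "FeatureMarginal",
    "zi_lognormal_cdf",
    "zi_lognormal_quantile",
    "ziln_cdf",
    "ziln_quantile",
    "ziln_logpdf_nonzero",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class FeatureMarginal:
    """Parameters of one feature's zero-inflated log-normal marginal.

    Parameters
    ----------
    feature_id : str
        Feature label (taxon, gene, pathway ...).
    pi : float
        Probability of biological absence, ``0 <= pi < 1``.
    mu : float
        Mean of the log non-zero absolute abundance (log units; only
        identified up to an additive constant shared across features).
    sigma : float
        Standard deviation of the log non-zero abundance, ``> 0``.
    """

    feature_id: str
    pi: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi < 1.0):
            raise ValueError(
                f"pi must be in [0, 1); got {self.pi!r} for {self.feature_id!r}"
            )
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite; got {self.mu!r}")
        if not (self.sigma > 0.0 and np.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive and finite; got {self.sigma!r}")


def ziln_cdf(a, pi, mu, sigma):
    """Vectorised CDF of the zero-inflated log-normal distribution.

    ``P(A <= a) = pi + (1 - pi) * Phi((log a - mu) / sigma)`` for ``a > 0``
    and ``pi`` at ``a == 0``.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundance must be non-negative")
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore"):
        z = (np.log(np.where(a > 0, a, 1.0)) - mu) / sigma
    out = pi + (1.0 - pi) * ndtr(z)
    return np.where(a > 0, out, pi + np.zeros_like(out))


def ziln_quantile(u, pi, mu, sigma):
    """Vectorised quantile (inverse CDF): 0 below the absence mass ``pi``,
    ``exp(mu + sigma * Phi^-1((u - pi) / (1 - pi)))`` above it."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("probability must be in [0, 1)")
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    v = (u - pi) / (1.0 - pi)
    with np.errstate(invalid="ignore"):
        q = np.exp(mu + sigma * ndtri(np.clip(v, 0.0, 1.0)))
    return np.where(u < pi, 0.0, q)


def ziln_logpdf_nonzero(a, pi, mu, sigma):
    """Log density of the continuous (non-zero) branch:
    ``log(1 - pi) + log phi((log a - mu)/sigma) - log(a * sigma)``."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("non-zero branch density requires a > 0")
    la = np.log(a)
    z = (la - mu) / sigma
    return np.log1p(-np.asarray(pi, dtype=float)) - 0.5 * z * z - _LOG_SQRT_2PI - la - np.log(sigma)


def zi_lognormal_cdf(a: float, marginal: FeatureMarginal) -> float:
    """CDF of one feature's zero-inflated log-normal marginal at ``a >= 0``."""
    return float(ziln_cdf(a, marginal.pi, marginal.mu, marginal.sigma))


def zi_lognormal_quantile(u: float, marginal: FeatureMarginal) -> float:
    """Quantile of one feature's marginal at probability ``u`` in [0, 1)."""
    return float(ziln_quantile(u, marginal.pi, marginal.mu, marginal.sigma))


def latent_gaussian_from_abundance(a, pi, mu, sigma, clip: float = 8.0):
    """Latent Gaussian score ``g = Phi^-1(F(a))`` for non-zero abundances.

    Clipped to ``+/- clip`` to keep downstream linear algebra finite when a
    value sits in the extreme tail of its fitted marginal.
    """
    u = ziln_cdf(a, pi, mu, sigma)
    return np.clip(ndtri(np.clip(u, 1e-300, 1 - 1e-16)), -clip, clip)


def log_ndtr_stable(x):
    """Alias of :func:`scipy.special.log_ndtr` (kept for symmetry of imports)."""
    return log_ndtr(x)
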