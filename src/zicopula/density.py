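"""Copula density machinery.

Implements the joint law of absolute abundances A = (A_1 ... A_p) under the
Gaussian copula with zero-inflated log-normal marginals:

* ``gaussian_to_abundance`` — the deterministic map from latent Gaussian
  scores g to abundances, A_j = F_j^{-1}(Phi(g_j)).
* ``log_density_absolute`` — log f_A at a mixed zero/non-zero vector. Over
  the non-zero coordinates this is the copula density times the Jacobian
  product of marginal densities; the zero coordinates contribute the
  probability of the latent orthant {g_j <= Phi^{-1}(pi_j)} conditional on
  the non-zero scores, evaluated by quasi-Monte Carlo (Genz) or, cheaply,
  by a one-pass conditional-independence approximation.
* ``sample_total_abundance_moments`` — the scalar integral over the latent
  total absolute abundance A^Sigma that turns f_A into the likelihood of an
  observed relative-abundance vector, plus the posterior moments of
  log A^Sigma needed by the EM fitter. Gauss-Legendre quadrature on
  log A^Sigma, centred on a Laplace-style independence approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import log_ndtr, logsumexp, ndtr, ndtri

from .marginals import ziln_cdf, ziln_logpdf_nonzero, ziln_quantile
from .model import CommunityModel

__all__ = [
    "gaussian_to_abundance",
    "log_density_absolute",
    "sample_total_abundance_moments",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_GCLIP = 8.0  # latent-score clip; Phi(+-8) is within 1e-15 of {0,1}


def gaussian_to_abundance(g: np.ndarray, model: CommunityModel) -> np.ndarray:
    """Map latent Gaussian scores to abundances, elementwise per feature.

    ``A_j = 0`` exactly when ``Phi(g_j) < pi_j``; otherwise
    ``A_j = F_j^{-1}(Phi(g_j))`` on the log-normal branch.
    """
    g = np.asarray(g, dtype=float)
    if g.shape[-1] != model.p:
        raise ValueError(f"g has dimension {g.shape[-1]}, model has p={model.p}")
    if not np.all(np.isfinite(g)):
        raise ValueError("g must be finite")
    u = ndtr(g)
    # Phi(g) can round to 1.0 in float; the quantile domain is [0, 1)
    u = np.minimum(u, 1.0 - 1e-16)
    return ziln_quantile(u, model.pi, model.mu, model.sigma)


@dataclass
class _ZeroBlocks:
    """Conditional structure of the zero-coordinate latent block given the
    non-zero block, for a fixed zero/non-zero pattern."""

    L_nn: np.ndarray  # cholesky (lower) of corr over non-zero coords
    W: np.ndarray  # regression of zero block on non-zero scores
    S_cond: np.ndarray  # conditional covariance of zero block
    s_cond: np.ndarray  # sqrt of its diagonal
    logdet_nn: float


def _zero_blocks(corr: np.ndarray, nz: np.ndarray, z: np.ndarray) -> _ZeroBlocks:
    R_nn = corr[np.ix_(nz, nz)]
    L = cholesky(R_nn, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    if z.size:
        R_zn = corr[np.ix_(z, nz)]
        W = cho_solve((L, True), R_zn.T).T  # R_zn R_nn^{-1}
        S = corr[np.ix_(z, z)] - W @ R_zn.T
        S = 0.5 * (S + S.T)
        s = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    else:
        W = np.zeros((0, nz.size))
        S = np.zeros((0, 0))
        s = np.zeros(0)
    return _ZeroBlocks(L_nn=L, W=W, S_cond=S, s_cond=s, logdet_nn=logdet)


def _mvn_logpdf_chol(g: np.ndarray, L: np.ndarray, logdet: float) -> np.ndarray:
    """MVN(0, R) log density for rows of ``g`` given R's cholesky."""
    w = solve_triangular(L, g.T, lower=True)
    quad = np.einsum("ij,ij->j", w, w)
    m = g.shape[1]
    return -0.5 * quad - 0.5 * logdet - m * _LOG_SQRT_2PI


def log_density_absolute(
    a: np.ndarray,
    model: CommunityModel,
    n_mc: int = 4096,
    seed: int | None = 0,
    orthant: str = "qmc",
) -> float:
    """Log joint density log f_A of an absolute-abundance vector.

    Exact (closed form) when every coordinate is non-zero; otherwise the
    zero coordinates contribute a conditional Gaussian orthant probability,
    estimated by quasi-Monte Carlo with ``n_mc`` points (``orthant="qmc"``)
    or by the product of univariate conditional normal CDFs
    (``orthant="conditional"``).
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (model.p,):
        raise ValueError(f"a has shape {a.shape}; expected ({model.p},)")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    pi, mu, sigma = model.pi, model.mu, model.sigma
    corr = model.copula.corr
    nz = np.flatnonzero(a > 0)
    z = np.flatnonzero(a == 0)
    if np.any(pi[z] == 0):
        return -np.inf  # a structural zero under a never-absent marginal

    total = 0.0
    if nz.size:
        u = ziln_cdf(a[nz], pi[nz], mu[nz], sigma[nz])
        g = np.clip(ndtri(np.clip(u, 1e-300, 1 - 1e-16)), -_GCLIP, _GCLIP)
        blocks = _zero_blocks(corr, nz, z)
        copula_ll = float(_mvn_logpdf_chol(g[None, :], blocks.L_nn, blocks.logdet_nn)[0])
        marg_ll = float(ziln_logpdf_nonzero(a[nz], pi[nz], mu[nz], sigma[nz]).sum())
        phi_ll = float((-0.5 * g * g - _LOG_SQRT_2PI).sum())
        total += copula_ll + marg_ll - phi_ll
        if z.size:
            c = ndtri(pi[z])
            m_cond = blocks.W @ g
            if orthant == "conditional" or z.size == 1:
                total += float(log_ndtr((c - m_cond) / blocks.s_cond).sum())
            else:
                rng = np.random.default_rng(seed)
                pz = stats.multivariate_normal.cdf(
                    c, mean=m_cond, cov=blocks.S_cond, maxpts=int(n_mc), rng=rng,
                    allow_singular=True,
                )
                total += float(np.log(np.clip(pz, 1e-300, None)))
    else:
        # fully absent sample: plain orthant probability under the copula
        c = ndtri(pi)
        if model.p == 1:
            total += float(log_ndtr(c[0]))
        elif orthant == "conditional":
            total += float(log_ndtr(c).sum())  # independence approximation
        else:
            total += _qmc_orthant(c, corr, n_mc, seed)
    return total


def _qmc_orthant(c, corr, n_mc, seed) -> float:
    rng = np.random.default_rng(seed)
    pz = stats.multivariate_normal.cdf(
        c, mean=np.zeros(len(c)), cov=corr, maxpts=int(n_mc), rng=rng,
        allow_singular=True,
    )
    return float(np.log(np.clip(pz, 1e-300, None)))


def _leggauss_cache():
    cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def get(n: int):
        if n not in cache:
            cache[n] = np.polynomial.legendre.leggauss(n)
        return cache[n]

    return get


_leggauss = _leggauss_cache()


def sample_total_abundance_moments(
    x: np.ndarray,
    model: CommunityModel,
    n_nodes: int = 64,
    blocks: _ZeroBlocks | None = None,
    nz: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Likelihood and posterior moments of t = log A^Sigma for one sample.

    Given a relative-abundance vector ``x`` (summing to 1), integrates the
    joint density of A = A^Sigma * x over the latent total A^Sigma,
    returning ``(loglik, E[t], E[t^2])`` where the expectation is under the
    conditional law of t given x. The integral uses ``n_nodes``-point
    Gauss-Legendre quadrature on t over mean +/- 8 SD of an independence
    (Laplace-style) Gaussian approximation, re-centred once if the mass
    touches the window boundary. Zero coordinates enter through the
    conditional-independence orthant approximation, which keeps the EM
    inner loop tractable.
    """
    x = np.asarray(x, dtype=float)
    pi, mu, sigma = model.pi, model.mu, model.sigma
    if nz is None:
        nz = np.flatnonzero(x > 0)
    z = np.setdiff1d(np.arange(model.p), nz, assume_unique=True)
    if nz.size == 0:
        raise ValueError("sample has no non-zero features")
    if np.any(pi[z] == 0):
        return -np.inf, np.nan, np.nan
    if blocks is None:
        blocks = _zero_blocks(model.copula.corr, nz, z)

    logx = np.log(x[nz])
    mu_nz, sg_nz, pi_nz = mu[nz], sigma[nz], pi[nz]
    prec = (1.0 / sg_nz**2).sum()
    mean0 = ((mu_nz - logx) / sg_nz**2).sum() / prec
    sd0 = max(np.sqrt(1.0 / prec), 1e-3)
    c_z = ndtri(pi[z]) if z.size else None

    nodes0, weights0 = _leggauss(n_nodes)

    def evaluate(center: float, half_width: float):
        t = center + half_width * nodes0
        logw = np.log(weights0 * half_width)
        la = t[:, None] + logx[None, :]  # K x m
        zst = (la - mu_nz) / sg_nz
        u = pi_nz + (1.0 - pi_nz) * ndtr(zst)
        g = np.clip(ndtri(np.clip(u, 1e-300, 1 - 1e-16)), -_GCLIP, _GCLIP)
        jac = (
            np.log1p(-pi_nz) - 0.5 * zst * zst - _LOG_SQRT_2PI - la - np.log(sg_nz)
        ).sum(axis=1)
        copula_ll = _mvn_logpdf_chol(g, blocks.L_nn, blocks.logdet_nn)
        phi_ll = (-0.5 * g * g - _LOG_SQRT_2PI).sum(axis=1)
        logh = copula_ll + jac - phi_ll + nz.size * t
        if z.size:
            m_cond = g @ blocks.W.T
            logh = logh + log_ndtr((c_z[None, :] - m_cond) / blocks.s_cond).sum(axis=1)
        return t, logw, logh

    center, half_width = mean0, 8.0 * sd0
    for _ in range(2):
        t, logw, logh = evaluate(center, half_width)
        lw = logw + logh
        if not np.any(np.isfinite(lw)):
            raise FloatingPointError("non-finite conditional density of log A^Sigma")
        loglik = logsumexp(lw)
        w = np.exp(lw - loglik)
        et = float(w @ t)
        et2 = float(w @ (t * t))
        peak = int(np.argmax(lw))
        if 1 < peak < n_nodes - 2:
            break
        # posterior mass touches the window edge: re-centre and widen
        center, half_width = et, 1.5 * half_width
    et2 = max(et2, et * et)  # guard quadrature round-off
    return float(loglik), et, et2
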