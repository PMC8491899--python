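"""Forward simulation of synthetic communities.

Layers, in generative order: latent Gaussian scores g ~ MVN(0, R); absolute
abundances A through the zero-inflated log-normal quantile map; relative
abundances X = A / sum(A); integer sequencing depths D from a log-normal;
counts C ~ Multinomial(D, X) per sample.

Also houses the "new feature" machinery: a three-dimensional Gaussian
kernel density estimate over transformed per-feature parameter triplets
(logit pi, mu, log sigma), resampled to invent features that share the
ecological characteristics (prevalence, abundance, variability) of a
fitted community.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit, ndtr

from .marginals import FeatureMarginal, ziln_quantile
from .model import CommunityModel

__all__ = [
    "SimulationResult",
    "simulate",
    "empirical_zero_rates",
    "NewFeatureGenerator",
    "build_new_feature_generator",
    "simulate_new_features",
]

_MAX_RESAMPLE = 100


@dataclass
class SimulationResult:
    """All layers of one simulated community (n samples x p features)."""

    latent_g: np.ndarray
    absolute: np.ndarray
    relabund: np.ndarray
    depths: np.ndarray
    counts: np.ndarray
    seed: int
    feature_ids: list[str]

    @property
    def n(self) -> int:
        return self.latent_g.shape[0]

    @property
    def p(self) -> int:
        return self.latent_g.shape[1]

    def counts_table(self):
        from .table import FeatureTable

        return FeatureTable(
            feature_ids=list(self.feature_ids),
            sample_ids=[f"sample_{i:05d}" for i in range(self.n)],
            values=self.counts.T,
            kind="counts",
        )

    def relabund_table(self):
        from .table import FeatureTable

        return FeatureTable(
            feature_ids=list(self.feature_ids),
            sample_ids=[f"sample_{i:05d}" for i in range(self.n)],
            values=self.relabund.T,
            kind="relabund",
        )


def _simulate_layers(
    model: CommunityModel,
    pi_matrix: np.ndarray,
    mu_matrix: np.ndarray,
    n: int,
    seed: int,
) -> SimulationResult:
    """Shared sampler: base simulation and spike-in simulation differ only
    in whether (pi, mu) vary by sample, so both route through here and are
    bit-identical at equal seed when the parameters coincide."""
    p = model.p
    sigma = model.sigma
    root = np.random.SeedSequence(seed)
    # independent child streams so adding samples or layers never perturbs
    # earlier draws
    rng_g, rng_d, rng_c = (np.random.default_rng(s) for s in root.spawn(3))

    chol = np.linalg.cholesky(model.copula.corr)
    g = rng_g.standard_normal((n, p)) @ chol.T
    u = np.minimum(ndtr(g), 1.0 - 1e-16)
    absolute = ziln_quantile(u, pi_matrix, mu_matrix, sigma)
    row_sums = absolute.sum(axis=1)
    for _ in range(_MAX_RESAMPLE + 1):
        dead = np.flatnonzero(row_sums == 0)
        if dead.size == 0:
            break
        g_new = rng_g.standard_normal((dead.size, p)) @ chol.T
        g[dead] = g_new
        u = np.minimum(ndtr(g_new), 1.0 - 1e-16)
        absolute[dead] = ziln_quantile(u, pi_matrix[dead], mu_matrix[dead], sigma)
        row_sums = absolute.sum(axis=1)
    else:
        raise RuntimeError("samples kept drawing all-absent communities")

    relabund = absolute / row_sums[:, None]
    depths = np.maximum(
        np.rint(np.exp(rng_d.normal(model.depth.mu_D, model.depth.sigma_D, size=n))),
        1.0,
    ).astype(np.int64)
    counts = rng_c.multinomial(depths, relabund)
    return SimulationResult(
        latent_g=g,
        absolute=absolute,
        relabund=relabund,
        depths=depths,
        counts=counts,
        seed=seed,
        feature_ids=model.feature_ids,
    )


def simulate(model: CommunityModel, n: int, seed: int = 0) -> SimulationResult:
    """Draw ``n`` samples from the community model; fully reproducible
    given ``seed``."""
    if n < 1:
        raise ValueError("n must be positive")
    pi = np.broadcast_to(model.pi, (n, model.p))
    mu = np.broadcast_to(model.mu, (n, model.p))
    return _simulate_layers(model, pi, mu, n, seed)


def empirical_zero_rates(result: SimulationResult) -> np.ndarray:
    """Per-feature fraction of zero counts (biological + technical zeros)."""
    return (result.counts == 0).mean(axis=0)


@dataclass
class NewFeatureGenerator:
    """Gaussian KDE over per-feature parameter triplets on the transformed
    scale (logit pi, mu, log sigma)."""

    training_triplets: np.ndarray  # k x 3
    bandwidth: np.ndarray  # 3 x 3 positive definite (diagonal by default)
    seed: int

    def __post_init__(self) -> None:
        self.training_triplets = np.atleast_2d(
            np.asarray(self.training_triplets, dtype=float)
        )
        self.bandwidth = np.asarray(self.bandwidth, dtype=float)
        if np.linalg.eigvalsh(self.bandwidth).min() <= 0:
            raise ValueError("bandwidth must be positive definite")


def build_new_feature_generator(
    model: CommunityModel, seed: int = 0, n_fit: int | None = None
) -> NewFeatureGenerator:
    """Assemble the KDE from a fitted model's (pi, mu, sigma) triplets.

    Bandwidth by the per-dimension normal-reference (Scott) rule for a
    3-D diagonal Gaussian kernel. Boundary pi values are clamped away from
    {0, 1} before the logit (with a warning); ``n_fit`` — the sample size
    behind the fit — sets the clamp 1/(2 n_fit).
    """
    if model.p < 4:
        raise ValueError("need at least 4 features to estimate the triplet KDE")
    pi, mu, sigma = model.pi, model.mu, model.sigma
    eps = 1.0 / (2.0 * n_fit) if n_fit else 1e-3
    if np.any(pi < eps) or np.any(pi > 1 - eps):
        warnings.warn(
            f"clamping boundary absence probabilities to [{eps:g}, {1 - eps:g}] "
            "before the logit transform",
            stacklevel=2,
        )
        pi = np.clip(pi, eps, 1 - eps)
    triplets = np.column_stack([logit(pi), mu, np.log(sigma)])
    k, d = triplets.shape
    sd = triplets.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1e-3)
    h = sd * (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * k ** (-1.0 / (d + 4.0))
    return NewFeatureGenerator(
        training_triplets=triplets, bandwidth=np.diag(h**2), seed=seed
    )


def simulate_new_features(
    gen: NewFeatureGenerator, p_new: int, seed: int | None = None
) -> list[FeatureMarginal]:
    """Sample ``p_new`` new feature marginals from the KDE (mixture-of-
    Gaussians sampling: training point uniformly at random plus kernel
    noise), back-transformed to (pi, mu, sigma)."""
    if p_new < 1:
        raise ValueError("p_new must be positive")
    rng = np.random.default_rng(gen.seed if seed is None else seed)
    k = gen.training_triplets.shape[0]
    idx = rng.integers(0, k, size=p_new)
    chol = np.linalg.cholesky(gen.bandwidth)
    noise = rng.standard_normal((p_new, 3)) @ chol.T
    samples = gen.training_triplets[idx] + noise
    out = []
    for i, (lp, m, ls) in enumerate(samples):
        out.append(
            FeatureMarginal(
                feature_id=f"new_{i:04d}",
                pi=float(expit(lp)),
                mu=float(m),
                sigma=float(np.exp(ls)),
            )
        )
    return out
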