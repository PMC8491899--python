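"""Ground-truth model generators for testing and demonstration.

The regimes are qualitative, engineering stand-ins for well-known community
archetypes: ``gut_like`` (moderate zero-inflation, broad log-abundance
spread, sparse weak correlation), ``vaginal_like`` (a few near-always-
present dominant features that exclude each other) and ``dense_small``
(tiny p with strong, known correlation structure for oracle tests). The
parameter ranges are documented defaults, not fits to any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CommunityModel, CopulaCorrelation, DepthModel, cov_to_corr
from .simulate import SimulationResult, simulate
from .table import FeatureTable

__all__ = ["FixtureSpec", "make_model", "make_template_table"]

REGIMES = ("gut_like", "vaginal_like", "dense_small")


@dataclass
class FixtureSpec:
    p: int = 50
    n: int = 500
    regime: str = "gut_like"
    correlation_sparsity: float = 0.05
    depth_mean_log: float = float(np.log(2e4))
    depth_sd_log: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if not (0 <= self.correlation_sparsity <= 1):
            raise ValueError("correlation_sparsity must be in [0, 1]")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")


def _sparse_precision(p: int, sparsity: float, rng, low=0.15, high=0.35) -> np.ndarray:
    """Sparse symmetric precision matrix, PD by diagonal dominance."""
    omega = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    n_off = iu[0].size
    k = int(round(sparsity * n_off))
    if k:
        chosen = rng.choice(n_off, size=k, replace=False)
        vals = rng.uniform(low, high, size=k) * rng.choice([-1.0, 1.0], size=k)
        omega[iu[0][chosen], iu[1][chosen]] = vals
    omega = omega + omega.T
    np.fill_diagonal(omega, 1.0 + np.abs(omega).sum(axis=1))
    return omega


def make_model(spec: FixtureSpec) -> CommunityModel:
    """Deterministic (seeded) ground-truth community model for a regime."""
    rng = np.random.default_rng(spec.seed)
    p = spec.p
    depth = DepthModel(spec.depth_mean_log, spec.depth_sd_log)

    if spec.regime == "dense_small":
        if p > 10:
            raise ValueError("dense_small is for p <= 10 oracle tests")
        pi = rng.uniform(0.1, 0.5, size=p)
        mu = rng.normal(0.0, 1.0, size=p)
        sigma = rng.uniform(0.5, 1.2, size=p)
        corr = np.eye(p)
        # strong, known pairwise structure for sign-recovery checks
        if p >= 2:
            corr[0, 1] = corr[1, 0] = 0.6
        if p >= 4:
            corr[2, 3] = corr[3, 2] = -0.5
        w, v = np.linalg.eigh(corr)
        corr = cov_to_corr((v * np.maximum(w, 1e-3)) @ v.T)
        copula = CopulaCorrelation.from_corr(corr)
    elif spec.regime == "gut_like":
        pi = rng.uniform(0.2, 0.8, size=p)
        mu = rng.uniform(-1.5, 1.5, size=p)  # ~3 log-units of spread
        sigma = rng.uniform(0.5, 1.5, size=p)
        omega = _sparse_precision(p, spec.correlation_sparsity, rng)
        copula = CopulaCorrelation.from_corr(np.linalg.inv(omega))
    else:  # vaginal_like: a few dominants with mutual exclusion
        n_dom = max(2, min(3, p // 5))
        pi = np.concatenate(
            [rng.uniform(0.0, 0.04, size=n_dom), rng.uniform(0.5, 0.95, size=p - n_dom)]
        )
        mu = np.concatenate(
            [rng.uniform(3.0, 5.0, size=n_dom), rng.normal(-1.0, 1.0, size=p - n_dom)]
        )
        sigma = np.concatenate(
            [rng.uniform(0.8, 1.5, size=n_dom), rng.uniform(0.5, 1.5, size=p - n_dom)]
        )
        omega = _sparse_precision(p, spec.correlation_sparsity, rng)
        corr = cov_to_corr(np.linalg.inv(omega))
        for a in range(n_dom):
            for b in range(a + 1, n_dom):
                corr[a, b] = corr[b, a] = -0.6 / (n_dom - 1)
        w, v = np.linalg.eigh(corr)
        corr = cov_to_corr((v * np.maximum(w, 1e-3)) @ v.T)
        copula = CopulaCorrelation.from_corr(corr)

    mu = mu - mu.mean()
    feature_ids = [f"feature_{j:04d}" for j in range(p)]
    return CommunityModel.from_arrays(feature_ids, pi, mu, sigma, copula, depth)


def make_template_table(
    spec: FixtureSpec,
) -> tuple[CommunityModel, FeatureTable, SimulationResult]:
    """Ground-truth model plus a counts table simulated from it."""
    model = make_model(spec)
    sim = simulate(model, spec.n, seed=spec.seed + 1)
    return model, sim.counts_table(), sim
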