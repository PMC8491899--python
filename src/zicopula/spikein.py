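"""Controlled association spike-in.

Known feature-covariate associations are injected by shifting per-sample
marginal parameters on the *absolute* abundance scale:

* abundance: ``mu_ij = mu_j + Z_i' beta_abundance`` (log fold changes);
* prevalence: presence log-odds shifted by ``Z_i' beta_prevalence``
  (log odds ratios of the feature being present).

Spiking absolute abundances keeps "true" and null features cleanly
defined; compositional effects then propagate into relative abundances on
their own. Feature-feature correlations are spiked through a hidden
standard-normal covariate shared by a pair of features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import CommunityModel
from .simulate import SimulationResult, _simulate_layers
from .table import FeatureTable

__all__ = [
    "SpikeinConfig",
    "PerSampleParams",
    "apply_spikein",
    "simulate_spiked",
    "select_spike_features",
    "spike_feature_pair",
]


@dataclass
class SpikeinConfig:
    """Covariate design and sparse per-feature effect maps.

    ``design`` is samples x covariates; effect frames are features x
    covariates (missing entries mean zero effect) in log fold-change
    (abundance) and log odds-ratio (prevalence) units.
    """

    design: pd.DataFrame
    abundance_effects: pd.DataFrame | None = None
    prevalence_effects: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.abundance_effects is None:
            self.abundance_effects = pd.DataFrame(index=[], columns=self.design.columns)
        if self.prevalence_effects is None:
            self.prevalence_effects = pd.DataFrame(index=[], columns=self.design.columns)
        for name, eff in (
            ("abundance", self.abundance_effects),
            ("prevalence", self.prevalence_effects),
        ):
            unknown = set(eff.columns) - set(self.design.columns)
            if unknown:
                raise ValueError(f"{name} effects reference unknown covariates {unknown}")
            if not np.all(np.isfinite(eff.fillna(0.0).to_numpy(dtype=float))):
                raise ValueError(f"{name} effects must be finite")

    @property
    def n(self) -> int:
        return self.design.shape[0]


@dataclass
class PerSampleParams:
    """Sample-specific marginal parameters produced by a spike-in."""

    mu_matrix: np.ndarray  # n x p
    pi_matrix: np.ndarray  # n x p
    base_model: CommunityModel

    def __post_init__(self) -> None:
        if self.mu_matrix.shape != self.pi_matrix.shape:
            raise ValueError("mu and pi matrices must have the same shape")
        if self.mu_matrix.shape[1] != self.base_model.p:
            raise ValueError("parameter matrices do not match the model dimension")
        if np.any(self.pi_matrix < 0) or np.any(self.pi_matrix >= 1):
            raise ValueError("pi entries must lie in [0, 1)")


def _effect_matrix(eff: pd.DataFrame, feature_ids: list[str], covariates) -> np.ndarray:
    """Dense p x q effect matrix from a sparse effect frame."""
    out = np.zeros((len(feature_ids), len(covariates)))
    if eff is None or eff.empty:
        return out
    unknown = set(eff.index) - set(feature_ids)
    if unknown:
        raise ValueError(f"effects reference unknown features {sorted(unknown)}")
    aligned = eff.reindex(index=feature_ids, columns=covariates).fillna(0.0)
    return aligned.to_numpy(dtype=float)


def apply_spikein(model: CommunityModel, config: SpikeinConfig) -> PerSampleParams:
    """Build per-sample (pi, mu) matrices from the base model and the
    linear spike-in predictors."""
    z = config.design.to_numpy(dtype=float)  # n x q
    feature_ids = model.feature_ids
    beta_a = _effect_matrix(config.abundance_effects, feature_ids, config.design.columns)
    beta_p = _effect_matrix(config.prevalence_effects, feature_ids, config.design.columns)

    mu_matrix = model.mu[None, :] + z @ beta_a.T

    pi = model.pi
    pi_matrix = np.broadcast_to(pi, (config.n, model.p)).copy()
    spiked_prev = np.flatnonzero(np.any(beta_p != 0, axis=1))
    if spiked_prev.size:
        zero_pi = pi[spiked_prev] == 0
        if np.any(zero_pi):
            bad = [feature_ids[j] for j in spiked_prev[zero_pi]]
            raise ValueError(
                f"prevalence spike-in undefined for never-absent features {bad} "
                "(presence log-odds infinite)"
            )
        # presence log-odds: log((1 - pi)/pi) + Z' beta
        base_logodds = np.log((1 - pi[spiked_prev]) / pi[spiked_prev])
        shifted = base_logodds[None, :] + z @ beta_p[spiked_prev].T
        pi_matrix[:, spiked_prev] = 1.0 - expit(shifted)
    return PerSampleParams(mu_matrix=mu_matrix, pi_matrix=pi_matrix, base_model=model)


def simulate_spiked(params: PerSampleParams, seed: int = 0) -> SimulationResult:
    """Simulate with sample-specific marginals; identical to the base
    sampler (bit-for-bit at equal seed) when no effect is active."""
    n = params.mu_matrix.shape[0]
    return _simulate_layers(
        params.base_model, params.pi_matrix, params.mu_matrix, n, seed
    )


def _prevalence_and_abundance(obj) -> tuple[list[str], np.ndarray, np.ndarray]:
    if isinstance(obj, FeatureTable):
        if obj.p == 0:
            raise ValueError("empty table")
        prev = obj.prevalence()
        vals = obj.values
        with np.errstate(invalid="ignore"):
            mean_nz = np.where(
                (vals > 0).any(axis=1),
                np.array(
                    [vals[j][vals[j] > 0].mean() if (vals[j] > 0).any() else 0.0
                     for j in range(obj.p)]
                ),
                0.0,
            )
        return list(obj.feature_ids), prev, mean_nz
    if isinstance(obj, CommunityModel):
        prev = 1.0 - obj.pi
        mean_nz = np.exp(obj.mu + 0.5 * obj.sigma**2)
        return list(obj.feature_ids), prev, mean_nz
    raise TypeError("expected a FeatureTable or CommunityModel")


def select_spike_features(
    table_or_model,
    fraction: float,
    mode: str = "most_prevalent",
    rounding: str = "ceil",
) -> list[str]:
    """Deterministically pick features to spike.

    ``most_prevalent`` ranks by prevalence descending; ``prevalence_near_half``
    by |prevalence - 0.5| ascending. Ties break by mean non-zero abundance
    (descending), then feature ID. ``rounding`` chooses between
    ceil(fraction * p) (default) and floor (minimum 1).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ids, prev, mean_nz = _prevalence_and_abundance(table_or_model)
    if not ids:
        raise ValueError("empty table")
    if mode == "most_prevalent":
        primary = -prev
    elif mode == "prevalence_near_half":
        primary = np.abs(prev - 0.5)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    k = math.ceil(fraction * len(ids)) if rounding == "ceil" else max(
        1, math.floor(fraction * len(ids))
    )
    order = sorted(range(len(ids)), key=lambda j: (primary[j], -mean_nz[j], ids[j]))
    return [ids[j] for j in order[:k]]


def spike_feature_pair(
    model: CommunityModel,
    j1: str,
    j2: str,
    beta: float,
    direction: str = "positive",
    n: int = 1000,
    seed: int = 0,
) -> tuple[SpikeinConfig, PerSampleParams]:
    """Correlate a pair of features through a hidden standard-normal
    covariate, with matched abundance and prevalence effects of size
    ``beta`` (sign flipped for ``j2`` when ``direction="negative"``)."""
    if j1 == j2:
        raise ValueError("need two distinct features")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    rng = np.random.default_rng(seed)
    covariate = f"hidden_{j1}_{j2}"
    design = pd.DataFrame({covariate: rng.standard_normal(n)},
                          index=[f"sample_{i:05d}" for i in range(n)])
    sign2 = 1.0 if direction == "positive" else -1.0
    eff_a = pd.DataFrame({covariate: [beta, sign2 * beta]}, index=[j1, j2])
    pi = dict(zip(model.feature_ids, model.pi))
    eff_p = eff_a.copy()
    if beta != 0 and (pi[j1] == 0 or pi[j2] == 0):
        raise ValueError("prevalence spike-in undefined for never-absent features")
    if beta == 0:
        eff_a = eff_p = None
    config = SpikeinConfig(design=design, abundance_effects=eff_a, prevalence_effects=eff_p)
    return config, apply_spikein(model, config)
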