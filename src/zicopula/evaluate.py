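"""Realism and recovery statistics.

Bray-Curtis dissimilarity and PERMANOVA R^2 summarise how distinguishable
two sets of community profiles are; the two-sample Kolmogorov-Smirnov
statistic compares single-feature abundance distributions; the recovery
regressions estimate spiked-in effect sizes back from simulated data; and
the power grid runs a spike -> simulate -> test -> adjust loop across
effect sizes and sample sizes for benchmarking association tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .model import CommunityModel
from .simulate import SimulationResult, simulate
from .spikein import SpikeinConfig, apply_spikein, select_spike_features, simulate_spiked

__all__ = [
    "DistanceMatrix",
    "bray_curtis",
    "bray_curtis_matrix",
    "permanova_r2",
    "ks_statistic",
    "recover_abundance_effect",
    "recover_prevalence_effect",
    "PowerGridResult",
    "run_power_grid",
    "default_abundance_test",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two abundance
    vectors; 0 for identical vectors, 1 for disjoint supports."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(profiles: np.ndarray, labels=None) -> DistanceMatrix:
    """Pairwise Bray-Curtis over samples (rows of ``profiles``)."""
    profiles = np.asarray(profiles, dtype=float)
    if labels is None:
        labels = [f"sample_{i:05d}" for i in range(profiles.shape[0])]
    d = squareform(pdist(profiles, metric="braycurtis"))
    return DistanceMatrix(labels=list(labels), values=np.nan_to_num(d))


def permanova_r2(d: DistanceMatrix, groups, n_permutations: int = 0, seed: int = 0):
    """PERMANOVA R^2: share of distance-based variability between groups.

    Uses the classical partition ``R^2 = (SS_T - SS_W) / SS_T`` with
    ``SS_T = (1/n) sum_{i<j} d_ij^2`` and within-group sums analogously per
    group. A single group returns 0 by convention. When
    ``n_permutations > 0`` a permutation p-value for the R^2 statistic is
    returned alongside.
    """
    groups = np.asarray(groups)
    n = len(d.labels)
    if groups.shape[0] != n:
        raise ValueError("groups must label every sample")
    d2 = d.values**2

    def _r2(gr) -> float:
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for g in np.unique(gr):
            idx = np.flatnonzero(gr == g)
            if idx.size > 1:
                sub = d2[np.ix_(idx, idx)]
                ss_w += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        if ss_t <= 0:
            return 0.0
        return max((ss_t - ss_w) / ss_t, 0.0)

    if np.unique(groups).size < 2:
        return (0.0, 1.0) if n_permutations else 0.0
    r2 = _r2(groups)
    if not n_permutations:
        return r2
    rng = np.random.default_rng(seed)
    hits = sum(
        _r2(rng.permutation(groups)) >= r2 for _ in range(n_permutations)
    )
    return r2, (hits + 1) / (n_permutations + 1)


def ks_statistic(x, y) -> float:
    """Two-sample Kolmogorov-Smirnov statistic: the largest absolute
    difference between the two empirical CDFs (zeros count as values)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(x, y, method="asymp").statistic)


def recover_abundance_effect(
    result: SimulationResult, z, feature_id: str, alpha: float = 0.05
) -> tuple[float, float, float]:
    """OLS estimate (with normal-theory CI) of the log fold change of a
    feature's non-zero relative abundances against covariate ``z``."""
    z = np.asarray(z, dtype=float)
    j = result.feature_ids.index(feature_id)
    vals = result.relabund[:, j]
    mask = vals > 0
    strata = np.unique(z) if np.unique(z).size <= 2 else None
    if strata is not None:
        for s in strata:
            if (mask & (z == s)).sum() < 3:
                raise ValueError(
                    f"feature {feature_id!r} has fewer than 3 non-zero "
                    f"observations in stratum {s!r}"
                )
    elif mask.sum() < 6:
        raise ValueError(f"feature {feature_id!r} has too few non-zero observations")
    y = np.log(vals[mask])
    X = sm.add_constant(z[mask])
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=alpha)[1]
    return float(fit.params[1]), float(ci[0]), float(ci[1])


def recover_prevalence_effect(
    result: SimulationResult, z, feature_id: str, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Logistic-regression estimate (with CI) of the presence log odds
    ratio of a feature against covariate ``z``."""
    z = np.asarray(z, dtype=float)
    j = result.feature_ids.index(feature_id)
    present = (result.relabund[:, j] > 0).astype(float)
    for s in np.unique(z) if np.unique(z).size <= 2 else []:
        sub = present[z == s]
        if sub.min() == sub.max():
            raise ValueError(
                f"feature {feature_id!r} lacks both presence and absence in "
                f"stratum {s!r}; a larger sample size may be needed"
            )
    X = sm.add_constant(z)
    try:
        fit = sm.Logit(present, X).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise ValueError(
            f"logistic fit failed for feature {feature_id!r} (separation?); "
            f"try a larger sample size: {err}"
        ) from err
    ci = fit.conf_int(alpha=alpha)[1]
    return float(fit.params[1]), float(ci[0]), float(ci[1])


def default_abundance_test(counts: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Built-in per-feature association test for the benchmarking harness:
    OLS of log(relative abundance + half the minimum positive value) on the
    covariate; returns one p-value per feature."""
    counts = np.asarray(counts, dtype=float)  # n x p
    totals = counts.sum(axis=1, keepdims=True)
    rel = counts / np.where(totals > 0, totals, 1.0)
    positive = rel[rel > 0]
    pseudo = 0.5 * (positive.min() if positive.size else 1e-6)
    y = np.log(rel + pseudo)
    n, p = y.shape
    zc = z - z.mean()
    denom = (zc**2).sum()
    beta = y.T @ zc / denom
    resid = y - np.outer(z, beta) - (y.mean(axis=0) - z.mean() * beta)
    dof = n - 2
    se = np.sqrt((resid**2).sum(axis=0) / dof / denom)
    tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    return 2.0 * stats.t.sf(np.abs(tstat), dof)


@dataclass
class PowerGridResult:
    """Raw per-replicate rows and per-cell summaries of the power grid."""

    rows: pd.DataFrame
    summary: pd.DataFrame


def run_power_grid(
    model: CommunityModel,
    effect_sizes,
    sample_sizes,
    n_reps: int = 50,
    spike_fraction: float = 0.05,
    test=None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    mode: str = "most_prevalent",
    seed: int = 0,
) -> PowerGridResult:
    """Spike -> simulate -> test -> adjust, across a grid of effect sizes
    and sample sizes.

    Per replicate, half the selected features get +effect and half -effect
    on abundance against a balanced binary covariate (effect 0 skips the
    spike entirely); power is the detected fraction of spiked features and
    FDR the false-discovery share among discoveries (0 when none).
    """
    test = test or default_abundance_test
    features = select_spike_features(model, spike_fraction, mode=mode)
    k = len(features)
    pos, neg = features[: (k + 1) // 2], features[(k + 1) // 2:]
    feature_ids = model.feature_ids
    spiked_idx = np.array([feature_ids.index(f) for f in features])
    root = np.random.SeedSequence(seed)
    rows = []
    for effect in effect_sizes:
        for n in sample_sizes:
            for rep in range(n_reps):
                child = np.random.SeedSequence(
                    entropy=root.entropy,
                    spawn_key=(int(round(effect * 1000)) % (2**20), int(n), rep),
                )
                rep_seed = int(child.generate_state(1)[0] % (2**31))
                try:
                    z = np.zeros(n)
                    z[n // 2:] = 1.0
                    if effect == 0:
                        sim = simulate(model, n, seed=rep_seed)
                    else:
                        design = pd.DataFrame(
                            {"z": z}, index=[f"sample_{i:05d}" for i in range(n)]
                        )
                        eff = pd.DataFrame(
                            {"z": [effect] * len(pos) + [-effect] * len(neg)},
                            index=pos + neg,
                        )
                        params = apply_spikein(
                            model, SpikeinConfig(design=design, abundance_effects=eff)
                        )
                        sim = simulate_spiked(params, seed=rep_seed)
                    pvals = np.asarray(test(sim.counts, z), dtype=float)
                    method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
                    reject = multipletests(pvals, alpha=alpha, method=method)[0]
                    detected = reject[spiked_idx].sum()
                    discoveries = reject.sum()
                    false_disc = discoveries - detected if effect != 0 else discoveries
                    power = detected / k
                    fdr = false_disc / max(1, discoveries)
                    rows.append(
                        dict(effect_size=effect, sample_size=n, replicate=rep,
                             power=power, fdr=fdr)
                    )
                except Exception:
                    rows.append(
                        dict(effect_size=effect, sample_size=n, replicate=rep,
                             power=np.nan, fdr=np.nan)
                    )
    df = pd.DataFrame(rows)
    grp = df.groupby(["effect_size", "sample_size"])
    summary = grp.agg(
        mean_power=("power", "mean"),
        se_power=("power", "sem"),
        mean_fdr=("fdr", "mean"),
        se_fdr=("fdr", "sem"),
    ).reset_index()
    return PowerGridResult(rows=df, summary=summary)
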