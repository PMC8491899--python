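"""Penalized EM estimation of the community model.

The likelihood of an observed relative-abundance vector integrates the
copula density of absolute abundances over the latent total A^Sigma. The
fitter alternates:

E-step
    For each sample, quadrature over t = log A^Sigma yields the sample
    log-likelihood and posterior moments E[t], E[t^2]; latent Gaussian
    scores are filled in deterministically for non-zero features and by
    one-pass conditional truncated-normal moments for zero features.
M-step
    pi is the empirical zero fraction and never updated; mu and sigma have
    closed-form weighted Gaussian maximizers over the non-zero entries
    (mu re-centred to sum to zero — the identifiability constraint);
    the latent precision matrix is re-estimated by graphical lasso on the
    expected latent second-moment matrix, with the L1 penalty applied to
    off-diagonals only.

The penalty weight lambda is chosen by K-fold cross-validation on mean
held-out log-likelihood. The public entry point is
:class:`CommunityProfileModel` (statsmodels-style: construct from data,
call ``fit``, get a results object).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri
from sklearn.covariance import graphical_lasso

from .density import _zero_blocks, sample_total_abundance_moments
from .marginals import latent_gaussian_from_abundance
from .model import CommunityModel, CopulaCorrelation, DepthModel, cov_to_corr
from .table import FeatureTable

__all__ = [
    "FitConfig",
    "EStepState",
    "FitResult",
    "CommunityProfileModel",
    "CommunityFitResult",
    "normalize_counts",
    "estimate_pi",
    "initialize_params",
    "e_step",
    "m_step",
    "fit_em",
    "cross_validate_lambda",
    "fit_depth",
]

_SIGMA_FLOOR = 1e-3
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class FitConfig:
    """Tuning knobs of the penalized EM fit.

    ``lambda_grid`` defaults to 10 log-spaced values on
    [0.01, 1] * sqrt(log p / n), the usual graphical-lasso scale.
    """

    lambda_grid: list[float] | None = None
    n_folds: int = 5
    max_iter: int = 100
    tol: float = 1e-4
    quadrature_nodes: int = 64
    seed: int = 0
    cv_max_iter: int = 25  # EM cap inside each CV fold fit

    def __post_init__(self) -> None:
        if self.lambda_grid is not None:
            if len(self.lambda_grid) == 0 or any(l <= 0 for l in self.lambda_grid):
                raise ValueError("lambda_grid must be non-empty and strictly positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.max_iter < 1 or self.tol <= 0 or self.quadrature_nodes < 2:
            raise ValueError("invalid max_iter / tol / quadrature_nodes")

    def resolved_grid(self, p: int, n: int) -> np.ndarray:
        if self.lambda_grid is not None:
            return np.asarray(sorted(self.lambda_grid), dtype=float)
        scale = np.sqrt(np.log(max(p, 2)) / max(n, 2))
        return np.geomspace(0.01, 1.0, 10) * scale


@dataclass
class EStepState:
    """Per-sample expected sufficient statistics from one E-step."""

    exp_t: np.ndarray  # E[log A^Sigma | x_i]
    exp_t2: np.ndarray  # E[(log A^Sigma)^2 | x_i]
    gbar: np.ndarray  # n x p latent scores (observed / truncated-conditional mean)
    gvar: np.ndarray  # n x p latent variances (non-zero entries: 0)
    loglik: np.ndarray  # per-sample log f_X at current parameters

    def __post_init__(self) -> None:
        if np.any(self.exp_t2 + 1e-8 < self.exp_t**2):
            raise ValueError("second moments must dominate squared first moments")


@dataclass
class FitResult:
    """Outcome of the penalized EM fit."""

    model: CommunityModel
    lambda_selected: float
    objective_trace: list[float]
    n_iter: int
    converged: bool
    cv_table: pd.DataFrame | None = None


def normalize_counts(table: FeatureTable) -> FeatureTable:
    """Divide each sample column by its total, the multinomial MLE of the
    relative abundances."""
    if table.kind == "relabund":
        return table
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"cannot normalize all-zero sample(s): {[table.sample_ids[i] for i in zero]}"
        )
    return FeatureTable(
        feature_ids=list(table.feature_ids),
        sample_ids=list(table.sample_ids),
        values=table.values / sums,
        kind="relabund",
    )


def estimate_pi(table: FeatureTable) -> np.ndarray:
    """Per-feature empirical zero fraction (absence probability).

    Identified directly because a zero relative abundance occurs exactly
    when the latent absolute abundance is zero.
    """
    return (table.values == 0).mean(axis=1)


def fit_depth(depths) -> DepthModel:
    """Maximum-likelihood log-normal fit of per-sample sequencing depths."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0 or np.any(depths <= 0):
        raise ValueError("depths must be positive")
    logd = np.log(depths)
    return DepthModel(mu_D=float(logd.mean()), sigma_D=float(logd.std(ddof=0)))


def initialize_params(table: FeatureTable, ridge: float = 0.1) -> CommunityModel:
    """Moment-based starting values: a multivariate log-normal fit on the
    non-zero relative abundances, plus a shrunk latent-score correlation."""
    table = normalize_counts(table)
    if table.p < 2:
        raise ValueError("need at least 2 features")
    x = table.values.T  # n x p
    n, p = x.shape
    present = x > 0
    n_present = present.sum(axis=0)
    bad = np.flatnonzero(n_present < 2)
    if bad.size:
        raise ValueError(
            "features non-zero in fewer than 2 samples: "
            f"{[table.feature_ids[i] for i in bad]}"
        )
    pi = estimate_pi(table)
    if np.any(pi >= 1.0):
        raise ValueError("never-present features must be dropped before fitting")

    logx = np.where(present, np.log(np.where(present, x, 1.0)), np.nan)
    mu0 = np.nanmean(logx, axis=0)
    sigma0 = np.maximum(np.nanstd(logx, axis=0, ddof=0), _SIGMA_FLOOR)

    # latent scores on the relative-abundance scale marginal
    scores = np.empty_like(x)
    u = pi + (1.0 - pi) * ndtr((np.where(present, logx, 0.0) - mu0) / sigma0)
    scores = np.clip(ndtri(np.clip(u, 1e-12, 1 - 1e-12)), -8, 8)
    if np.any(~present):
        c = ndtri(np.clip(pi, 1e-12, 1 - 1e-12))
        lam = np.exp(-0.5 * c * c - _LOG_SQRT_2PI - log_ndtr(c))
        trunc_mean = -lam  # E[g | g < Phi^-1(pi)] for a standard normal
        scores = np.where(present, scores, trunc_mean[None, :])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr0 = np.corrcoef(scores, rowvar=False)
    corr0 = np.nan_to_num(corr0, nan=0.0)
    corr0 = cov_to_corr((1.0 - ridge) * corr0 + ridge * np.eye(p))
    # guard PD-ness for the inverse
    w, v = np.linalg.eigh(corr0)
    corr0 = cov_to_corr((v * np.maximum(w, 1e-4)) @ v.T)
    copula = CopulaCorrelation.from_corr(corr0)

    mu0 = mu0 - mu0.mean()  # identifiability: sum_j mu_j = 0
    return CommunityModel.from_arrays(
        table.feature_ids, pi, mu0, sigma0, copula, DepthModel(np.log(1e4), 0.0)
    )


def _truncnorm_upper_moments(m, s, c):
    """Mean and variance of Normal(m, s^2) truncated above at c."""
    beta = (c - m) / s
    lam = np.exp(-0.5 * beta * beta - _LOG_SQRT_2PI - log_ndtr(beta))
    mean = m - s * lam
    var = s * s * np.clip(1.0 - beta * lam - lam * lam, 1e-10, 1.0)
    return mean, var


def e_step(table: FeatureTable, model: CommunityModel, config: FitConfig) -> EStepState:
    """One E-step: per-sample log-likelihood, posterior moments of
    log A^Sigma, and filled-in latent Gaussian scores."""
    table = normalize_counts(table)
    x = table.values.T
    n, p = x.shape
    pi, mu, sigma = model.pi, model.mu, model.sigma
    corr = model.copula.corr
    exp_t = np.empty(n)
    exp_t2 = np.empty(n)
    loglik = np.empty(n)
    gbar = np.zeros((n, p))
    gvar = np.zeros((n, p))
    block_cache: dict[bytes, object] = {}
    for i in range(n):
        xi = x[i]
        nz = np.flatnonzero(xi > 0)
        z = np.flatnonzero(xi == 0)
        key = (xi > 0).tobytes()
        blocks = block_cache.get(key)
        if blocks is None:
            blocks = _zero_blocks(corr, nz, z)
            block_cache[key] = blocks
        try:
            ll, et, et2 = sample_total_abundance_moments(
                xi, model, n_nodes=config.quadrature_nodes, blocks=blocks, nz=nz
            )
        except FloatingPointError as err:
            raise FloatingPointError(
                f"E-step quadrature failed for sample {table.sample_ids[i]!r}: {err}"
            ) from err
        exp_t[i], exp_t2[i], loglik[i] = et, et2, ll
        # latent scores at the posterior-mean total abundance
        a_nz = np.exp(et) * xi[nz]
        g_nz = latent_gaussian_from_abundance(a_nz, pi[nz], mu[nz], sigma[nz])
        gbar[i, nz] = g_nz
        if z.size:
            m_cond = blocks.W @ g_nz
            c = ndtri(np.clip(pi[z], 1e-12, 1 - 1e-12))
            tm, tv = _truncnorm_upper_moments(m_cond, blocks.s_cond, c)
            gbar[i, z] = tm
            gvar[i, z] = tv
    return EStepState(exp_t=exp_t, exp_t2=exp_t2, gbar=gbar, gvar=gvar, loglik=loglik)


def _latent_second_moment(state: EStepState) -> np.ndarray:
    n = state.gbar.shape[0]
    s = state.gbar.T @ state.gbar / n
    s[np.diag_indices_from(s)] += state.gvar.mean(axis=0)
    return 0.5 * (s + s.T)


def m_step(
    state: EStepState,
    table: FeatureTable,
    lambda_: float,
    model: CommunityModel,
) -> CommunityModel:
    """Closed-form marginal updates plus a graphical-lasso precision update.

    ``model`` supplies the (never-updated) pi and the feature metadata.
    """
    table = normalize_counts(table)
    x = table.values.T
    present = x > 0
    logx = np.where(present, np.log(np.where(present, x, 1.0)), 0.0)
    # E[log A_ij] = log x_ij + E[t_i] on present entries
    ela = logx + state.exp_t[:, None]
    ela2 = logx**2 + 2 * logx * state.exp_t[:, None] + state.exp_t2[:, None]
    n_j = present.sum(axis=0)
    mu = (ela * present).sum(axis=0) / n_j
    sigma2 = (ela2 * present).sum(axis=0) / n_j - mu**2
    sigma = np.maximum(np.sqrt(np.clip(sigma2, 0.0, None)), _SIGMA_FLOOR)
    mu = mu - mu.mean()

    s_emp = _latent_second_moment(state)
    s_emp[np.diag_indices_from(s_emp)] += 1e-6
    try:
        cov, _prec = graphical_lasso(s_emp, alpha=float(lambda_), max_iter=200)
    except FloatingPointError as err:
        raise RuntimeError(
            f"graphical lasso failed to converge at lambda={lambda_:g}: {err}"
        ) from err
    corr = cov_to_corr(cov)
    copula = CopulaCorrelation.from_corr(corr)
    return CommunityModel.from_arrays(
        model.feature_ids, model.pi, mu, sigma, copula, model.depth
    )


def penalized_objective(state: EStepState, model: CommunityModel, lambda_: float) -> float:
    """Penalized negative log-likelihood: -sum_i log f_X + lambda * ||Omega||_1
    (off-diagonals)."""
    omega = model.copula.omega
    l1 = np.abs(omega).sum() - np.abs(np.diag(omega)).sum()
    return float(-state.loglik.sum() + lambda_ * l1)


def fit_em(
    table: FeatureTable,
    lambda_: float,
    config: FitConfig | None = None,
    init: CommunityModel | None = None,
    depth: DepthModel | None = None,
) -> FitResult:
    """Penalized EM at a fixed penalty weight ``lambda_``."""
    config = config or FitConfig()
    if table.p < 2:
        raise ValueError("the copula is undefined for a single feature")
    depth_model = depth
    if depth_model is None and table.kind == "counts":
        depth_model = fit_depth(table.values.sum(axis=0))
    relabund = normalize_counts(table)
    model = init if init is not None else initialize_params(relabund)
    if depth_model is not None:
        model = CommunityModel(model.marginals, model.copula, depth_model)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for r in range(config.max_iter):
        state = e_step(relabund, model, config)
        obj = penalized_objective(state, model, lambda_)
        trace.append(obj)
        n_iter = r + 1
        if r > 0 and abs(trace[-2] - obj) <= config.tol * (abs(trace[-2]) + 1.0):
            converged = True
            break
        model = m_step(state, relabund, lambda_, model)
    return FitResult(
        model=model,
        lambda_selected=float(lambda_),
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
    )


def heldout_loglik(table: FeatureTable, model: CommunityModel, config: FitConfig) -> float:
    """Mean unpenalized log-likelihood of held-out samples under ``model``."""
    state = e_step(table, model, config)
    return float(state.loglik.mean())


def cross_validate_lambda(
    table: FeatureTable,
    config: FitConfig | None = None,
    depth: DepthModel | None = None,
) -> FitResult:
    """K-fold CV over the lambda grid, then a final fit on all samples."""
    config = config or FitConfig()
    relabund = normalize_counts(table)
    n = relabund.n
    if n < config.n_folds:
        raise ValueError("need at least n_folds samples")
    grid = config.resolved_grid(relabund.p, n)
    if depth is None and table.kind == "counts":
        depth = fit_depth(table.values.sum(axis=0))
    if len(grid) == 1:
        return fit_em(relabund, float(grid[0]), config, depth=depth)

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, config.n_folds)
    cv_config = FitConfig(
        lambda_grid=config.lambda_grid,
        n_folds=config.n_folds,
        max_iter=config.cv_max_iter,
        tol=config.tol,
        quadrature_nodes=config.quadrature_nodes,
        seed=config.seed,
    )
    rows = []
    scores = np.zeros((len(grid), config.n_folds))
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        train = relabund.sample_subset(train_idx)
        test = relabund.sample_subset(test_idx)
        init = initialize_params(train)
        for a, lam in enumerate(grid):
            res = fit_em(train, float(lam), cv_config, init=init)
            scores[a, k] = heldout_loglik(test, res.model, cv_config)
    for a, lam in enumerate(grid):
        rows.append(
            {
                "lambda": float(lam),
                "mean_heldout_loglik": scores[a].mean(),
                "se": scores[a].std(ddof=1) / np.sqrt(config.n_folds),
            }
        )
    cv_table = pd.DataFrame(rows)
    best = float(cv_table.loc[cv_table["mean_heldout_loglik"].idxmax(), "lambda"])
    final = fit_em(relabund, best, config, depth=depth)
    final.cv_table = cv_table
    return final


# ---------------------------------------------------------------------------
# statsmodels-style model / results surface
# ---------------------------------------------------------------------------


class CommunityProfileModel:
    """Zero-inflated log-normal Gaussian-copula model of a feature table.

    Parameters
    ----------
    table : FeatureTable
        Counts or relative abundances, features x samples. Counts are
        normalized internally; sequencing depths are then fitted from the
        column totals.
    config : FitConfig, optional
        EM and cross-validation settings.

    Examples
    --------
    >>> model = CommunityProfileModel(table)
    >>> res = model.fit(lambda_=0.1)
    >>> print(res.summary())
    """

    def __init__(self, table: FeatureTable, config: FitConfig | None = None):
        self.table = table
        self.config = config or FitConfig()
        self.depth = (
            fit_depth(table.values.sum(axis=0)) if table.kind == "counts" else None
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, kind: str = "counts", config: FitConfig | None = None
    ) -> "CommunityProfileModel":
        return cls(FeatureTable.from_dataframe(df, kind=kind), config=config)

    def fit(self, lambda_: float | None = None) -> "CommunityFitResult":
        """Fit by penalized EM; ``lambda_=None`` selects the penalty by
        K-fold cross-validation."""
        if lambda_ is None:
            res = cross_validate_lambda(self.table, self.config, depth=self.depth)
        else:
            res = fit_em(self.table, float(lambda_), self.config, depth=self.depth)
        return CommunityFitResult(self, res)


class CommunityFitResult:
    """Results wrapper: fitted parameters, diagnostics, simulation."""

    def __init__(self, model: CommunityProfileModel, fit: FitResult):
        self.model = model
        self._fit = fit

    # pass-through of the FitResult contract
    @property
    def community(self) -> CommunityModel:
        return self._fit.model

    @property
    def params(self) -> pd.DataFrame:
        c = self._fit.model
        return pd.DataFrame(
            {"pi": c.pi, "mu": c.mu, "sigma": c.sigma}, index=c.feature_ids
        )

    @property
    def lambda_selected(self) -> float:
        return self._fit.lambda_selected

    @property
    def objective_trace(self) -> list[float]:
        return self._fit.objective_trace

    @property
    def n_iter(self) -> int:
        return self._fit.n_iter

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def cv_table(self) -> pd.DataFrame | None:
        return self._fit.cv_table

    def simulate(self, n: int, seed: int = 0):
        from .simulate import simulate

        return simulate(self.community, n, seed=seed)

    def summary(self) -> str:
        c = self._fit.model
        lines = [
            "Zero-inflated log-normal copula community model",
            "=" * 48,
            f"features: {c.p}    samples: {self.model.table.n}",
            f"lambda: {self.lambda_selected:.4g}    EM iterations: {self.n_iter}"
            f"    converged: {self.converged}",
            f"sum(mu): {c.mu.sum():.2e} (identifiability constraint)",
            f"depth: logN(mu_D={c.depth.mu_D:.3f}, sigma_D={c.depth.sigma_D:.3f})",
            "",
            self.params.round(4).to_string(),
        ]
        off = c.copula.omega[~np.eye(c.p, dtype=bool)]
        lines.insert(6, f"non-zero precision off-diagonals: {(np.abs(off) > 1e-8).sum()}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CommunityFitResult p={self._fit.model.p} "
            f"lambda={self.lambda_selected:.4g} converged={self.converged}>"
        )
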