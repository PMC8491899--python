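"""Community-level parameter containers.

A :class:`CommunityModel` is the full generative parameterisation of a
microbial community: one zero-inflated log-normal marginal per feature, a
Gaussian-copula correlation structure coupling the features' latent Gaussian
scores, and a log-normal model of per-sample sequencing depth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marginals import FeatureMarginal

__all__ = ["CopulaCorrelation", "DepthModel", "CommunityModel"]


def _symmetrize(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + m.T)


def cov_to_corr(cov: np.ndarray) -> np.ndarray:
    """Rescale a covariance matrix to unit diagonal, symmetrizing first."""
    cov = _symmetrize(np.asarray(cov, dtype=float))
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return _symmetrize(corr)


@dataclass
class CopulaCorrelation:
    """Latent-Gaussian correlation structure of the copula.

    ``omega`` is the precision matrix of the latent Gaussian vector g,
    so g ~ MVN(0, omega^-1); ``corr`` is that inverse rescaled to unit
    diagonal. Both are kept because the sparsity pattern of ``omega``
    (conditional independence) and the pairwise structure of ``corr``
    are each meaningful.
    """

    omega: np.ndarray
    corr: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.omega = _symmetrize(np.asarray(self.omega, dtype=float))
        eigvals = np.linalg.eigvalsh(self.omega)
        if eigvals.min() <= 0:
            raise ValueError(
                f"omega must be positive definite (min eigenvalue {eigvals.min():.3g})"
            )
        if self.corr is None:
            self.corr = cov_to_corr(np.linalg.inv(self.omega))
        else:
            self.corr = _symmetrize(np.asarray(self.corr, dtype=float))
            if not np.allclose(np.diag(self.corr), 1.0, atol=1e-8):
                raise ValueError("corr must have unit diagonal")

    @classmethod
    def from_corr(cls, corr: np.ndarray) -> "CopulaCorrelation":
        corr = cov_to_corr(corr)
        omega = _symmetrize(np.linalg.inv(corr))
        return cls(omega=omega, corr=corr)

    @classmethod
    def identity(cls, p: int) -> "CopulaCorrelation":
        return cls(omega=np.eye(p), corr=np.eye(p))

    @property
    def p(self) -> int:
        return self.omega.shape[0]


@dataclass(frozen=True)
class DepthModel:
    """Log-normal sequencing depth: log D ~ Normal(mu_D, sigma_D^2)."""

    mu_D: float
    sigma_D: float

    def __post_init__(self) -> None:
        if self.sigma_D < 0:
            raise ValueError("sigma_D must be non-negative")


@dataclass
class CommunityModel:
    """Full generative model: marginals + copula + sequencing depth."""

    marginals: list[FeatureMarginal]
    copula: CopulaCorrelation
    depth: DepthModel

    def __post_init__(self) -> None:
        if len(self.marginals) != self.copula.p:
            raise ValueError(
                f"{len(self.marginals)} marginals but copula dimension {self.copula.p}"
            )

    @property
    def p(self) -> int:
        return len(self.marginals)

    @property
    def feature_ids(self) -> list[str]:
        return [m.feature_id for m in self.marginals]

    # vectorised parameter views used throughout the numerics
    @property
    def pi(self) -> np.ndarray:
        return np.array([m.pi for m in self.marginals])

    @property
    def mu(self) -> np.ndarray:
        return np.array([m.mu for m in self.marginals])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([m.sigma for m in self.marginals])

    @classmethod
    def from_arrays(
        cls,
        feature_ids,
        pi,
        mu,
        sigma,
        copula: CopulaCorrelation,
        depth: DepthModel,
    ) -> "CommunityModel":
        marginals = [
            FeatureMarginal(str(f), float(p_), float(m_), float(s_))
            for f, p_, m_, s_ in zip(feature_ids, pi, mu, sigma, strict=True)
        ]
        return cls(marginals=marginals, copula=copula, depth=depth)

    # -- flat TSV serialization ------------------------------------------
    # One marginal row per feature, then the p x p latent correlation
    # block, then the two depth parameters. Plain text so fitted models
    # are diff-able and portable.

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("#zicopula-model\tv1\n")
        buf.write("#marginals\n")
        pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "pi": self.pi,
                "mu": self.mu,
                "sigma": self.sigma,
            }
        ).to_csv(buf, sep="\t", index=False)
        buf.write("#correlation\n")
        pd.DataFrame(self.copula.corr, index=self.feature_ids).to_csv(
            buf, sep="\t", header=False
        )
        buf.write("#depth\n")
        buf.write(f"mu_D\t{self.depth.mu_D!r}\n")
        buf.write(f"sigma_D\t{self.depth.sigma_D!r}\n")
        return buf.getvalue()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_tsv())

    @classmethod
    def from_tsv(cls, text: str) -> "CommunityModel":
        lines = text.splitlines()
        if not lines or not lines[0].startswith("#zicopula-model"):
            raise ValueError("not a zicopula model file")
        sections: dict[str, list[str]] = {}
        current = None
        for line in lines[1:]:
            if line.startswith("#"):
                current = line[1:].strip()
                sections[current] = []
            elif current is not None and line.strip():
                sections[current].append(line)
        marg = pd.read_csv(io.StringIO("\n".join(sections["marginals"])), sep="\t")
        corr_df = pd.read_csv(
            io.StringIO("\n".join(sections["correlation"])),
            sep="\t",
            header=None,
            index_col=0,
        )
        depth_kv = dict(
            line.split("\t") for line in sections["depth"]
        )
        corr = cov_to_corr(corr_df.to_numpy(dtype=float))
        return cls.from_arrays(
            marg["feature_id"].astype(str),
            marg["pi"].to_numpy(),
            marg["mu"].to_numpy(),
            marg["sigma"].to_numpy(),
            CopulaCorrelation.from_corr(corr),
            DepthModel(float(depth_kv["mu_D"]), float(depth_kv["sigma_D"])),
        )

    @classmethod
    def load(cls, path) -> "CommunityModel":
        with open(path) as fh:
            return cls.from_tsv(fh.read())
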