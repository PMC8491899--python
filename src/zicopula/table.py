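"""Feature-by-sample abundance tables.

The on-disk and in-memory convention is microbiome-standard: features in
rows, samples in columns. ``kind`` records what the values are — raw
sequencing ``counts``, ``relabund`` (relative abundances, columns sum to 1)
or ``absolute`` (simulated latent absolute abundances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]

KINDS = ("counts", "relabund", "absolute")


@dataclass
class FeatureTable:
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # p x n
    kind: str

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}; got {self.kind!r}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite and non-negative")
        if self.kind == "counts" and not np.allclose(self.values, np.round(self.values)):
            raise ValueError("counts must be integers")
        if self.kind == "relabund":
            colsums = self.values.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-6):
                bad = np.flatnonzero(~np.isclose(colsums, 1.0, atol=1e-6))
                raise ValueError(
                    f"relabund columns must sum to 1; offending samples: "
                    f"{[self.sample_ids[i] for i in bad[:5]]}"
                )

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str) -> "FeatureTable":
        return cls(
            feature_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            kind=kind,
        )

    def sample_subset(self, idx) -> "FeatureTable":
        """New table restricted to the sample positions in ``idx``."""
        idx = np.asarray(idx)
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            kind=self.kind,
        )

    def prevalence(self) -> np.ndarray:
        """Per-feature fraction of samples where the feature is present."""
        return (self.values > 0).mean(axis=1)
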