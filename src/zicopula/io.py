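"""Tab-separated readers and writers.

On-disk convention: features in rows, samples in columns; the first column
holds feature IDs and the header row sample IDs. Lines starting with ``#``
are provenance comments (tool version, subcommand, seed, input checksums)
and are ignored on read.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .table import FeatureTable

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "provenance_header",
]


def provenance_header(subcommand: str, seed=None, inputs: dict | None = None) -> str:
    lines = [f"# zicopula v{__version__} subcommand={subcommand}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for name, path in (inputs or {}).items():
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
        lines.append(f"# input {name}={path} sha256={digest}")
    return "\n".join(lines) + "\n"


def _detect_kind(values: np.ndarray) -> str:
    if np.allclose(values, np.round(values)) and values.max(initial=0) > 1:
        return "counts"
    colsums = values.sum(axis=0)
    if np.allclose(colsums, 1.0, atol=1e-6):
        return "relabund"
    if np.allclose(values, np.round(values)):
        return "counts"
    raise ValueError(
        "cannot auto-detect table kind: values are neither all integers "
        "(counts) nor do columns sum to 1 (relative abundances)"
    )


def read_feature_table(path, kind: str | None = None) -> FeatureTable:
    """Read a feature x sample TSV, auto-detecting counts vs relabund."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed table {path}: {err}") from err
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs in {path}: {dup[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample IDs in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"non-numeric entries in {path}: {err}") from err
    neg = np.argwhere(values < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(
            f"negative value at feature {df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    if kind is None:
        kind = _detect_kind(values)
    if kind == "relabund":
        values = values / values.sum(axis=0)  # renormalize away rounding error
    return FeatureTable(
        feature_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        values=values,
        kind=kind,
    )


def write_feature_table(table: FeatureTable, path, header: str | None = None) -> None:
    """Write a table as TSV with full float precision (round-trippable)."""
    path = Path(path)
    df = table.to_dataframe()
    if table.kind == "counts":
        df = df.astype(np.int64)
    buf = _io.StringIO()
    if header:
        buf.write(header)
    df.to_csv(buf, sep="\t", float_format=None)
    path.write_text(buf.getvalue())


def read_metadata(path) -> pd.DataFrame:
    """Samples x covariates TSV (first column sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample IDs in metadata {path}")
    return df
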