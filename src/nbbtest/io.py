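"""Readers and writers for the plain-text table formats.

Count tables are TSV/CSV with a header of sample names and leading
``gene_id``/``feature_id`` columns; the design table maps ``sample`` to
``condition`` (two conditions, first listed = condition A).  The dialect
is auto-detected from the extension (.csv → comma, otherwise tab) and
can be overridden.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .count_model import CountTable
from .differential import RESULT_COLUMNS

__all__ = ["read_counts", "write_counts", "write_results", "read_design"]

FLOAT_FORMAT = "%.12g"  # results round-trip at 12 significant digits


def _sep(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_design(design_path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    design_path = Path(design_path)
    df = pd.read_csv(design_path, sep=_sep(design_path, delimiter))
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ValueError(f"design table {design_path} lacks column {col!r}")
    return dict(zip(df["sample"].astype(str), df["condition"].astype(str)))


def read_counts(
    path: str | Path,
    design_path: str | Path,
    feature_kind: str = "isoform",
    delimiter: str | None = None,
) -> CountTable:
    """Read and validate a count table against its design table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path, delimiter))
    for col in ("gene_id", "feature_id"):
        if col not in df.columns:
            raise ValueError(f"count table {path} lacks column {col!r}")
    samples = [c for c in df.columns if c not in ("gene_id", "feature_id")]
    if not samples:
        raise ValueError(f"count table {path} has no sample columns")
    counts = df[samples].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        bad = [s for s in samples if not pd.api.types.is_numeric_dtype(df[s])]
        raise ValueError(f"non-numeric cells in sample column(s): {bad}")
    design = read_design(design_path, delimiter)
    missing = [s for s in samples if s not in design]
    if missing:
        raise ValueError(f"design does not cover sample(s): {missing}")
    return CountTable(
        gene_ids=df["gene_id"].to_numpy(dtype=object),
        feature_ids=df["feature_id"].to_numpy(dtype=object),
        counts=counts.astype(float),
        samples=samples,
        sample_condition={s: design[s] for s in samples},
        feature_kind=feature_kind,
    )


def write_counts(table: CountTable, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    table.to_frame().to_csv(
        path, sep=_sep(path, delimiter), index=False, float_format=FLOAT_FORMAT
    )


def write_results(results: pd.DataFrame, path: str | Path, delimiter: str | None = None) -> None:
    """Write a results table with fixed column order.

    An empty (fully filtered) table produces a header-only file.
    """
    path = Path(path)
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(
        path, sep=_sep(path, delimiter), index=False, float_format=FLOAT_FORMAT
    )
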