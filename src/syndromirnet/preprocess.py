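"""Expression-matrix container and the normalization chain.

The pipeline works on log2-scale miRNA expression matrices (miRNAs in rows,
samples in columns) with a sample-to-group map. Two normalizations are
offered: per-sample z-scoring (zero mean, unit sample variance) and
per-patient median centering (each sample's median brought to exactly 0).
Both are independently switchable; which branch uses which chain is recorded
in the run manifest by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "log2_transform",
    "standardize_samples",
    "median_center_patients",
    "read_expression",
    "write_expression",
]


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values plus sample group labels.

    Parameters
    ----------
    values
        DataFrame, rows indexed by miRNA id, columns by sample id.
    groups
        Series mapping sample id -> group label; must cover every column.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate miRNA ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_columns(self, group: str) -> list[str]:
        cols = [s for s in self.values.columns if self.groups[s] == group]
        if not cols:
            raise KeyError(f"unknown group label: {group!r}")
        return cols

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, groups=self.groups.copy())


def log2_transform(raw: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """log2(raw + pseudocount); raw must be non-negative.

    The default pseudocount is 0 because the simulator emits strictly
    positive intensities; user data with zeros needs a positive pseudocount.
    """
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log2_transform requires non-negative input")
    shifted = arr + pseudocount
    if np.any(shifted <= 0):
        raise ValueError("zero values present; use a positive pseudocount")
    out = np.log2(shifted)
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out


def standardize_samples(m: ExpressionMatrix, tol: float = 1e-12) -> ExpressionMatrix:
    """Z-score each sample column to zero mean and unit sample variance.

    Uses the n-1 denominator so downstream t-statistics see the same scale.
    Raises on constant columns, naming the offending sample.
    """
    vals = m.values
    sd = vals.std(axis=0, ddof=1)
    bad = sd.index[sd <= tol]
    if len(bad):
        raise ValueError(f"constant sample column(s), cannot standardize: {list(bad)}")
    out = (vals - vals.mean(axis=0)) / sd
    return m.copy_with(out)


def median_center_patients(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each sample column's median so every patient has median 0."""
    out = m.values - m.values.median(axis=0)
    return m.copy_with(out)


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read the TSV dialect: matrix with header row of sample ids, first
    column miRNA ids; sidecar two-column TSV sample_id<TAB>group."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t", header=0)
    groups = pd.Series(gdf.iloc[:, 1].values, index=gdf.iloc[:, 0].astype(str))
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(m: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path) -> None:
    m.values.to_csv(matrix_path, sep="\t", index_label="mirna_id")
    pd.DataFrame({"sample_id": m.sample_ids, "group": m.groups.values}).to_csv(
        groups_path, sep="\t", index=False
    )
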