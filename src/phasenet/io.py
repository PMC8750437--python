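"""Expression-matrix and sample-metadata input/output.

The central container is a plain :class:`pandas.DataFrame` with genes in rows
and samples in columns, holding log2-ratios of hybridization intensity versus
a common reference pool.  Sample metadata is a DataFrame with one row per
sample (columns ``sample_id``, ``phase``, ``accelerated_subtype``).

Two-color microarray intensities are commonly deposited as log10-ratios;
:func:`log10_to_log2` rescales them, and :func:`quantile_normalize` forces all
samples onto the common empirical distribution before any comparison across
samples.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "ACCEL_SUBTYPES",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_meta",
    "write_sample_meta",
    "validate_expression",
    "validate_meta",
    "log10_to_log2",
    "quantile_normalize",
]

logger = logging.getLogger(__name__)

PHASES = ("chronic", "accelerated", "blast", "resistant")
ACCEL_SUBTYPES = ("blast_count", "cytogenetic", "not_applicable")

MISSING_TOKENS = ("NA", "NaN", "nan", "")

LOG2_OF_10 = math.log2(10.0)


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants (unique ids, finite values)."""
    dup_genes = matrix.index[matrix.index.duplicated()].unique()
    if len(dup_genes):
        raise ValueError(f"duplicate gene identifiers: {list(dup_genes)}")
    dup_samples = matrix.columns[matrix.columns.duplicated()].unique()
    if len(dup_samples):
        raise ValueError(f"duplicate sample identifiers: {list(dup_samples)}")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return matrix


def validate_meta(meta: pd.DataFrame, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check sample-metadata invariants, optionally against a matrix."""
    required = {"sample_id", "phase"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dups}")
    bad = set(meta["phase"]) - set(PHASES)
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")
    if "accelerated_subtype" in meta.columns:
        bad = set(meta["accelerated_subtype"]) - set(ACCEL_SUBTYPES)
        if bad:
            raise ValueError(f"unknown accelerated_subtype labels: {sorted(bad)}")
        mism = (meta["accelerated_subtype"] != "not_applicable") ^ (
            meta["phase"] == "accelerated"
        )
        if mism.any():
            raise ValueError(
                "accelerated_subtype must be set exactly for accelerated-phase samples"
            )
    if matrix is not None:
        missing = set(matrix.columns) - set(meta["sample_id"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
    return meta


def read_expression_tsv(
    path,
    missing_drop_frac: float = 0.5,
) -> pd.DataFrame:
    """Read a tab-delimited gene x sample matrix of expression ratios.

    First column holds gene identifiers, the header row sample identifiers.
    Cells equal to ``NA`` (or empty) are missing.  Genes with more than
    ``missing_drop_frac`` missing values are dropped (and logged); remaining
    missing cells are imputed with the gene's median across samples.

    Raises ``ValueError`` on duplicate identifiers or non-numeric cells.
    """
    raw = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS),
        keep_default_na=False, dtype=str,
    )
    if raw.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    matrix = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {raw[col].iloc[i]!r} at "
                f"gene {raw.index[i]!r}, sample {col!r} (row {i + 1}, column {j + 2})"
            )
        matrix[col] = converted

    dup = matrix.index[matrix.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate gene identifiers: {list(dup)}")
    dup = matrix.columns[matrix.columns.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate sample identifiers: {list(dup)}")

    frac_missing = matrix.isna().mean(axis=1)
    drop = frac_missing > missing_drop_frac
    if drop.any():
        logger.info(
            "dropping %d genes with >%d%% missing values: %s",
            int(drop.sum()), int(100 * missing_drop_frac),
            list(matrix.index[drop]),
        )
        matrix = matrix.loc[~drop]
    if matrix.isna().any().any():
        med = matrix.median(axis=1)
        matrix = matrix.apply(lambda row: row.fillna(med[row.name]), axis=1)
    return validate_expression(matrix)


def write_expression_tsv(matrix: pd.DataFrame, path, precision: int = 6) -> None:
    """Write a matrix in the tab-delimited format read_expression_tsv accepts."""
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=f"%.{precision}g", na_rep="NA")


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "accelerated_subtype" not in meta.columns:
        meta["accelerated_subtype"] = np.where(
            meta["phase"] == "accelerated", "blast_count", "not_applicable"
        )
    return validate_meta(meta)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def log10_to_log2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale log10-ratios to log2-ratios (multiply by log2(10))."""
    return matrix * LOG2_OF_10


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples (columns) of an expression matrix.

    After normalization every sample shares the same empirical distribution:
    the cross-sample mean of sorted value vectors.  Ties within a sample
    receive the mean of the quantile values they span.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("quantile normalization requires a complete matrix")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n)
        mapped[order] = ref
        # average the reference quantiles spanned by each tied group
        col_sorted = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col_sorted[k + 1] == col_sorted[i]:
                k += 1
            if k > i:
                mapped[order[i : k + 1]] = ref[i : k + 1].mean()
            i = k + 1
        out[:, j] = mapped
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
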