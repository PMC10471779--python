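"""Count-matrix I/O, normalization, gene filtering and batch handling.

Normalization follows the common bulk RNA-seq recipe: median-of-ratios
size factors (reference = genes observed in every sample) followed by a
``log2(count / factor + 1)`` transform. The log2(x+1) step is a
simplified, exactly-specified variance-stabilizing transform: it
preserves ranks, maps zero counts to zero and is invertible given the
size factor. Batch (or RNA-integrity) effects are removed by per-gene
mean-centering within batches, preserving each gene's grand mean — a
location-only adjustment, deliberately simpler than empirical-Bayes
batch correction.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, FilterReport, FormatError

__all__ = [
    "read_counts",
    "write_counts",
    "read_annotation",
    "size_factors",
    "vst_like",
    "normalize",
    "filter_genes",
    "bin_rin",
    "batch_center",
]


def read_counts(path, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples count matrix.

    ``tsv``: tab-separated, gene ids in the first column, header row of
    sample ids. ``mtx``: MatrixMarket triplet with companion ``genes.tsv``
    and ``samples.tsv`` (one id per line) next to the ``.mtx`` file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"counts file not found: {path}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx":
        mat = scipy.sparse.coo_matrix(scipy.io.mmread(path)).toarray()
        genes_f = path.with_name("genes.tsv")
        samples_f = path.with_name("samples.tsv")
        for f in (genes_f, samples_f):
            if not f.exists():
                raise FileNotFoundError(f"companion id file not found: {f}")
        genes = genes_f.read_text().split()
        samples = samples_f.read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match "
                f"{len(genes)} gene ids x {len(samples)} sample ids"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionMatrix(df, layer="counts")


def write_counts(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path) -> pd.DataFrame:
    """Read a sample metadata TSV; requires a ``sample_id`` column."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise FormatError("metadata table must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dup[:10]}")
    return df.set_index("sample_id")


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with a nonzero count in every sample; per
    sample the factor is the median over reference genes of
    count / (gene's geometric mean across samples).
    """
    if counts.layer != "counts":
        raise ValueError("size_factors expects the counts layer")
    vals = counts.values.astype(float)
    ref = (vals > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "pre-filter all-zero/low-coverage genes first"
        )
    logs = np.log(vals[ref])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def vst_like(counts: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """log2(count / size_factor + 1) normalized layer."""
    if (np.asarray(factors) <= 0).any():
        raise ValueError("size factors must be positive")
    f = factors.reindex(counts.sample_ids)
    if f.isna().any():
        raise ValueError("size factors missing for some samples")
    norm = np.log2(counts.values / f.to_numpy()[None, :] + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(norm, index=counts.gene_ids, columns=counts.sample_ids),
        layer="normalized",
    )


def normalize(counts: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """Convenience: size factors + vst-like transform."""
    f = size_factors(counts)
    return vst_like(counts, f), f


def filter_genes(
    matrix: ExpressionMatrix,
    keep_list=None,
    low_expr_threshold: float = 1.0,
    low_expr_fraction: float = 0.95,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Sequential gene filters with a per-rule report.

    Order: (1) restrict to ``keep_list`` if given (e.g. protein-coding
    symbols), (2) drop genes with zero signal in all samples, (3) drop
    genes whose expression is below ``low_expr_threshold`` in strictly
    more than ``low_expr_fraction`` of samples. The low-expression rule
    is intended for the normalized layer, where a value of 1 is one
    normalized log2 unit.
    """
    if matrix.n_genes == 0:
        raise ValueError("empty matrix")
    df = matrix.data
    n_input = len(df)

    if keep_list is not None:
        keep = set(keep_list)
        mask = df.index.isin(keep)
        n_keep_removed = int((~mask).sum())
        df = df.loc[mask]
    else:
        n_keep_removed = 0

    nz = (df.to_numpy() != 0).any(axis=1)
    n_zero_removed = int((~nz).sum())
    df = df.loc[nz]

    vals = df.to_numpy()
    frac_below = (vals < low_expr_threshold).mean(axis=1)
    low = frac_below > low_expr_fraction
    n_low_removed = int(low.sum())
    df = df.loc[~low]

    report = FilterReport(
        n_input=n_input,
        n_removed_not_in_keep_list=n_keep_removed,
        n_removed_zero_total=n_zero_removed,
        n_removed_low_expression=n_low_removed,
        n_retained=len(df),
    )
    if len(df) == 0:
        raise ValueError(f"all genes filtered out; report: {report}")
    return ExpressionMatrix(df, layer=matrix.layer), report


def bin_rin(rin: float) -> int:
    """Map an RNA integrity number in [6.5, 10] to one of 7 half-unit
    classes: [6.5, 7.0), [7.0, 7.5), ..., [9.5, 10.0]; boundaries go to
    the right-hand class, the top bin is closed at 10."""
    rin = float(rin)
    if not (6.5 <= rin <= 10.0):
        raise ValueError(f"RIN {rin} outside the supported range [6.5, 10]")
    return min(int((rin - 6.5) // 0.5) + 1, 7)


def batch_center(normalized: ExpressionMatrix, batch_labels) -> ExpressionMatrix:
    """Per-gene batch mean-centering that preserves each gene's grand mean.

    For every gene: subtract the batch mean and add back the grand mean
    over all samples. A single batch is a no-op.
    """
    labels = pd.Series(batch_labels)
    if len(labels) != normalized.n_samples:
        raise ValueError("one batch label per sample required")
    if labels.isna().any():
        bad = normalized.sample_ids[labels.isna().to_numpy()][:5].tolist()
        raise ValueError(f"unlabeled samples: {bad}")
    vals = normalized.values.astype(float)
    grand = vals.mean(axis=1, keepdims=True)
    out = vals.copy()
    for b in labels.unique():
        cols = (labels == b).to_numpy()
        out[:, cols] += grand - vals[:, cols].mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(out, index=normalized.gene_ids, columns=normalized.sample_ids),
        layer="normalized",
    )
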