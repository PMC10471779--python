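"""Core data containers shared across the pipeline.

The pipeline moves three kinds of tables around: a genes x samples
expression matrix (raw counts or normalized values), a per-sample
annotation table, and small result records (filter reports, fingerprint
panels, per-sample score pairs, differential-expression tables, reversal
reports). Everything tabular is a :class:`pandas.DataFrame` underneath;
the thin wrappers here add the invariants the pipeline relies on
(unique identifiers, integer-valued counts, layer tags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "FingerprintPanel",
    "ClusterResult",
    "ExtensionResult",
    "ReversalReport",
    "LfpError",
    "ConfigError",
    "FormatError",
]


class LfpError(Exception):
    """Base class for pipeline errors."""


class ConfigError(LfpError, ValueError):
    """Invalid configuration (sizes, rates, thresholds)."""


class FormatError(LfpError, ValueError):
    """Malformed input data (duplicate ids, non-integer counts, ...)."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a layer tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    layer
        ``"counts"`` (integer-valued, non-negative) or ``"normalized"``
        (non-negative reals, log2 scale in this pipeline).
    """

    data: pd.DataFrame
    layer: str = "counts"

    def __post_init__(self) -> None:
        if self.layer not in ("counts", "normalized"):
            raise FormatError(f"unknown layer {self.layer!r}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy()
        if self.layer == "counts" and vals.size:
            if np.nanmin(vals) < 0:
                bad = self.data.index[(self.data < 0).any(axis=1)][:5].tolist()
                raise FormatError(f"negative counts in genes {bad}")
            frac = np.mod(vals, 1)
            if np.any(frac != 0):
                bad_rows = np.nonzero((frac != 0).any(axis=1))[0][:5]
                bad = self.data.index[bad_rows].tolist()
                raise FormatError(f"non-integer counts in genes {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = pd.Index(genes).difference(self.data.index)
        if len(missing):
            raise KeyError(f"genes not in matrix: {missing[:10].tolist()}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.layer)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = pd.Index(samples).difference(self.data.columns)
        if len(missing):
            raise KeyError(f"samples not in matrix: {missing[:10].tolist()}")
        return ExpressionMatrix(self.data[list(samples)], self.layer)


@dataclass
class FilterReport:
    """Sequential gene-filter bookkeeping.

    Rules are applied in order (keep-list restriction, all-zero removal,
    low-expression removal); each count refers to the rule's own input,
    so ``n_input - sum(removed) == n_retained``.
    """

    n_input: int
    n_removed_not_in_keep_list: int
    n_removed_zero_total: int
    n_removed_low_expression: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_not_in_keep_list
            + self.n_removed_zero_total
            + self.n_removed_low_expression
        )
        if self.n_input - removed != self.n_retained:
            raise ValueError("filter report counts are inconsistent")


@dataclass
class FingerprintPanel:
    """Stability-selected gene panel with selection frequency and direction.

    ``direction`` is +1 for genes higher in the reference (most severe)
    cluster, -1 for genes lower; ``G_up``/``G_down`` count each sign.
    """

    table: pd.DataFrame  # index gene_id; columns: frequency, direction
    B: int
    frequency_threshold: float

    def __post_init__(self) -> None:
        t = self.table
        if not {"frequency"}.issubset(t.columns):
            raise ValueError("panel table needs a 'frequency' column")
        if ((t["frequency"] < 0) | (t["frequency"] > 1)).any():
            raise ValueError("selection frequencies must lie in [0, 1]")
        if (t["frequency"] < self.frequency_threshold).any():
            raise ValueError("panel contains genes below the frequency threshold")
        if "direction" in t.columns and not t["direction"].isin([1, -1]).all():
            raise ValueError("directions must be +1 or -1")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def up_genes(self) -> list[str]:
        return self.table.index[self.table["direction"] == 1].tolist()

    @property
    def down_genes(self) -> list[str]:
        return self.table.index[self.table["direction"] == -1].tolist()

    @property
    def G_up(self) -> int:
        return len(self.up_genes)

    @property
    def G_down(self) -> int:
        return len(self.down_genes)


AMBIGUOUS = -1
"""Consensus label for samples the three clusterings do not agree on."""


@dataclass
class ClusterResult:
    """Outcome of the three-way consensus clustering at a fixed k."""

    k: int
    labels_by_method: pd.DataFrame  # index sample_id; columns hclust/kmeans/gmm
    consensus_label: pd.Series  # int labels 1..k, AMBIGUOUS for disagreement
    agreement_score: float  # mean pairwise ARI among the three methods
    seed: int | None = None

    @property
    def n_consensus(self) -> int:
        return int((self.consensus_label != AMBIGUOUS).sum())

    @property
    def consensus_fraction(self) -> float:
        return self.n_consensus / len(self.consensus_label)


@dataclass
class ExtensionResult:
    """Classifier extension of consensus labels to held-out samples."""

    table: pd.DataFrame  # index sample_id; columns: label, confidence, retained
    tau: float

    def __post_init__(self) -> None:
        expected = self.table["confidence"] >= self.tau
        if not (self.table["retained"] == expected).all():
            raise ValueError("retained flag inconsistent with tau")


@dataclass
class ReversalReport:
    """Pathology gene sets and their per-arm reversal."""

    pathology_up: list[str]
    pathology_down: list[str]
    reversed_by_arm: dict[str, list[str]] = field(default_factory=dict)

    @property
    def pathology_genes(self) -> list[str]:
        return list(self.pathology_up) + list(self.pathology_down)

    @property
    def reversal_fraction(self) -> dict[str, float]:
        n = len(self.pathology_genes)
        return {
            arm: (len(genes) / n if n else float("nan"))
            for arm, genes in self.reversed_by_arm.items()
        }

    def __post_init__(self) -> None:
        patho = set(self.pathology_genes)
        for arm, genes in self.reversed_by_arm.items():
            extra = set(genes) - patho
            if extra:
                raise ValueError(
                    f"arm {arm!r}: reversed genes not in pathology set: "
                    f"{sorted(extra)[:5]}"
                )
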