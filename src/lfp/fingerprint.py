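"""Interactant panel assembly, bootstrap stability selection, and the
composite up/down severity scores.

The fingerprint is the subset of candidate (interactant) genes that
discriminates the molecular clusters in essentially every bootstrap
replicate: per replicate a stratified bootstrap of samples is drawn, a
random forest predicts the cluster label from the candidate genes, and a
gene counts as "chosen" when its out-of-bag permutation importance —
averaged per tree, as the classical random-forest importance is — is
strictly positive. Selection frequency is the fraction of replicates in
which a gene is chosen; the default threshold keeps only genes chosen in
100% of replicates.

Each selected gene gets a direction: +1 if its mean normalized
expression in the reference (most severe) cluster exceeds the mean over
the remaining patients, else -1. The per-sample scores are then

    score_up(i)   = median_{j in up-genes}   ( Y_ij - median_k Ctrl_kj )
    score_down(i) = median_{j in down-genes} ( Y_ij - median_k Ctrl_kj )

where Ctrl is the healthy-volunteer (HV) reference, with the midpoint
convention for even-sized medians, and are finally z-normalized against
the HV population's own score distribution.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from .containers import AMBIGUOUS, ExpressionMatrix, FingerprintPanel

__all__ = [
    "assemble_interactants",
    "StabilitySelector",
    "stability_select",
    "split_directions",
    "score",
    "score_samples",
    "z_normalize_scores",
    "compute_scores",
]


def assemble_interactants(list_a, list_b, dataset_genes):
    """Case-normalized, de-duplicated union of two interactant lists.

    Returns ``(merged, absent)`` where ``absent`` are union members not
    found in ``dataset_genes`` (case-insensitively). Order of ``merged``
    follows first occurrence.
    """
    if not len(list_a) or not len(list_b):
        raise ValueError("both gene lists must be nonempty")
    merged: list[str] = []
    seen: set[str] = set()
    for g in list(list_a) + list(list_b):
        gu = str(g).strip().upper()
        if gu and gu not in seen:
            seen.add(gu)
            merged.append(gu)
    dataset = {str(g).upper() for g in dataset_genes}
    absent = [g for g in merged if g not in dataset]
    if len(absent) == len(merged):
        warnings.warn("no interactant gene found in the dataset")
    return merged, absent


def _per_tree_oob_importance(forest: RandomForestClassifier, X: np.ndarray,
                             y_enc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permutation importance averaged per tree on its out-of-bag samples.

    For each tree: accuracy on its OOB set minus accuracy after permuting
    a feature's OOB values (one shared permutation per tree). Features a
    tree does not split on contribute exactly zero for that tree, so only
    split features need re-prediction.
    """
    n, d = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    imp = np.zeros(d)
    n_trees = len(forest.estimators_)
    for tree, inbag in zip(forest.estimators_, forest.estimators_samples_):
        mask = np.ones(n, dtype=bool)
        mask[inbag] = False
        oob = np.flatnonzero(mask)
        if oob.size == 0:
            continue
        Xo = X32[oob]
        yo = y_enc[oob]
        base = np.count_nonzero(_tree_pred(tree, Xo) == yo)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        perm = rng.permutation(oob.size)
        for f in used:
            Xp = Xo.copy()
            Xp[:, f] = Xo[perm, f]
            hits = np.count_nonzero(_tree_pred(tree, Xp) == yo)
            imp[f] += (base - hits) / oob.size
    return imp / n_trees


def _tree_pred(tree, X32: np.ndarray) -> np.ndarray:
    proba = tree.tree_.predict(X32)
    if proba.ndim == 3:
        proba = proba[:, 0, :]
    return np.argmax(proba, axis=1)


class StabilitySelector(BaseEstimator):
    """Bootstrap random-forest stability selection of discriminant genes.

    Parameters
    ----------
    B : int
        Number of bootstrap replicates (study default 200).
    threshold : float in (0, 1]
        Selection-frequency threshold (1.0 keeps only genes chosen in
        every replicate).
    rule : {"positive_importance", "top_q"}
        What "chosen" means within one replicate: strictly positive
        per-tree OOB permutation importance, or membership in the top-q
        genes by that importance.
    q : int
        Panel size per replicate for the "top_q" rule.
    n_estimators : int
        Trees per forest.
    random_state : int or None

    Attributes
    ----------
    frequencies_ : pd.Series, selection frequency per candidate gene
    selected_genes_ : list of genes with frequency >= threshold
    """

    def __init__(self, B=200, threshold=1.0, rule="positive_importance",
                 q=69, n_estimators=100, random_state=None):
        self.B = B
        self.threshold = threshold
        self.rule = rule
        self.q = q
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must lie in (0, 1]")
        if self.rule not in ("positive_importance", "top_q"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if hasattr(X, "columns"):
            names = pd.Index(X.columns)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            names = pd.Index([f"f{i}" for i in range(arr.shape[1])])
        if arr.shape[1] == 0:
            raise ValueError("empty candidate gene set")
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2 or (counts < 5).any():
            raise ValueError("need >= 2 clusters with >= 5 samples each")

        # canonical feature order makes frequencies independent of the
        # caller's candidate ordering
        order = np.argsort(names)
        arr_c = np.ascontiguousarray(arr[:, order])
        names_c = names[order]
        y_enc = np.searchsorted(classes, y)
        class_rows = [np.flatnonzero(y == c) for c in classes]

        ss = np.random.SeedSequence(self.random_state)
        chosen_counts = np.zeros(arr.shape[1])
        for child in ss.spawn(self.B):
            rng = np.random.default_rng(child)
            rows = np.concatenate(
                [rng.choice(r, size=r.size, replace=True) for r in class_rows]
            )
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                random_state=int(rng.integers(2**31)),
            ).fit(arr_c[rows], y[rows])
            imp = _per_tree_oob_importance(forest, arr_c[rows], y_enc[rows], rng)
            if self.rule == "positive_importance":
                chosen_counts += imp > 0
            else:
                top = np.argsort(imp)[::-1][: self.q]
                sel = np.zeros_like(imp, dtype=bool)
                sel[top[imp[top] > 0]] = True
                chosen_counts += sel

        freq_c = pd.Series(chosen_counts / self.B, index=names_c)
        self.frequencies_ = freq_c.reindex(names)
        self.selected_genes_ = self.frequencies_[
            self.frequencies_ >= self.threshold
        ].index.tolist()
        self.classes_ = classes
        return self

    def get_support(self) -> np.ndarray:
        return (self.frequencies_ >= self.threshold).to_numpy()

    def panel(self) -> FingerprintPanel:
        table = pd.DataFrame(
            {"frequency": self.frequencies_.loc[self.selected_genes_]}
        )
        table.index.name = "gene_id"
        return FingerprintPanel(
            table=table, B=self.B, frequency_threshold=self.threshold
        )


def stability_select(X_norm: ExpressionMatrix, consensus_labels: pd.Series,
                     candidate_genes, B: int = 200, threshold: float = 1.0,
                     seed=None, **kwargs) -> tuple[FingerprintPanel, pd.Series]:
    """Functional wrapper: select the fingerprint from a normalized
    matrix and per-sample consensus labels. Ambiguous samples are
    dropped. Returns ``(panel, frequencies)``."""
    cands = [g for g in candidate_genes if g in set(X_norm.gene_ids)]
    if not cands:
        raise ValueError("no candidate gene present in the matrix")
    labels = consensus_labels[consensus_labels != AMBIGUOUS]
    X = X_norm.data.loc[cands, labels.index].T
    sel = StabilitySelector(B=B, threshold=threshold, random_state=seed,
                            **kwargs).fit(X, labels.to_numpy())
    return sel.panel(), sel.frequencies_


def split_directions(X_norm: ExpressionMatrix, labels: pd.Series,
                     panel: FingerprintPanel, ref_cluster="C3",
                     hv_label="HV") -> FingerprintPanel:
    """Assign +1/-1 directions to panel genes by contrasting the
    reference cluster against all other patients on the normalized
    layer; exact ties fall back to the contrast against HV, then +1."""
    labels = labels.loc[labels.index.intersection(X_norm.sample_ids)]
    ref_ids = labels.index[labels == ref_cluster]
    if len(ref_ids) == 0:
        raise ValueError(f"reference cluster {ref_cluster!r} is empty")
    other_ids = labels.index[(labels != ref_cluster) & (labels != hv_label)]
    hv_ids = labels.index[labels == hv_label]
    genes = panel.gene_ids.tolist()
    sub = X_norm.data.loc[genes]
    ref_mean = sub[ref_ids].mean(axis=1)
    other_mean = sub[other_ids].mean(axis=1) if len(other_ids) else ref_mean * 0
    diff = ref_mean - other_mean
    direction = np.sign(diff).astype(int)
    if (direction == 0).any() and len(hv_ids):
        hv_diff = np.sign(ref_mean - sub[hv_ids].mean(axis=1)).astype(int)
        direction = direction.where(direction != 0, hv_diff)
    direction = direction.replace(0, 1)
    table = panel.table.copy()
    table["direction"] = direction.to_numpy()
    return FingerprintPanel(table=table, B=panel.B,
                            frequency_threshold=panel.frequency_threshold)


def _hv_medians(hv_matrix: pd.DataFrame, gene_set) -> pd.Series:
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in hv_matrix.index]
    if missing:
        raise KeyError(f"genes missing from the HV reference: {missing[:10]}")
    if hv_matrix.shape[1] < 1:
        raise ValueError("need at least one HV sample")
    return hv_matrix.loc[gene_set].median(axis=1)


def score(sample_expr: pd.Series, hv_matrix: pd.DataFrame, gene_set) -> float:
    """Median over the gene set of the sample's deviation from the
    per-gene HV median (midpoint convention for even counts)."""
    med = _hv_medians(hv_matrix, gene_set)
    missing = [g for g in med.index if g not in sample_expr.index]
    if missing:
        raise KeyError(f"genes missing from the sample: {missing[:10]}")
    dev = sample_expr.loc[med.index] - med
    return float(np.median(dev.to_numpy()))


def score_samples(X_norm: ExpressionMatrix, hv_ids, gene_set) -> pd.Series:
    """Vectorized deviation score for every sample in the matrix, using
    the HV columns as the reference."""
    hv_ids = list(hv_ids)
    med = _hv_medians(X_norm.data[hv_ids], gene_set)
    dev = X_norm.data.loc[med.index].to_numpy() - med.to_numpy()[:, None]
    return pd.Series(np.median(dev, axis=0), index=X_norm.sample_ids)


def z_normalize_scores(scores, hv_scores) -> np.ndarray:
    """Standardize scores against the HV score distribution
    (mean 0, sd 1 with n-1 denominator on the HV scores)."""
    hv = np.asarray(hv_scores, dtype=float)
    if hv.size < 2:
        raise ValueError("need at least 2 HV scores")
    sd = hv.std(ddof=1)
    if sd == 0:
        raise ValueError("HV scores have zero variance")
    return (np.asarray(scores, dtype=float) - hv.mean()) / sd


def compute_scores(X_norm: ExpressionMatrix, hv_ids,
                   panel: FingerprintPanel) -> pd.DataFrame:
    """Per-sample score pairs (raw and HV-z-normalized) for a panel with
    directions."""
    if "direction" not in panel.table.columns:
        raise ValueError("panel has no directions; run split_directions first")
    hv_ids = list(hv_ids)
    out = pd.DataFrame(index=X_norm.sample_ids)
    for name, genes in (("up", panel.up_genes), ("down", panel.down_genes)):
        if not genes:
            out[f"score_{name}"] = np.nan
            out[f"z_{name}"] = np.nan
            continue
        s = score_samples(X_norm, hv_ids, genes)
        out[f"score_{name}"] = s
        out[f"z_{name}"] = z_normalize_scores(s, s.loc[hv_ids])
    return out
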