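"""Semi-supervised consensus clustering of expression profiles.

Molecular subgroups are called only where three unrelated clusterings
agree: agglomerative hierarchical clustering on 1 - Pearson correlation
with Ward linkage, k-means, and a Gaussian mixture. Each method's labels
are aligned to the hierarchical solution by optimal assignment on the
contingency table, and a sample receives a consensus label only under
unanimity — the strictest reading of "consensus". The cluster number is
chosen where the three methods agree best (mean pairwise adjusted Rand
index), preferring the finest partition among statistically equivalent
ones. Consensus labels are extended to held-out samples with a
random-forest classifier gated by a vote-confidence threshold tau.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .containers import AMBIGUOUS, ClusterResult, ExtensionResult

__all__ = [
    "ConsensusClusterer",
    "highly_variable_genes",
    "cluster_three_ways",
    "align_labels",
    "consensus",
    "select_k",
    "extend_to_test",
]

METHODS = ("hclust", "kmeans", "gmm")


def _stage_seeds(seed, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _as_array(X) -> np.ndarray:
    arr = X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X)
    return np.asarray(arr, dtype=float)


def highly_variable_genes(X, n_top: int, window: int = 101) -> np.ndarray:
    """Rank features by variance in excess of the mean-variance trend.

    On log-scale expression the technical variance depends strongly on
    the mean (low-count genes are noisiest), so raw variance ranking
    mostly picks lowly expressed genes. Following standard
    highly-variable-gene practice, the per-gene variance is divided by a
    rolling-median trend of variance against mean expression, and the
    top ``n_top`` genes by that ratio are returned (column indices,
    sorted ascending).
    """
    arr = _as_array(X)
    mean = arr.mean(axis=0)
    var = arr.var(axis=0)
    order = np.argsort(mean, kind="stable")
    trend = np.empty_like(var)
    trend[order] = (
        pd.Series(var[order])
        .rolling(window, center=True, min_periods=max(window // 5, 5))
        .median()
        .to_numpy()
    )
    ratio = var / np.maximum(trend, 1e-12)
    top = np.argsort(ratio, kind="stable")[::-1][:n_top]
    return np.sort(top)


def cluster_three_ways(X, k: int, seed=None, X_corr=None) -> pd.DataFrame:
    """Run the three clusterings at a fixed k on a samples x features
    matrix; returns a DataFrame with columns hclust / kmeans / gmm and
    labels in 1..k.

    ``X_corr``, when given, is the (wider) feature matrix used for the
    correlation-distance hierarchical method — sample-sample Pearson
    correlation is meaningful across many genes but not across a few
    principal components, so the estimator passes the standardized gene
    matrix here while k-means and the Gaussian mixture run on ``X``.
    """
    arr = _as_array(X)
    n = arr.shape[0]
    if not (2 <= k < n):
        raise ValueError(f"need 2 <= k < n_samples, got k={k}, n={n}")
    const = arr.std(axis=0) == 0
    if const.any():
        warnings.warn(f"dropping {const.sum()} constant feature(s)")
        arr = arr[:, ~const]
    if arr.shape[1] == 0:
        raise ValueError("no non-constant features left")
    corr_arr = arr if X_corr is None else _as_array(X_corr)
    s_km, s_gmm = _stage_seeds(seed, 2)

    corr = np.corrcoef(corr_arr)
    d = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    hc = fcluster(linkage(squareform(d, checks=False), method="ward"), k,
                  criterion="maxclust")

    km = KMeans(n_clusters=k, n_init=10, random_state=s_km).fit_predict(arr) + 1

    # full covariance needs enough samples per component to stay
    # well-conditioned; otherwise fall back to diagonal
    cov = "full" if arr.shape[0] >= k * (arr.shape[1] + 1) else "diag"
    gmm = GaussianMixture(
        n_components=k, covariance_type=cov, n_init=3, random_state=s_gmm
    ).fit_predict(arr) + 1

    index = X.index if hasattr(X, "index") else pd.RangeIndex(n)
    return pd.DataFrame({"hclust": hc, "kmeans": km, "gmm": gmm}, index=index)


def align_labels(reference_labels, labels) -> np.ndarray:
    """Relabel ``labels`` by the one-to-one mapping maximizing agreement
    with ``reference_labels`` (optimal assignment on the contingency
    table, zero-padded to square when label counts differ)."""
    ref = np.asarray(reference_labels)
    lab = np.asarray(labels)
    if ref.shape != lab.shape:
        raise ValueError("label vectors must have the same length")
    ref_vals, ref_inv = np.unique(ref, return_inverse=True)
    lab_vals, lab_inv = np.unique(lab, return_inverse=True)
    size = max(len(ref_vals), len(lab_vals))
    cont = np.zeros((size, size))
    np.add.at(cont, (lab_inv, ref_inv), 1)
    rows, cols = linear_sum_assignment(-cont)
    mapping = {}
    # clusters matched to a padded (empty) reference column keep fresh ids
    if np.issubdtype(ref_vals.dtype, np.integer):
        fresh = iter(range(int(ref_vals.max()) + 1, int(ref_vals.max()) + size + 1))
    else:
        fresh = iter(f"unmatched_{i}" for i in range(size))
    for r, c in zip(rows, cols):
        if r < len(lab_vals):
            mapping[lab_vals[r]] = ref_vals[c] if c < len(ref_vals) else next(fresh)
    return np.asarray([mapping[v] for v in lab])


def consensus(labels_a, labels_b, labels_c) -> np.ndarray:
    """Unanimity consensus: a sample keeps the common label when all
    three (aligned) methods agree, else AMBIGUOUS (-1)."""
    a, b, c = (np.asarray(v) for v in (labels_a, labels_b, labels_c))
    if not (a.shape == b.shape == c.shape):
        raise ValueError("label vectors must have the same length")
    agree = (a == b) & (a == c)
    return np.where(agree, a, AMBIGUOUS)


def _mean_pairwise_ari(labels: pd.DataFrame) -> float:
    cols = labels.columns
    aris = [
        adjusted_rand_score(labels[cols[i]], labels[cols[j]])
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
    ]
    return float(np.mean(aris))


def select_k(X, k_range=range(2, 7), seed=None, tol: float = 0.01,
             agreement_warn: float = 0.5, X_corr=None):
    """Pick the cluster number where the three methods agree best.

    Agreement per k is the mean pairwise adjusted Rand index among the
    three partitions. Among k values whose agreement is within ``tol``
    of the maximum, the largest k wins: a coarsening of a clean
    partition is just as unanimous as the partition itself, so ties are
    resolved toward the finer, more informative solution. Returns
    ``(k_star, per_k_agreement, low_agreement_flag)``.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    per_k = {}
    seeds = _stage_seeds(seed, len(k_range))
    for k, s in zip(k_range, seeds):
        per_k[k] = _mean_pairwise_ari(
            cluster_three_ways(X, k, seed=s, X_corr=X_corr)
        )
    best = max(per_k.values())
    k_star = max(k for k, a in per_k.items() if a >= best - tol)
    low = best < agreement_warn
    if low:
        warnings.warn(
            f"low clustering agreement (max mean ARI {best:.2f}); "
            "the data may not support distinct clusters"
        )
    return k_star, per_k, low


def extend_to_test(train_X, train_consensus_labels, test_X, tau: float = 0.6,
                   seed=None, n_estimators: int = 100) -> ExtensionResult:
    """Extend consensus labels to held-out samples with a random forest.

    Confidence is the fraction of trees voting the winning class; a test
    sample is retained iff confidence >= tau.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    labels = np.asarray(train_consensus_labels)
    mask = labels != AMBIGUOUS
    Xtr = _as_array(train_X)[mask]
    ytr = labels[mask]
    classes, counts = np.unique(ytr, return_counts=True)
    if len(classes) < 2 or (counts == 0).any():
        raise ValueError("every class needs at least one consensus-labeled training sample")
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=_stage_seeds(seed, 1)[0]
    ).fit(Xtr, ytr)
    Xte = _as_array(test_X)
    # sub-trees predict encoded class indices; map through rf.classes_
    votes = np.stack(
        [t.predict(Xte.astype(np.float32)).astype(int) for t in rf.estimators_]
    )
    pred = np.zeros(Xte.shape[0], dtype=ytr.dtype)
    conf = np.zeros(Xte.shape[0])
    for i in range(Xte.shape[0]):
        cnts = np.bincount(votes[:, i], minlength=len(rf.classes_))
        j = int(np.argmax(cnts))
        pred[i], conf[i] = rf.classes_[j], cnts[j] / len(rf.estimators_)
    index = test_X.index if hasattr(test_X, "index") else pd.RangeIndex(Xte.shape[0])
    table = pd.DataFrame(
        {"label": pred, "confidence": conf, "retained": conf >= tau}, index=index
    )
    return ExtensionResult(table=table, tau=tau)


class ConsensusClusterer(BaseEstimator, ClusterMixin):
    """Three-way consensus clustering with classifier extension.

    Parameters
    ----------
    n_clusters : int or "auto"
        Number of clusters, or "auto" to pick it by the agreement rule
        over ``k_range``.
    k_range : iterable of int
        Candidate cluster numbers for "auto".
    n_top_genes : int
        Number of highly-variable features (variance in excess of the
        mean-variance trend) used for clustering.
    n_pcs : int or None
        Project the standardized features onto this many principal
        components before clustering (None disables the projection).
    scale : bool
        Standardize each retained feature to unit variance.
    tau : float
        Confidence threshold for extending labels to new samples.
    random_state : int or None
        Seed for all stochastic steps (method seeds derived from it).

    Attributes
    ----------
    k_ : selected cluster number
    labels_ : consensus labels (AMBIGUOUS = -1 for disagreement)
    labels_by_method_ : aligned per-method labels, DataFrame
    agreement_score_ : mean pairwise ARI among the methods at k_
    per_k_agreement_ : dict of agreement per candidate k (auto mode)
    """

    def __init__(self, n_clusters=3, k_range=range(2, 7), n_top_genes=150,
                 n_pcs=5, scale=True, tau=0.6, n_estimators=100,
                 random_state=None):
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.n_top_genes = n_top_genes
        self.n_pcs = n_pcs
        self.scale = scale
        self.tau = tau
        self.n_estimators = n_estimators
        self.random_state = random_state

    # -- internal -----------------------------------------------------
    def _prepare_fit(self, X) -> np.ndarray:
        arr = _as_array(X)
        if arr.ndim != 2 or arr.shape[0] < 3:
            raise ValueError("need a 2-D matrix with at least 3 samples")
        var = arr.var(axis=0)
        keep = np.flatnonzero(var > 0)
        if keep.size == 0:
            raise ValueError("all features are constant")
        if keep.size < var.size:
            warnings.warn(f"dropping {var.size - keep.size} constant feature(s)")
        if keep.size > self.n_top_genes:
            keep = keep[highly_variable_genes(arr[:, keep], self.n_top_genes)]
        self.feature_indices_ = keep
        if hasattr(X, "columns"):
            self.feature_names_ = X.columns[keep]
        sub = arr[:, keep]
        self.feature_means_ = sub.mean(axis=0)
        self.feature_scales_ = (
            sub.std(axis=0, ddof=0) if self.scale else np.ones(keep.size)
        )
        Z = (sub - self.feature_means_) / self.feature_scales_
        self._train_genes_Z = Z
        if self.n_pcs is not None and self.n_pcs < min(Z.shape):
            from sklearn.decomposition import PCA

            self._pca = PCA(n_components=self.n_pcs, svd_solver="full").fit(Z)
            Z = self._pca.transform(Z)
        else:
            self._pca = None
        return Z

    def _prepare_new(self, X) -> np.ndarray:
        if hasattr(X, "columns") and hasattr(self, "feature_names_"):
            missing = self.feature_names_.difference(X.columns)
            if len(missing):
                raise KeyError(f"missing features: {missing[:10].tolist()}")
            arr = X[self.feature_names_].to_numpy(dtype=float)
        else:
            arr = _as_array(X)[:, self.feature_indices_]
        Z = (arr - self.feature_means_) / self.feature_scales_
        return self._pca.transform(Z) if self._pca is not None else Z

    # -- estimator API ------------------------------------------------
    def fit(self, X, y=None):
        Z = self._prepare_fit(X)
        seeds = _stage_seeds(self.random_state, 3)
        if self.n_clusters == "auto":
            self.k_, self.per_k_agreement_, self.low_agreement_ = select_k(
                Z, self.k_range, seed=seeds[0], X_corr=self._train_genes_Z
            )
        else:
            self.k_ = int(self.n_clusters)
            self.per_k_agreement_ = None
            self.low_agreement_ = False
        raw = cluster_three_ways(Z, self.k_, seed=seeds[1],
                                 X_corr=self._train_genes_Z)
        if hasattr(X, "index"):
            raw.index = X.index
        aligned = raw.copy()
        for m in ("kmeans", "gmm"):
            aligned[m] = align_labels(raw["hclust"], raw[m])
        cons = consensus(aligned["hclust"], aligned["kmeans"], aligned["gmm"])
        self.labels_by_method_ = aligned
        self.labels_ = cons
        self.agreement_score_ = _mean_pairwise_ari(aligned)
        self._train_Z = Z
        self._rf_seed = seeds[2]
        index = X.index if hasattr(X, "index") else pd.RangeIndex(len(cons))
        self.result_ = ClusterResult(
            k=self.k_,
            labels_by_method=aligned,
            consensus_label=pd.Series(cons, index=index, name="consensus"),
            agreement_score=self.agreement_score_,
            seed=self.random_state,
        )
        return self

    def extend(self, X, tau=None) -> ExtensionResult:
        """Predict cluster labels for new samples with vote confidence."""
        if not hasattr(self, "labels_"):
            raise RuntimeError("fit the clusterer first")
        tau = self.tau if tau is None else tau
        Z = self._prepare_new(X)
        res = extend_to_test(
            self._train_Z, self.labels_, Z, tau=tau, seed=self._rf_seed,
            n_estimators=self.n_estimators,
        )
        if hasattr(X, "index"):
            res.table.index = X.index
        return res

    def predict(self, X) -> np.ndarray:
        return self.extend(X, tau=0.0).table["label"].to_numpy()

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
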