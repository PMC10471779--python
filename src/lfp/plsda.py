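"""Two-component PLS-DA via NIPALS for group-discrimination plots.

Partial least-squares discriminant analysis projects samples onto a few
latent components chosen to preserve the covariance between the
(centered, optionally unit-scaled) expression matrix and a one-hot
encoding of the group labels. The NIPALS inner loop is a power
iteration, so the first weight vector is the dominant eigenvector of
X'Y Y'X; successive components are extracted after rank-one deflation
of X, which makes the score vectors mutually orthogonal. Signs are
fixed per component (largest-magnitude weight entry positive) so fits
are reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["PLSDA", "fit_plsda"]


class PLSDA(BaseEstimator, TransformerMixin):
    """NIPALS PLS-DA.

    Parameters
    ----------
    n_components : int, default 2
    scale : bool
        Unit-scale the columns of X (constant columns are dropped with
        a warning when scaling).
    tol : float
        Convergence tolerance on the score vector between iterations.
    max_iter : int
        Iteration cap per component.

    Attributes
    ----------
    x_weights_ : (n_features, n_components) unit-norm weight vectors
    x_loadings_, y_loadings_ : deflation loadings
    x_scores_ : (n_samples, n_components) training scores
    x_rotations_ : projection matrix accounting for deflation, so
        ``transform(X) = (X - mean) / scale @ x_rotations_``
    classes_ : class labels in one-hot column order
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 tol: float = 1e-10, max_iter: int = 500):
        self.n_components = n_components
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self._feature_names = pd.Index(X.columns)
            arr = X.to_numpy(dtype=float)
        else:
            self._feature_names = None
            arr = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("PLS-DA needs at least 2 classes")
        n, d = arr.shape
        if not (1 <= self.n_components < min(n, d)):
            raise ValueError(
                f"n_components must lie in [1, min(n_samples, n_features)), "
                f"got {self.n_components} for shape {arr.shape}"
            )

        keep = np.arange(d)
        sd = arr.std(axis=0, ddof=1)
        if self.scale and (sd == 0).any():
            warnings.warn(f"dropping {(sd == 0).sum()} constant feature(s)")
            keep = np.flatnonzero(sd > 0)
            arr, sd = arr[:, keep], sd[keep]
        self.feature_indices_ = keep
        if self._feature_names is not None:
            self.feature_names_in_ = self._feature_names[keep]

        self.x_mean_ = arr.mean(axis=0)
        self.x_scale_ = sd if self.scale else np.ones(arr.shape[1])
        Xc = (arr - self.x_mean_) / self.x_scale_

        Y = (y[:, None] == classes[None, :]).astype(float)
        Yc = Y - Y.mean(axis=0)
        self.classes_ = classes

        A = self.n_components
        W = np.zeros((Xc.shape[1], A))
        P = np.zeros((Xc.shape[1], A))
        Q = np.zeros((Yc.shape[1], A))
        T = np.zeros((n, A))
        Xd, Yd = Xc.copy(), Yc.copy()
        for a in range(A):
            u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
            t_old = np.zeros(n)
            for _ in range(self.max_iter):
                w = Xd.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    raise ValueError("degenerate component (zero weight vector)")
                w /= nw
                t = Xd @ w
                q = Yd.T @ t / (t @ t)
                u = Yd @ q / (q @ q)
                if np.linalg.norm(t - t_old) < self.tol * max(np.linalg.norm(t), 1.0):
                    break
                t_old = t
            j = int(np.argmax(np.abs(w)))
            if w[j] < 0:
                w, t, q = -w, -t, -q
            p = Xd.T @ t / (t @ t)
            Xd = Xd - np.outer(t, p)
            Yd = Yd - np.outer(t, q)
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, p, q, t

        self.x_weights_, self.x_loadings_, self.y_loadings_ = W, P, Q
        self.x_scores_ = T
        self.x_rotations_ = W @ np.linalg.pinv(P.T @ W)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "x_rotations_"):
            raise RuntimeError("fit the model first")
        if hasattr(X, "columns") and self._feature_names is not None:
            missing = self.feature_names_in_.difference(X.columns)
            if len(missing):
                raise KeyError(f"missing genes: {missing[:10].tolist()}")
            arr = X[self.feature_names_in_].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)[:, self.feature_indices_]
        return ((arr - self.x_mean_) / self.x_scale_) @ self.x_rotations_

    def fit_transform(self, X, y=None):
        return self.fit(X, y).x_scores_


def fit_plsda(X, labels, n_components: int = 2, scale: bool = True) -> PLSDA:
    """Functional wrapper around :class:`PLSDA`."""
    return PLSDA(n_components=n_components, scale=scale).fit(X, labels)
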