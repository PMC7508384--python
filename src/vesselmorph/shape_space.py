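"""PCA shape space over normalized Fourier coefficient vectors.

Each outline's size-normalized coefficient vector becomes a point; the
principal components of the pooled coefficient matrix define a common
shape space in which a trial traces a trajectory from its pre-formed
shape to the final vessel.  Scores on the first three components usually
capture the bulk of the shape variance, so stage-wise dispersion is
summarised by Euclidean distances from group mean locations in 3D.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["ShapeSpacePCA", "fit_shape_space", "project", "stage_distances"]


class ShapeSpacePCA(TransformerMixin, BaseEstimator):
    """Centered PCA via spectral decomposition of the covariance matrix.

    PCA is run on the covariance (not correlation) matrix: after size
    normalization all coefficients share one scale, so no per-feature
    standardisation is applied.  Components are ordered by decreasing
    variance with a deterministic sign convention (the largest-magnitude
    loading of each component is positive), making scores reproducible
    across runs and platforms.

    Attributes after ``fit``: ``mean_``, ``components_`` (rows, all of
    them), ``explained_variance_``, ``explained_variance_ratio_``.
    ``transform`` returns scores on the first ``n_components``.
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        cov = (Xc.T @ Xc) / (X.shape[0] - 1)
        total = float(np.trace(cov))
        if total <= 0:
            raise ValueError("degenerate input: zero total variance")
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # deterministic sign: largest-|loading| entry positive
        for j in range(evecs.shape[1]):
            i = np.argmax(np.abs(evecs[:, j]))
            if evecs[i, j] < 0:
                evecs[:, j] = -evecs[:, j]
        self.components_ = evecs.T
        self.explained_variance_ = evals
        self.explained_variance_ratio_ = evals / evals.sum()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, k: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: expected {self.n_features_in_} features, "
                f"got {X.shape[1]}"
            )
        k = self.n_components if k is None else k
        return (X - self.mean_) @ self.components_[:k].T


def fit_shape_space(coeff_matrix: np.ndarray, n_components: int = 3) -> ShapeSpacePCA:
    """Fit the PCA shape space over coefficient-vector rows."""
    return ShapeSpacePCA(n_components=n_components).fit(coeff_matrix)


def project(space: ShapeSpacePCA, coeffs: np.ndarray, k: int = 3) -> np.ndarray:
    """Scores of one or more coefficient vectors on the first k components."""
    return space.transform(coeffs, k=k)


def stage_distances(
    scores: np.ndarray,
    trial_ids,
    grouping,
    stage_label: str = "",
) -> pd.DataFrame:
    """Euclidean distance of each trial's shape from its group mean shape.

    ``scores`` holds one row per trial at a single stage (typically the
    3D shape-space scores); ``grouping`` assigns each trial to the pool
    whose mean location is the reference — the full potter pool, or a
    single community's pool.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    grouping = np.asarray(grouping)
    trial_ids = np.asarray(trial_ids)
    if len(grouping) != scores.shape[0] or len(trial_ids) != scores.shape[0]:
        raise ValueError("scores, trial_ids and grouping must align")
    out = []
    for g in pd.unique(grouping):
        m = grouping == g
        if not np.any(m):
            raise ValueError(f"empty group {g!r}")
        mu = scores[m].mean(axis=0)
        d = np.linalg.norm(scores[m] - mu, axis=1)
        for tid, dist in zip(trial_ids[m], d):
            out.append(
                {"trial_id": tid, "stage": stage_label, "group": g,
                 "distance": float(dist)}
            )
    return pd.DataFrame(out)
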