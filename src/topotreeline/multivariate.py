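"""Correlation-matrix principal components analysis of monthly
meteorological summaries.

The 20 summary variables mix units (degC, %, W/m2, counts), so the PCA
operates on the correlation scale: columns are z-scored and the
eigendecomposition is of the correlation matrix. Loadings follow a fixed
sign convention (the largest-magnitude entry of each component is
positive) so tables reproduce bit-for-bit across runs and platforms.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["standardize", "CorrelationPCA", "pca", "biplot_coordinates"]


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return pd.DataFrame(np.asarray(matrix, dtype=float))


def standardize(matrix) -> pd.DataFrame:
    """Column-wise z-scores (sample SD, ddof=1).

    Raises
    ------
    ValueError
        Naming the first zero-variance column, if any.
    """
    df = _as_frame(matrix)
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("matrix contains non-finite entries")
    sd = df.std(ddof=1)
    dead = sd[sd == 0]
    if len(dead):
        raise ValueError(f"zero-variance column: {dead.index[0]!r}")
    return (df - df.mean()) / sd


class CorrelationPCA(TransformerMixin, BaseEstimator):
    """PCA on the correlation matrix with a deterministic sign convention.

    Parameters
    ----------
    n_components : int or None
        Number of components kept; ``None`` keeps all.

    Attributes
    ----------
    loadings_ : DataFrame (variables x components)
        Unit-norm eigenvectors of the correlation matrix, columns
        ``PC1..PCk``, ordered by decreasing eigenvalue. The
        largest-|loading| entry of each column is positive.
    explained_variance_ : ndarray
        Eigenvalues (they sum to the number of variables).
    explained_variance_ratio_ : ndarray
        Eigenvalues / total variance; sums to 1 over all components.
    scores_ : DataFrame (rows x components)
        Standardized training data projected onto the loadings.
    """

    def __init__(self, n_components: Optional[int] = None):
        self.n_components = n_components

    def fit(self, X, y=None) -> "CorrelationPCA":
        df = _as_frame(X)
        z = standardize(df)
        corr = np.asarray(z.corr().to_numpy())
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval = np.maximum(eigval[order], 0.0)
        eigvec = eigvec[:, order]
        # sign convention: dominant entry of each component positive
        for j in range(eigvec.shape[1]):
            k = np.argmax(np.abs(eigvec[:, j]))
            if eigvec[k, j] < 0:
                eigvec[:, j] = -eigvec[:, j]
        k = self.n_components or len(eigval)
        names = [f"PC{i + 1}" for i in range(k)]
        self.n_features_in_ = df.shape[1]
        self.feature_names_in_ = np.asarray(df.columns)
        self.mean_ = df.mean().to_numpy()
        self.scale_ = df.std(ddof=1).to_numpy()
        self.eigenvalues_all_ = eigval
        self.explained_variance_ = eigval[:k]
        self.explained_variance_ratio_ = eigval[:k] / eigval.sum()
        self.loadings_ = pd.DataFrame(eigvec[:, :k], index=df.columns, columns=names)
        self.scores_ = pd.DataFrame(
            z.to_numpy() @ eigvec[:, :k], index=df.index, columns=names
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        df = _as_frame(X)
        z = (df.to_numpy() - self.mean_) / self.scale_
        return pd.DataFrame(
            z @ self.loadings_.to_numpy(),
            index=df.index,
            columns=self.loadings_.columns,
        )

    def cumulative_variance(self, k: int) -> float:
        """Proportion of total variance carried by the first k axes."""
        return float(self.explained_variance_ratio_[:k].sum())


def pca(matrix, n_components: Optional[int] = None) -> CorrelationPCA:
    """Fit a :class:`CorrelationPCA` and return it."""
    return CorrelationPCA(n_components=n_components).fit(matrix)


def biplot_coordinates(result: CorrelationPCA, axis_pair: tuple[int, int] = (1, 2)):
    """Loading vectors and row scores for one axis pair (1-based).

    Returns ``(variable_vectors, row_points)`` — DataFrames of shape
    (n_variables x 2) and (n_rows x 2) — ready for plotting or export.
    """
    k = result.loadings_.shape[1]
    for ax in axis_pair:
        if not 1 <= ax <= k:
            raise ValueError(f"axis {ax} out of range (1..{k})")
    cols = [f"PC{ax}" for ax in axis_pair]
    return result.loadings_[cols].copy(), result.scores_[cols].copy()
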