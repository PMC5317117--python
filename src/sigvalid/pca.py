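"""PCA engine: scores, loadings, explained variance, and sign orientation.

With variables scaled to unit variance, PCA is the eigendecomposition of the
gene-gene correlation matrix: explained_variance_pct[i] = 100 * lambda_i /
sum(lambda). Computation goes through the singular value decomposition of the
samples x genes matrix (numerically stabler than forming the correlation
matrix explicitly), with lambda_i = s_i^2 / (n - 1).

The sign of any principal component is arbitrary; a 180-degree rotation
(negating scores and loadings together) leaves the model equivalent. A
deterministic orientation policy is applied so that results are reproducible
and comparable across runs: components are flipped toward positive
correlation with a reference vector when one is given, otherwise toward a
positive largest-magnitude loading.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateDataError
from .preprocessing import ScaledMatrix

logger = logging.getLogger(__name__)

__all__ = ["PCAModel", "OrientedPCA", "fit_pca", "orient_model"]

#: relative eigenvalue threshold below which a component is considered null
RANK_TOL = 1e-12


@dataclass
class PCAModel:
    """A fitted PCA model: per-sample scores t and per-gene loadings p.

    ``scores`` is samples x k, ``loadings`` genes x k (unit-norm orthonormal
    columns), and ``explained_variance_pct`` the percentage of total variance
    captured by each retained component. ``eigenvalues`` holds the full
    correlation-matrix spectrum so explained-variance profiles can extend
    beyond k.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_pct: np.ndarray
    eigenvalues: np.ndarray
    k: int
    gene_ids: list[str] | None = None
    sample_ids: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_genes(self) -> int:
        return self.loadings.shape[0]

    def full_explained_variance_pct(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return 100.0 * self.eigenvalues / total


class OrientedPCA(BaseEstimator, TransformerMixin):
    """PCA of standardized data with a deterministic sign-orientation policy.

    Follows the sklearn convention: ``fit(X)`` with X samples x features,
    ``transform`` projects onto the loadings. Input is expected to be
    standardized already (see :class:`~sigvalid.preprocessing.GeneScaler`);
    this class centers nothing.

    Parameters
    ----------
    n_components : int or None
        Components to retain; default ``min(5, rank bound)`` where the rank
        bound is ``min(n_features, n_samples - 1)``.
    reference : array-like or None
        Per-feature reference values. Each component whose loadings correlate
        (nonzero) with the reference is flipped so the correlation is
        positive; without a reference (or at zero correlation) the largest-
        magnitude loading is made positive.

    Attributes
    ----------
    loadings_ : (n_features, k) array with orthonormal columns.
    scores_ : (n_samples, k) array, ``X @ loadings_``.
    explained_variance_pct_ : (k,) percentages of total variance.
    eigenvalues_ : full spectrum ``s_i^2 / (n - 1)``.
    """

    def __init__(self, n_components: int | None = None, reference=None):
        self.n_components = n_components
        self.reference = reference

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        n, p = X.shape
        rank_bound = min(p, n - 1)
        if rank_bound < 1:
            raise DegenerateDataError("need at least 2 samples and 1 feature")
        k = self.n_components if self.n_components is not None else min(5, rank_bound)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k > rank_bound:
            raise DegenerateDataError(
                f"n_components={k} exceeds rank bound min(n_features, "
                f"n_samples - 1) = {rank_bound}"
            )
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        eigenvalues = s**2 / (n - 1)
        total = eigenvalues.sum()
        if total <= 0:
            raise DegenerateDataError("input matrix has zero total variance")
        numerical_rank = int((eigenvalues > eigenvalues[0] * RANK_TOL).sum())
        if k > numerical_rank:
            warnings.warn(
                f"requested {k} components but numerical rank is "
                f"{numerical_rank}; trailing components have ~zero variance",
                RuntimeWarning,
                stacklevel=2,
            )
        loadings = Vt[:k].T
        scores = U[:, :k] * s[:k]
        loadings, scores = _orient(
            loadings,
            scores,
            None if self.reference is None else np.asarray(self.reference, float),
        )
        self.n_features_in_ = p
        self.n_components_ = k
        self.numerical_rank_ = numerical_rank
        self.eigenvalues_ = eigenvalues
        self.explained_variance_pct_ = 100.0 * eigenvalues[:k] / total
        self.loadings_ = loadings
        self.scores_ = scores
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than at fit")
        return X @ self.loadings_

    def to_model(
        self,
        gene_ids: list[str] | None = None,
        sample_ids: list[str] | None = None,
    ) -> PCAModel:
        return PCAModel(
            scores=self.scores_,
            loadings=self.loadings_,
            explained_variance_pct=self.explained_variance_pct_,
            eigenvalues=self.eigenvalues_,
            k=self.n_components_,
            gene_ids=gene_ids,
            sample_ids=sample_ids,
        )


def _orient(
    loadings: np.ndarray, scores: np.ndarray, reference: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the sign policy column-by-column; scores and loadings flip together."""
    loadings = loadings.copy()
    scores = scores.copy()
    for j in range(loadings.shape[1]):
        v = loadings[:, j]
        sign = 0.0
        if reference is not None and reference.std() > 0 and v.std() > 0:
            r = float(np.corrcoef(v, reference)[0, 1])
            if abs(r) > 1e-12:
                sign = np.sign(r)
        if sign == 0.0:
            i = int(np.argmax(np.abs(v)))
            if v[i] != 0:
                sign = np.sign(v[i])
            else:  # exact-zero tie: orient toward positive first element
                logger.info("component %d all-zero loadings; kept as-is", j + 1)
                sign = 1.0
        if sign < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return loadings, scores


def fit_pca(
    scaled: ScaledMatrix,
    k: int | None = None,
    reference: np.ndarray | None = None,
) -> PCAModel:
    """Fit an oriented PCA model to a standardized genes x samples matrix.

    Explained-variance percentages equal eigenvalue shares of the gene-gene
    correlation matrix. ``k`` defaults to ``min(5, rank bound)``. When the
    input is numerically rank-deficient the trailing components are reported
    with ~zero explained variance (warning) rather than raising, so perfectly
    coherent toy inputs do not crash the pipeline.
    """
    est = OrientedPCA(n_components=k, reference=reference)
    est.fit(scaled.samples_by_genes())
    return est.to_model(gene_ids=scaled.gene_ids, sample_ids=scaled.sample_ids)


def orient_model(model: PCAModel, reference: np.ndarray | None = None) -> PCAModel:
    """Re-apply the deterministic sign policy to a fitted model.

    Idempotent; with a reference, each component's loadings end up
    non-negatively correlated with it.
    """
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        if reference.shape[0] != model.loadings.shape[0]:
            raise ValueError("reference length does not match number of genes")
    loadings, scores = _orient(model.loadings, model.scores, reference)
    return replace(model, loadings=loadings, scores=scores)
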