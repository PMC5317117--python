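"""Per-gene standardization applied before every PCA model.

Each gene (variable) is mean-centered and scaled to unit variance across
samples, so that PCA of the result is the eigendecomposition of the gene-gene
correlation matrix. Genes with (numerically) zero variance carry no
correlation information and are dropped before scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateDataError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["GeneScaler", "ScaledMatrix", "scale_genes"]

#: genes with standard deviation below this (log2 scale) are treated as constant
ZERO_VARIANCE_TOL = 1e-12


class GeneScaler(BaseEstimator, TransformerMixin):
    """Standardize each feature to zero mean and unit sample variance.

    Follows the sklearn samples x features convention: rows are samples,
    columns are genes. Uses the sample standard deviation (``ddof=1``);
    correlations and explained-variance ratios are unaffected by the
    denominator choice, but documenting it makes results bit-reproducible.

    Parameters
    ----------
    ddof : int, default 1
        Delta degrees of freedom for the standard deviation.
    drop_zero_variance : bool, default True
        Remove features whose standard deviation is below ``tol`` instead of
        producing NaNs. Dropped feature indices are available as
        ``dropped_idx_``.
    tol : float, default 1e-12
        Zero-variance threshold on the standard deviation.
    """

    def __init__(
        self,
        ddof: int = 1,
        drop_zero_variance: bool = True,
        tol: float = ZERO_VARIANCE_TOL,
    ):
        self.ddof = ddof
        self.drop_zero_variance = drop_zero_variance
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x genes)")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=self.ddof)
        keep = self.scale_ > self.tol
        if self.drop_zero_variance:
            self.keep_mask_ = keep
        else:
            if not keep.all():
                raise DegenerateDataError(
                    f"{int((~keep).sum())} zero-variance features present"
                )
            self.keep_mask_ = np.ones(X.shape[1], dtype=bool)
        self.dropped_idx_ = np.flatnonzero(~self.keep_mask_)
        if self.keep_mask_.sum() < 2:
            raise DegenerateDataError(
                "fewer than 2 features survive zero-variance filtering"
            )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than at fit")
        Xk = X[:, self.keep_mask_]
        return (Xk - self.mean_[self.keep_mask_]) / self.scale_[self.keep_mask_]


@dataclass
class ScaledMatrix:
    """A standardized genes x samples matrix with scaling provenance.

    Every surviving row has mean 0 and sample standard deviation 1 across
    samples; rows dropped for zero variance are listed in
    ``dropped_gene_ids``.
    """

    data: pd.DataFrame
    gene_means: pd.Series
    gene_sds: pd.Series
    dropped_gene_ids: list[str]
    base_gene_ids: list[str]

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def samples_by_genes(self) -> np.ndarray:
        """The scaled data as a samples x genes array (PCA orientation)."""
        return self.data.to_numpy(dtype=float).T

    def restrict(self, gene_ids: list[str]) -> "ScaledMatrix":
        """Row-subset to ``gene_ids`` (matrix order is preserved by caller)."""
        sub = self.data.loc[gene_ids]
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ScaledMatrix(
            data=sub,
            gene_means=self.gene_means.loc[gene_ids],
            gene_sds=self.gene_sds.loc[gene_ids],
            dropped_gene_ids=[],
            base_gene_ids=[self.base_gene_ids[i] for i in idx],
        )


def scale_genes(matrix: ExpressionMatrix) -> ScaledMatrix:
    """Mean-center and unit-variance scale every gene across samples.

    Thin wrapper over :class:`GeneScaler` operating on the genes x samples
    ``ExpressionMatrix``. Zero-variance genes are removed (logged); an error
    is raised if fewer than 2 genes survive.
    """
    scaler = GeneScaler()
    scaler.fit(matrix.values.T)  # samples x genes
    keep = scaler.keep_mask_
    dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if dropped:
        logger.warning(
            "dropped %d zero-variance genes before scaling: %s%s",
            len(dropped),
            ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    scaled = scaler.transform(matrix.values.T).T  # back to genes x samples
    kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    kept_base = [b for b, k in zip(matrix.base_gene_ids, keep) if k]
    data = pd.DataFrame(scaled, index=kept_ids, columns=matrix.sample_ids)
    return ScaledMatrix(
        data=data,
        gene_means=pd.Series(scaler.mean_[keep], index=kept_ids),
        gene_sds=pd.Series(scaler.scale_[keep], index=kept_ids),
        dropped_gene_ids=dropped,
        base_gene_ids=kept_base,
    )
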