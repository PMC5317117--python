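"""The four signature-validation statistics and the full pipeline.

A PCA-based signature score (the PC1 score of a signature-restricted PCA)
is trustworthy on a dataset when four properties hold:

* **coherence** — the signature genes co-vary beyond chance: PC1 explained
  variance, in percent, judged against a randomized gene-set null.
* **robustness** — one biological effect dominates: the PC1/PC2
  explained-variance ratio. A ratio near 1 flags a mixed, multi-biology
  signature whose leading component can switch between datasets.
* **uniqueness** — the signature is distinct from the dataset's general
  direction: |Pearson r| between signature PC1 scores and all-gene PC1
  scores. Low is good; random sets track the dominant direction.
* **transferability** — the model measures the intended biology: squared
  Pearson r between PC1 loadings and the signature's reference values
  (squaring makes the value orientation-free).

Pearson correlation is used throughout; loadings and scores are continuous.
Reference magnitudes are only ever the comparison vector in transferability;
they never re-weight expression values before PCA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import __version__ as _version
from .errors import DegenerateDataError, SigvalidError
from .io import ExpressionMatrix, GeneMatch, SignatureTable, match_genes
from .nulls import NULL_DIRECTIONS, NullDistribution, build_null, empirical_p
from .pca import PCAModel, fit_pca
from .preprocessing import ScaledMatrix, scale_genes

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationStatistics",
    "ValidationReport",
    "SignatureValidator",
    "coherence",
    "robustness",
    "uniqueness",
    "transferability",
    "explained_variance_profile",
    "validate_signature",
]


def coherence(sig_model: PCAModel) -> float:
    """PC1 explained variance (percent) of the signature PCA."""
    return float(sig_model.explained_variance_pct[0])


def robustness(sig_model: PCAModel) -> float:
    """PC1/PC2 explained-variance ratio; >= 1 by eigenvalue ordering.

    When PC2 variance is numerically zero (a perfectly one-dimensional
    signature) the ratio is reported as the +inf sentinel with a warning
    rather than raising.
    """
    ev = sig_model.eigenvalues
    if ev.size < 2 or ev[1] <= ev[0] * 1e-12:
        logger.warning(
            "PC2 explained variance is numerically zero; robustness reported as +inf"
        )
        return float("inf")
    return float(ev[0] / ev[1])


def uniqueness(sig_model: PCAModel, allgene_model: PCAModel) -> float:
    """|Pearson r| between signature PC1 scores and all-gene PC1 scores."""
    if (
        sig_model.sample_ids is not None
        and allgene_model.sample_ids is not None
        and sig_model.sample_ids != allgene_model.sample_ids
    ):
        raise SigvalidError("signature and all-gene models have different samples")
    a = sig_model.scores[:, 0]
    b = allgene_model.scores[:, 0]
    if a.shape != b.shape:
        raise SigvalidError("score vectors differ in length")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("constant PC1 scores; uniqueness undefined")
    return float(abs(np.corrcoef(a, b)[0, 1]))


def transferability(sig_model: PCAModel, match: GeneMatch | np.ndarray) -> float:
    """Squared Pearson r between PC1 loadings and the reference values."""
    reference = (
        match.matched_reference if isinstance(match, GeneMatch) else np.asarray(match, float)
    )
    loadings = sig_model.loadings[:, 0]
    if reference.shape[0] != loadings.shape[0]:
        raise SigvalidError(
            f"reference length {reference.shape[0]} does not match "
            f"{loadings.shape[0]} signature genes"
        )
    if np.unique(reference).size < 2:
        raise DegenerateDataError("constant reference values; correlation undefined")
    if loadings.std() == 0:
        raise DegenerateDataError("constant PC1 loadings; correlation undefined")
    r = float(np.corrcoef(loadings, reference)[0, 1])
    return r * r


def explained_variance_profile(sig_model: PCAModel, n: int = 5) -> np.ndarray:
    """Leading explained-variance percentages for scree-style inspection.

    Returns up to ``n`` values (fewer when the model has fewer components;
    logged). No automatic component-count cutoff is applied — a large drop
    after component m suggests m real effects, and that call is the
    analyst's.
    """
    full = sig_model.full_explained_variance_pct()
    if full.size < n:
        logger.info("only %d components available for the profile", full.size)
    return full[:n]


@dataclass
class ValidationStatistics:
    """The four statistics plus the leading explained-variance profile."""

    coherence_pct: float
    robustness_ratio: float
    uniqueness_abs_r: float
    transferability_r2: float
    ev_profile: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {
            "coherence": self.coherence_pct,
            "robustness": self.robustness_ratio,
            "uniqueness": self.uniqueness_abs_r,
            "transferability": self.transferability_r2,
        }


@dataclass
class ValidationReport:
    """Statistics, null summaries, and provenance for one signature/dataset pair."""

    statistics: ValidationStatistics
    nulls: dict[str, NullDistribution]
    null_means: dict[str, float]
    empirical_p: dict[str, float]
    match: GeneMatch
    signature_name: str
    dataset_name: str
    seed: int
    n_random: int
    loadings_pc1: np.ndarray | None = None

    def summary_row(self) -> dict[str, object]:
        """One row in the fixed summary-table column order."""
        s = self.statistics
        return {
            "signature": self.signature_name,
            "dataset": self.dataset_name,
            "coherence_pct": s.coherence_pct,
            "random_mean_coherence_pct": self.null_means.get("coherence", math.nan),
            "robustness_ratio": s.robustness_ratio,
            "random_mean_robustness_ratio": self.null_means.get("robustness", math.nan),
            "uniqueness_abs_r": s.uniqueness_abs_r,
            "random_mean_uniqueness_abs_r": self.null_means.get("uniqueness", math.nan),
            "transferability_r2": s.transferability_r2,
        }

    def to_text(self) -> str:
        """Structured key-value document (full results + provenance)."""
        lines = [
            f"sigvalid_version\t{_version}",
            f"signature\t{self.signature_name}",
            f"dataset\t{self.dataset_name}",
            f"n_signature\t{self.match.n_signature}",
            f"n_matched\t{self.match.n_matched}",
            f"n_matched_rows\t{self.match.n_rows}",
            f"match_fraction\t{self.match.fraction:.6f}",
            f"seed\t{self.seed}",
            f"n_random\t{self.n_random}",
            f"coherence_pct\t{self.statistics.coherence_pct:.10g}",
            f"robustness_ratio\t{self.statistics.robustness_ratio:.10g}",
            f"uniqueness_abs_r\t{self.statistics.uniqueness_abs_r:.10g}",
            f"transferability_r2\t{self.statistics.transferability_r2:.10g}",
        ]
        for i, v in enumerate(self.statistics.ev_profile, start=1):
            lines.append(f"explained_variance_pc{i}_pct\t{v:.10g}")
        for name in ("coherence", "robustness", "uniqueness"):
            if name in self.null_means:
                lines.append(f"random_mean_{name}\t{self.null_means[name]:.10g}")
            if name in self.empirical_p:
                lines.append(f"empirical_p_{name}\t{self.empirical_p[name]:.10g}")
        return "\n".join(lines) + "\n"


class SignatureValidator(BaseEstimator):
    """Validate a gene signature against an expression dataset.

    ``fit`` runs the whole pipeline: gene matching, per-gene standardization,
    signature-restricted and all-gene PCA, the four statistics, and the
    randomized gene-set null engine. sklearn-style: parameters are set at
    construction, fitted results live in trailing-underscore attributes.

    Parameters
    ----------
    signature : SignatureTable
        Gene ids plus reference values (direction -1/+1 or continuous
        weights).
    n_random : int, default 10000
        Randomized gene-sets per null distribution. 0 skips the null engine
        (statistics only).
    seed : int, default 0
        Seed for the random gene-set stream.
    min_match_fraction : float, default 0.5
        Minimum fraction of signature genes that must be present in the
        matrix.
    n_components : int, default 5
        Components retained in the signature PCA (capped by the rank bound);
        five feeds the scree-style explained-variance profile.
    dataset_name : str, default "dataset"
        Label used in reports.

    Attributes
    ----------
    report_ : ValidationReport
    statistics_ : ValidationStatistics
    nulls_ : dict of NullDistribution (empty when n_random=0)
    signature_model_, allgene_model_ : PCAModel
    match_ : GeneMatch
    """

    def __init__(
        self,
        signature: SignatureTable,
        n_random: int = 10000,
        seed: int = 0,
        min_match_fraction: float = 0.5,
        n_components: int = 5,
        dataset_name: str = "dataset",
    ):
        self.signature = signature
        self.n_random = n_random
        self.seed = seed
        self.min_match_fraction = min_match_fraction
        self.n_components = n_components
        self.dataset_name = dataset_name

    def fit(self, X: ExpressionMatrix | ScaledMatrix, y=None):
        if isinstance(X, ScaledMatrix):
            scaled = X
        elif isinstance(X, ExpressionMatrix):
            scaled = scale_genes(X)
        else:
            scaled = scale_genes(ExpressionMatrix(X))
        # match against the scaled matrix so zero-variance drops are honored
        match = match_genes(scaled, self.signature, self.min_match_fraction)

        sub = scaled.restrict(match.matched_gene_ids)
        n = sub.n_samples
        # >= 3 matched genes and >= 3 samples guarantee a rank bound of >= 2
        rank_bound = min(sub.n_genes, n - 1)
        k_sig = max(2, min(self.n_components, rank_bound))
        sig_model = fit_pca(sub, k=k_sig, reference=match.matched_reference)

        k_all = min(2, min(scaled.n_genes, n - 1))
        allgene_model = fit_pca(scaled, k=k_all)

        stats = ValidationStatistics(
            coherence_pct=coherence(sig_model),
            robustness_ratio=robustness(sig_model),
            uniqueness_abs_r=uniqueness(sig_model, allgene_model),
            transferability_r2=transferability(sig_model, match),
            ev_profile=explained_variance_profile(sig_model),
        )

        nulls: dict[str, NullDistribution] = {}
        null_means: dict[str, float] = {}
        pvals: dict[str, float] = {}
        if self.n_random > 0:
            nulls = build_null(
                scaled,
                allgene_model,
                set_size=match.n_rows,
                n_random=self.n_random,
                seed=self.seed,
            )
            observed = stats.as_dict()
            for name, dist in nulls.items():
                null_means[name] = dist.mean
                pvals[name] = empirical_p(
                    observed[name], dist, NULL_DIRECTIONS[name]
                )
        else:
            logger.warning("n_random=0: statistics computed without null context")

        self.scaled_ = scaled
        self.match_ = match
        self.signature_model_ = sig_model
        self.allgene_model_ = allgene_model
        self.statistics_ = stats
        self.nulls_ = nulls
        self.report_ = ValidationReport(
            statistics=stats,
            nulls=nulls,
            null_means=null_means,
            empirical_p=pvals,
            match=match,
            signature_name=self.signature.name,
            dataset_name=self.dataset_name,
            seed=self.seed,
            n_random=self.n_random,
            loadings_pc1=sig_model.loadings[:, 0].copy(),
        )
        logger.info(
            "validated '%s' on '%s': coherence %.2f%%, robustness %.3g, "
            "uniqueness %.3f, transferability r2 %.3f",
            self.signature.name,
            self.dataset_name,
            stats.coherence_pct,
            stats.robustness_ratio,
            stats.uniqueness_abs_r,
            stats.transferability_r2,
        )
        return self


def validate_signature(
    matrix: ExpressionMatrix,
    signature: SignatureTable,
    n_random: int = 10000,
    seed: int = 0,
    min_match_fraction: float = 0.5,
    dataset_name: str = "dataset",
) -> ValidationReport:
    """Run the full validation pipeline; thin wrapper over SignatureValidator."""
    validator = SignatureValidator(
        signature=signature,
        n_random=n_random,
        seed=seed,
        min_match_fraction=min_match_fraction,
        dataset_name=dataset_name,
    )
    validator.fit(matrix)
    return validator.report_
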