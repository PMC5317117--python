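"""Empirical null distributions from randomized gene-sets.

Every statistic of a signature PCA depends on the dataset, the number of
genes, and any dataset-wide bias, so raw values are not comparable across
datasets. The null engine calibrates them: it repeatedly draws gene-sets of
the same size as the matched signature, uniformly without replacement from
all dataset genes (signature genes included — no exclusion), fits the same
signature-restricted PCA, and records coherence, robustness and uniqueness
for each draw. Transferability has no randomized analogue because random
gene-sets carry no reference values.

One shared stream of random sets evaluates all statistics, and everything is
deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateDataError
from .pca import PCAModel
from .preprocessing import ScaledMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "sample_random_geneset",
    "build_null",
    "empirical_p",
]

#: statistics with a randomized-gene-set analogue
NULL_STATISTICS = ("coherence", "robustness", "uniqueness")

#: tail direction used when comparing each observed statistic to its null
NULL_DIRECTIONS = {"coherence": "greater", "robustness": "greater", "uniqueness": "less"}


@dataclass
class NullDistribution:
    """Values of one statistic over N randomized gene-sets.

    ``values`` holds the finite draws; infinite robustness sentinels (a
    random set whose PC2 variance vanished) are excluded from ``values`` and
    counted in ``n_infinite``, so ``N == len(values) + n_infinite``.
    """

    statistic: str
    values: np.ndarray
    N: int
    set_size: int
    seed: int
    universe_size: int
    n_infinite: int = 0
    n_retries: int = 0

    @property
    def mean(self) -> float:
        """Mean over finite draws (the Table-style 'random mean')."""
        return float(np.mean(self.values)) if self.values.size else float("nan")

    def to_tsv(self, path: str | Path) -> None:
        """Single-column TSV with provenance comment headers."""
        with open(path, "w") as fh:
            fh.write(f"# statistic: {self.statistic}\n")
            fh.write(f"# N: {self.N}\n")
            fh.write(f"# set_size: {self.set_size}\n")
            fh.write(f"# seed: {self.seed}\n")
            fh.write(f"# universe_size: {self.universe_size}\n")
            fh.write(f"# n_infinite: {self.n_infinite}\n")
            fh.write("value\n")
            for v in self.values:
                fh.write(f"{v:.10g}\n")


def sample_random_geneset(universe: list[str], size: int, rng: np.random.Generator):
    """Draw ``size`` distinct gene ids uniformly without replacement."""
    if size > len(universe):
        raise ValueError(
            f"requested set size {size} exceeds universe size {len(universe)}"
        )
    idx = rng.choice(len(universe), size=size, replace=False)
    return [universe[i] for i in idx]


def _random_set_statistics(
    X: np.ndarray, idx: np.ndarray, allgene_t1: np.ndarray | None
) -> tuple[float, float, float | None]:
    """Coherence, robustness, uniqueness of one random gene-set.

    ``X`` is the scaled samples x genes array; ``allgene_t1`` the centered,
    norm-1 all-gene PC1 score vector (or None to skip uniqueness).
    """
    Xs = X[:, idx]
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    ev = s**2
    total = ev.sum()
    if total <= 0 or ev[0] <= 0:
        raise DegenerateDataError("random set has zero variance")
    coherence = 100.0 * ev[0] / total
    robustness = float("inf") if ev[1] <= ev[0] * 1e-12 else float(ev[0] / ev[1])
    uniqueness = None
    if allgene_t1 is not None:
        t1 = U[:, 0]
        t1 = t1 - t1.mean()
        norm = np.linalg.norm(t1)
        if norm == 0:
            raise DegenerateDataError("degenerate random-set scores")
        uniqueness = float(abs(t1 @ allgene_t1) / norm)
    return float(coherence), robustness, uniqueness


def build_null(
    scaled: ScaledMatrix,
    allgene_model: PCAModel | None,
    set_size: int,
    n_random: int = 10000,
    seed: int = 0,
) -> dict[str, NullDistribution]:
    """Build null distributions of coherence, robustness and uniqueness.

    Draws ``n_random`` gene-sets of ``set_size`` from all rows of ``scaled``
    (one shared stream for every statistic), fitting a signature-restricted
    PCA per draw. Draws on which the PCA fails are retried with the next draw
    and counted; more than 1% failures is an error. When ``allgene_model`` is
    None the uniqueness null is omitted.
    """
    if set_size < 3:
        raise ValueError("set_size must be >= 3")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    X = scaled.samples_by_genes()
    n, p = X.shape
    if set_size > p:
        raise ValueError(f"set_size {set_size} exceeds gene universe {p}")
    allgene_t1 = None
    if allgene_model is not None:
        if (
            allgene_model.sample_ids is not None
            and allgene_model.sample_ids != scaled.sample_ids
        ):
            raise ValueError("all-gene model samples differ from the scaled matrix")
        t1 = allgene_model.scores[:, 0].astype(float)
        t1 = t1 - t1.mean()
        norm = np.linalg.norm(t1)
        if norm == 0:
            raise DegenerateDataError("all-gene PC1 scores are constant")
        allgene_t1 = t1 / norm

    rng = np.random.default_rng(seed)
    coh = np.empty(n_random)
    rob = np.empty(n_random)
    uni = np.empty(n_random) if allgene_t1 is not None else None
    n_failures = 0
    max_failures = max(1, int(0.01 * n_random))
    i = 0
    while i < n_random:
        idx = rng.choice(p, size=set_size, replace=False)
        try:
            c, r, u = _random_set_statistics(X, idx, allgene_t1)
        except DegenerateDataError:
            n_failures += 1
            if n_failures > max_failures:
                raise DegenerateDataError(
                    f"more than 1% of random gene-set PCA fits failed "
                    f"({n_failures}/{i + n_failures} draws)"
                )
            continue
        coh[i], rob[i] = c, r
        if uni is not None:
            uni[i] = u  # type: ignore[assignment]
        i += 1
    if n_failures:
        logger.warning("%d random gene-set draws failed and were retried", n_failures)

    def _dist(name: str, values: np.ndarray) -> NullDistribution:
        finite = np.isfinite(values)
        return NullDistribution(
            statistic=name,
            values=values[finite],
            N=n_random,
            set_size=set_size,
            seed=seed,
            universe_size=p,
            n_infinite=int((~finite).sum()),
            n_retries=n_failures,
        )

    out = {"coherence": _dist("coherence", coh), "robustness": _dist("robustness", rob)}
    if uni is not None:
        out["uniqueness"] = _dist("uniqueness", uni)
    return out


def empirical_p(
    observed: float, null: NullDistribution, direction: str = "greater"
) -> float:
    """Add-one empirical p-value: (1 + #as-or-more-extreme) / (N + 1).

    Never returns 0 (an observation beating all N draws gives 1/(N+1)) and is
    at most 1. ``direction='greater'`` counts null values >= observed
    (coherence, robustness); ``'less'`` counts <= observed (uniqueness, where
    a distinct signature shows a *lower* correlation with the dataset's
    general direction than random sets do).
    """
    if direction not in {"greater", "less"}:
        raise ValueError("direction must be 'greater' or 'less'")
    if null.N < 1:
        raise ValueError("null distribution is empty")
    values = null.values
    if direction == "greater":
        # +inf sentinels are as-or-more extreme than any observation
        b = int((values >= observed).sum()) + null.n_infinite
    else:
        b = int((values <= observed).sum())
        if np.isinf(observed):
            b += null.n_infinite
    return (1 + b) / (null.N + 1)
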