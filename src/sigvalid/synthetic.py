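"""Synthetic expression data with planted signature structure.

The generator is a latent factor model chosen because it has closed-form
population correlations and eigenvalues, which makes analytic tests
possible. A gene g in block b with sign s_g and within-block correlation
rho_b is generated as

    x_gs = s_g * sqrt(rho_b) * f_bs  +  beta * h_s * [g bias-loaded]
           + sqrt(1 - rho_b) * noise_sd * eps_gs  +  baseline_g

with f_b (one latent factor per block) and h (a single dataset-wide bias
factor, the stand-in for a dominant proliferation-like direction) standard
normal per sample, and eps independent standard normal. Background genes
carry only the bias term (if loaded) and noise. Two-group factors take +-1
group labels standardized to mean 0, variance 1, so the same closed forms
hold regardless of group balance. At ``noise_sd=1`` the population
within-block correlation is exactly rho_b and a k-gene block has leading
correlation eigenvalue 1 + (k-1) rho.

Per-gene baselines make the output look like log2 intensities; they are
removed by standardization and do not affect any statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SigvalidError
from .io import ExpressionMatrix, SignatureTable

logger = logging.getLogger(__name__)

__all__ = ["Block", "SyntheticDesign", "Manifest", "generate_dataset", "make_signature"]


@dataclass
class Block:
    """One planted gene block sharing a latent factor.

    ``factor`` is "continuous" (Gaussian factor) or "two-group" (+-1 group
    labels, standardized). ``signs`` fixes each gene's direction; None draws
    them +-1 at random from the design seed.
    """

    size: int
    rho: float
    factor: str = "continuous"
    signs: np.ndarray | None = None

    def validate(self) -> None:
        if self.size < 2:
            raise SigvalidError("block size must be >= 2")
        if not (0 <= self.rho < 1):
            raise SigvalidError("block rho must be in [0, 1)")
        if self.factor not in {"continuous", "two-group"}:
            raise SigvalidError(f"unknown factor type: {self.factor!r}")
        if self.signs is not None and len(self.signs) != self.size:
            raise SigvalidError("signs length must equal block size")


@dataclass
class SyntheticDesign:
    """Full description of a synthetic cohort."""

    n_samples: int = 200
    n_background_genes: int = 500
    blocks: list[Block] = field(default_factory=list)
    bias_fraction: float = 0.0
    bias_strength: float = 0.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3:
            raise SigvalidError("need at least 3 samples")
        if self.n_background_genes < 0:
            raise SigvalidError("n_background_genes must be >= 0")
        if not (0 <= self.bias_fraction <= 1):
            raise SigvalidError("bias_fraction must be in [0, 1]")
        if self.bias_strength < 0:
            raise SigvalidError("bias_strength must be >= 0")
        if self.noise_sd <= 0:
            raise SigvalidError("noise_sd must be positive")
        for b in self.blocks:
            b.validate()
        total = sum(b.size for b in self.blocks) + self.n_background_genes
        if total < 2:
            raise SigvalidError("design generates fewer than 2 genes")


@dataclass
class Manifest:
    """Ground truth for a generated dataset.

    ``genes`` has one row per gene: block index (-1 for background), sign,
    planted loading (sign * sqrt(rho), 0 for background) and whether the gene
    is bias-loaded. ``factors`` holds each block's latent factor and
    ``bias_factor`` the dataset-wide bias factor, per sample.
    """

    genes: pd.DataFrame
    factors: dict[int, np.ndarray]
    bias_factor: np.ndarray
    design: SyntheticDesign

    def block_gene_ids(self, block: int) -> list[str]:
        return self.genes.index[self.genes["block"] == block].tolist()

    def background_gene_ids(self) -> list[str]:
        return self.genes.index[self.genes["block"] == -1].tolist()

    def to_text(self) -> str:
        d = self.design
        lines = [
            f"# synthetic dataset manifest (seed={d.seed})",
            f"n_samples\t{d.n_samples}",
            f"n_background_genes\t{d.n_background_genes}",
            f"n_blocks\t{len(d.blocks)}",
            f"bias_fraction\t{d.bias_fraction}",
            f"bias_strength\t{d.bias_strength}",
            f"noise_sd\t{d.noise_sd}",
            "gene_id\tblock\tsign\tloading\tbias_loaded",
        ]
        for gid, row in self.genes.iterrows():
            lines.append(
                f"{gid}\t{int(row['block'])}\t{int(row['sign'])}"
                f"\t{row['loading']:.10g}\t{int(row['bias_loaded'])}"
            )
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def _standardized_two_group(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random half/half +-1 group labels, standardized to mean 0, var 1."""
    labels = np.ones(n)
    labels[: n // 2] = -1.0
    rng.shuffle(labels)
    labels = labels - labels.mean()
    sd = labels.std(ddof=0)
    return labels / sd


def generate_dataset(design: SyntheticDesign) -> tuple[ExpressionMatrix, Manifest]:
    """Generate an expression matrix plus its ground-truth manifest.

    Deterministic given ``design.seed``. Gene ids are ``B<block>G<i>`` for
    block genes and ``BG<i>`` for background genes.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_samples

    factors: dict[int, np.ndarray] = {}
    gene_rows = []
    blocks_values = []
    for b_idx, block in enumerate(design.blocks):
        if block.factor == "two-group":
            f = _standardized_two_group(rng, n)
        else:
            f = rng.standard_normal(n)
        factors[b_idx] = f
        signs = (
            np.asarray(block.signs, dtype=float)
            if block.signs is not None
            else rng.choice([-1.0, 1.0], size=block.size)
        )
        eps = rng.standard_normal((block.size, n))
        values = (
            np.sqrt(block.rho) * np.outer(signs, f)
            + np.sqrt(1 - block.rho) * design.noise_sd * eps
        )
        blocks_values.append(values)
        for i in range(block.size):
            gene_rows.append(
                {
                    "gene_id": f"B{b_idx}G{i:04d}",
                    "block": b_idx,
                    "sign": signs[i],
                    "loading": signs[i] * np.sqrt(block.rho),
                }
            )

    bg = rng.standard_normal((design.n_background_genes, n)) * design.noise_sd
    blocks_values.append(bg)
    for i in range(design.n_background_genes):
        gene_rows.append(
            {"gene_id": f"BG{i:05d}", "block": -1, "sign": 1.0, "loading": 0.0}
        )

    X = np.vstack(blocks_values)
    n_genes = X.shape[0]

    bias_factor = rng.standard_normal(n)
    n_loaded = int(round(design.bias_fraction * n_genes))
    loaded_idx = rng.choice(n_genes, size=n_loaded, replace=False)
    bias_loaded = np.zeros(n_genes, dtype=bool)
    bias_loaded[loaded_idx] = True
    if design.bias_strength > 0 and n_loaded > 0:
        X[bias_loaded] += design.bias_strength * bias_factor

    baselines = rng.normal(design.baseline_mean, design.baseline_sd, size=n_genes)
    X = X + baselines[:, None]

    genes = pd.DataFrame(gene_rows).set_index("gene_id")
    genes["bias_loaded"] = bias_loaded

    sample_ids = [f"S{j:04d}" for j in range(n)]
    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=genes.index.tolist(), columns=sample_ids)
    )
    manifest = Manifest(
        genes=genes, factors=factors, bias_factor=bias_factor, design=design
    )
    logger.info(
        "generated synthetic dataset: %d genes (%d in %d blocks) x %d samples",
        n_genes,
        n_genes - design.n_background_genes,
        len(design.blocks),
        n,
    )
    return matrix, manifest


def make_signature(
    manifest: Manifest,
    blocks: list[int] | None = None,
    dilution: float = 0.0,
    mode: str = "replace",
    reference: str = "sign",
    name: str | None = None,
    seed: int | None = None,
) -> SignatureTable:
    """Build a signature from planted blocks, optionally diluted with noise.

    The base signature is the concatenation of the requested blocks' genes,
    each carrying its planted sign (``reference="sign"``) or planted loading
    (``reference="loading"``) as reference value. A ``dilution`` fraction d
    replaces (default) that share of block genes with background genes whose
    reference values are drawn +-1 at random — or appends them when
    ``mode="append"`` — mirroring a signature progressively contaminated
    with unrelated genes while its nominal size stays fixed.

    A dilution leaving fewer than 3 true genes warns (the deliberate extreme
    stress case) but does not raise.
    """
    if blocks is None:
        blocks = sorted(manifest.factors.keys())
    for b in blocks:
        if b not in manifest.factors:
            raise SigvalidError(f"block {b} not present in manifest")
    if not (0 <= dilution < 1):
        raise SigvalidError("dilution must be in [0, 1)")
    if mode not in {"replace", "append"}:
        raise SigvalidError("mode must be 'replace' or 'append'")
    if reference not in {"sign", "loading"}:
        raise SigvalidError("reference must be 'sign' or 'loading'")

    rng = np.random.default_rng(
        manifest.design.seed + 104729 if seed is None else seed
    )
    ref_col = "sign" if reference == "sign" else "loading"
    block_ids: list[str] = []
    for b in blocks:
        block_ids.extend(manifest.block_gene_ids(b))
    n_total = len(block_ids)

    if mode == "replace":
        n_noise = int(round(dilution * n_total))
        n_keep = n_total - n_noise
        keep_idx = np.sort(rng.choice(n_total, size=n_keep, replace=False))
        kept = [block_ids[i] for i in keep_idx]
    else:
        n_noise = int(round(dilution / (1 - dilution) * n_total))
        kept = list(block_ids)
    if len(kept) < 3:
        warnings.warn(
            f"dilution {dilution} leaves only {len(kept)} true signature genes",
            UserWarning,
            stacklevel=2,
        )

    background = manifest.background_gene_ids()
    if n_noise > len(background):
        raise SigvalidError(
            f"dilution needs {n_noise} background genes, only {len(background)} exist"
        )
    noise_ids = [
        background[i]
        for i in np.sort(rng.choice(len(background), size=n_noise, replace=False))
    ]

    entries: list[tuple[str, float]] = [
        (g, float(manifest.genes.loc[g, ref_col])) for g in kept
    ]
    entries += [(g, float(rng.choice([-1.0, 1.0]))) for g in noise_ids]
    if name is None:
        tag = "+".join(str(b) for b in blocks)
        name = f"block{tag}" + (f"-d{dilution:g}" if dilution else "")
    logger.info(
        "signature '%s': %d block genes + %d background genes (mode=%s)",
        name,
        len(kept),
        n_noise,
        mode,
    )
    return SignatureTable(entries, name=name)
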