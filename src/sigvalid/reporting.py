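"""Summary tables and validation figures.

The four-panel validation figure shows, for one signature/dataset pair:
(a) the coherence null histogram with the observed value marked,
(b) the same for robustness, (c) the same for uniqueness, and
(d) PC1 loadings against the reference values with the transferability r^2.
Null histograms use a fixed 50-bin rule so images are reproducible.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .nulls import NullDistribution
from .pca import PCAModel
from .validation import ValidationReport

logger = logging.getLogger(__name__)

__all__ = [
    "SUMMARY_COLUMNS",
    "summary_table",
    "write_summary",
    "render_validation_figure",
    "render_score_scatter",
]

#: fixed column order of the summary table
SUMMARY_COLUMNS = [
    "signature",
    "dataset",
    "coherence_pct",
    "random_mean_coherence_pct",
    "robustness_ratio",
    "random_mean_robustness_ratio",
    "uniqueness_abs_r",
    "random_mean_uniqueness_abs_r",
    "transferability_r2",
]

_HIST_BINS = 50


def summary_table(reports: list[ValidationReport]) -> pd.DataFrame:
    """Stack reports into a DataFrame with the fixed column order."""
    rows = [r.summary_row() for r in reports]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary(reports: list[ValidationReport], path: str | Path) -> None:
    summary_table(reports).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _null_panel(ax, null: NullDistribution | None, observed: float, title, xlabel):
    if null is None or null.values.size == 0:
        ax.axvline(observed, color="crimson", lw=2)
        ax.set_title(f"{title} (no null available)", fontsize=10)
        ax.text(
            0.5,
            0.5,
            "null distribution missing",
            transform=ax.transAxes,
            ha="center",
            color="gray",
        )
    else:
        ax.hist(null.values, bins=_HIST_BINS, color="steelblue", alpha=0.8)
        if math.isfinite(observed):
            ax.axvline(observed, color="crimson", lw=2, label="observed")
        obs_txt = f"{observed:.3g}" if math.isfinite(observed) else "inf"
        ax.set_title(
            f"{title}: observed {obs_txt}, null mean {null.mean:.3g}\n"
            f"(N={null.N}, seed={null.seed})",
            fontsize=9,
        )
    ax.set_xlabel(xlabel)
    ax.set_ylabel("random gene-sets")


def render_validation_figure(
    report: ValidationReport,
    nulls: dict[str, NullDistribution] | None = None,
    path: str | Path = "validation.png",
) -> Path:
    """Render the four-panel validation figure to PNG/SVG/PDF by extension.

    Panels a-c fall back to an observed-only marker with a warning banner
    when nulls are missing; a +-1 (direction-only) reference renders panel d
    as a strip plot over the two loading columns.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    nulls = nulls if nulls is not None else report.nulls
    s = report.statistics
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    _null_panel(
        axes[0, 0],
        nulls.get("coherence"),
        s.coherence_pct,
        "(a) coherence",
        "PC1 explained variance (%)",
    )
    _null_panel(
        axes[0, 1],
        nulls.get("robustness"),
        s.robustness_ratio,
        "(b) robustness",
        "PC1/PC2 explained-variance ratio",
    )
    _null_panel(
        axes[1, 0],
        nulls.get("uniqueness"),
        s.uniqueness_abs_r,
        "(c) uniqueness",
        "|r| with all-gene PC1 scores",
    )

    ax = axes[1, 1]
    ref = report.match.matched_reference
    loadings = report.loadings_pc1
    if loadings is None:
        # degrade to a three-panel figure when no transferability is available
        ax.set_axis_off()
    else:
        if np.unique(ref).size == 2 and set(np.unique(ref)) <= {-1.0, 1.0}:
            # direction-only reference: strip plot over the two loading columns
            for val, color in ((-1.0, "steelblue"), (1.0, "darkorange")):
                y = loadings[ref == val]
                x = val + 0.08 * (np.arange(y.size) / max(1, y.size - 1) - 0.5)
                ax.scatter(x, y, s=18, color=color, alpha=0.8)
            ax.set_xticks([-1, 1])
            ax.set_xlim(-2, 2)
        else:
            ax.scatter(ref, loadings, s=18, color="steelblue", alpha=0.8)
        ax.axhline(0, color="gray", lw=0.5)
        ax.set_title(
            f"(d) transferability: r$^2$ = {s.transferability_r2:.3f}", fontsize=10
        )
        ax.set_xlabel("reference value")
        ax.set_ylabel("PC1 loading")

    fig.suptitle(
        f"Validation: {report.signature_name} on {report.dataset_name}", fontsize=12
    )
    fig.tight_layout(rect=(0, 0, 1, 0.96))
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    logger.info("wrote validation figure %s", path)
    return path


def render_score_scatter(
    model_a: PCAModel,
    model_b: PCAModel,
    path: str | Path = "scores.png",
    labels: pd.Series | None = None,
    name_a: str = "model A",
    name_b: str = "model B",
) -> Path:
    """PC1-vs-PC1 score scatter with Pearson r^2 annotation.

    ``labels`` (optional, per sample) colors the points categorically — the
    idiom used to show e.g. gender separation on top of two signature scores.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if (
        model_a.sample_ids is not None
        and model_b.sample_ids is not None
        and model_a.sample_ids != model_b.sample_ids
    ):
        raise ValueError("models were fitted on different samples")
    a = model_a.scores[:, 0]
    b = model_b.scores[:, 0]
    if a.shape != b.shape:
        raise ValueError("score vectors differ in length")
    r = float(np.corrcoef(a, b)[0, 1])

    fig, ax = plt.subplots(figsize=(5, 5))
    if labels is not None:
        labels = pd.Series(labels)
        for i, cat in enumerate(pd.unique(labels)):
            m = (labels == cat).to_numpy()
            ax.scatter(a[m], b[m], s=16, alpha=0.8, label=str(cat))
        ax.legend(fontsize=8)
    else:
        ax.scatter(a, b, s=16, color="steelblue", alpha=0.8)
    ax.set_xlabel(f"{name_a} PC1 score")
    ax.set_ylabel(f"{name_b} PC1 score")
    ax.set_title(f"r$^2$ = {r * r:.3f}", fontsize=11)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
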