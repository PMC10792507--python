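"""Figures: mirrored indicator histograms, similarity heatmap, dendrogram,
d-distribution histograms.

Every figure has a tabular twin written elsewhere in the pipeline;
nothing is plotted that is not also available as TSV.  Vector output
(SVG/PDF) is the default and is byte-stable across runs: the SVG hash
salt and document date are pinned.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .clustering import Dendrogram
from .homogeneity import HomogeneityResult

__all__ = [
    "plot_summary",
    "plot_similarity",
    "plot_dendrogram",
    "plot_d_histograms",
]

plt.rcParams["svg.hashsalt"] = "degcompare"


def _save(fig, outpath: str | Path) -> Path:
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(outpath, metadata=_stable_metadata(outpath))
    plt.close(fig)
    return outpath


def _stable_metadata(outpath: Path) -> dict | None:
    suffix = outpath.suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".pdf":
        return {"CreationDate": None}
    return None


def plot_summary(summary: pd.DataFrame, outpath: str | Path) -> Path:
    """Mirrored histogram of DEG counts (up) and specific fractions
    (down, sign-flipped) per experiment, with a companion R bar panel.

    ``summary`` is the table from :func:`degcompare.indicators.summarize`.
    """
    if len(summary) == 0:
        raise ValueError("empty summary table")
    exps = list(summary.index)
    x = np.arange(len(exps))
    fig, (ax_top, ax_r) = plt.subplots(
        2, 1, figsize=(max(6, 0.45 * len(exps)), 7), sharex=True,
        gridspec_kw={"height_ratios": [2, 1]},
    )

    n_scaled = summary["n"] / summary["n"].max()
    ax_top.bar(x, n_scaled, color="#3b6ea5", label="DEG count (scaled)")
    ax_top.bar(
        x, -summary["specific_fraction"], color="#b2532e",
        label="specific fraction (mirrored)",
    )
    ax_top.axhline(0.0, color="black", lw=0.8)
    ax_top.set_ylabel("n (scaled)  /  −δ")
    ax_top.legend(loc="upper right", fontsize=8)
    for xi, n in zip(x, summary["n"]):
        ax_top.text(xi, n_scaled.iloc[xi] + 0.02, str(int(n)),
                    ha="center", va="bottom", fontsize=7)

    ax_r.bar(x, summary["R"], color="#4a7c59")
    ax_r.axhline(1.0, color="black", lw=0.8, ls="--")
    ax_r.set_ylabel("R")
    ax_r.set_xticks(x)
    ax_r.set_xticklabels(exps, rotation=90, fontsize=8)
    fig.tight_layout()
    return _save(fig, outpath)


def plot_similarity(
    matrix: pd.DataFrame, outpath: str | Path, *, order: list[str] | None = None
) -> Path:
    """Heatmap of the pairwise similarity matrix, annotated to 2 decimals.

    Rows/columns follow input order unless ``order`` (e.g. dendrogram
    leaves) is given.
    """
    if order is not None:
        matrix = matrix.loc[order, order]
    exps = list(matrix.index)
    n = len(exps)
    fig, ax = plt.subplots(figsize=(max(5, 0.5 * n + 2),) * 2)
    im = ax.imshow(matrix.to_numpy(), vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(n))
    ax.set_yticks(range(n))
    ax.set_xticklabels(exps, rotation=90, fontsize=8)
    ax.set_yticklabels(exps, fontsize=8)
    if n <= 25:
        for i in range(n):
            for j in range(n):
                v = matrix.iat[i, j]
                ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                        fontsize=6, color="white" if v < 0.6 else "black")
    fig.colorbar(im, ax=ax, label="similarity index I", shrink=0.8)
    fig.tight_layout()
    return _save(fig, outpath)


def plot_dendrogram(dend: Dendrogram, outpath: str | Path) -> Path:
    """Dendrogram of the experiment clustering; bootstrap supports, when
    present, annotate the internal nodes."""
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(dend.labels)), 5))
    info = hierarchy.dendrogram(
        dend.linkage, labels=dend.labels, ax=ax, leaf_rotation=90,
        color_threshold=0.0, above_threshold_color="black",
    )
    if dend.support is not None:
        leafsets = dend.bipartitions()
        # locate each internal node in the drawing by its merge height
        for leafset, (_a, _b, height, _size) in zip(leafsets, dend.linkage):
            sup = dend.support.get(leafset)
            if sup is None:
                continue
            for xs, ys in zip(info["icoord"], info["dcoord"]):
                if abs(max(ys) - height) < 1e-9:
                    ax.text(0.5 * (xs[1] + xs[2]), height, f"{sup:.2f}",
                            ha="center", va="bottom", fontsize=7, color="#7a1f1f")
                    break
    ax.set_ylabel("Ward.D2 merge height")
    fig.tight_layout()
    return _save(fig, outpath)


def plot_d_histograms(result: HomogeneityResult, outpath: str | Path) -> Path:
    """One histogram of the resampled d distribution per subsample size k,
    with the percentile interval and zero marked."""
    ks = [r.k for r in result.results]
    ncol = min(4, len(ks))
    nrow = int(np.ceil(len(ks) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False
    )
    for ax in axes.flat[len(ks):]:
        ax.set_visible(False)
    for ax, r in zip(axes.flat, result.results):
        d = r.d_samples
        lo, hi = int(d.min()), int(d.max())
        bins = max(10, min(40, hi - lo + 1))
        ax.hist(d, bins=bins, color="#3b6ea5")
        ax.axvline(0, color="black", lw=0.8)
        ax.axvline(r.ci[0], color="#b2532e", lw=0.8, ls="--")
        ax.axvline(r.ci[1], color="#b2532e", lw=0.8, ls="--")
        flag = "*" if r.significant else ""
        ax.set_title(f"k = {r.k}{flag}", fontsize=9)
        ax.set_xlabel("d")
    fig.suptitle(f"verdict: {result.verdict}", fontsize=10)
    fig.tight_layout()
    return _save(fig, outpath)
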