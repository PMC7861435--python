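"""Diagnostic figures for an evaluation report.

Static matplotlib figures mirroring the audit: real-vs-artificial allele
frequencies, binned LD decay, pairwise-distance histograms, and the joint
PCA scatter.  Import cost is deferred so headless library use never touches
a matplotlib backend.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .haplotypes import HaplotypeMatrix
from .metrics import (
    allele_freq_comparison,
    joint_pca,
    ld_decay,
    pairwise_distance_distributions,
)

__all__ = ["plot_report"]


def plot_report(
    real: HaplotypeMatrix,
    art: HaplotypeMatrix,
    out_dir: str | Path,
    fmt: str = "png",
) -> list[Path]:
    """Write the four standard comparison figures; returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pairs, corr = allele_freq_comparison(real, art)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(pairs[:, 0], pairs[:, 1], s=8, alpha=0.6)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("real allele frequency")
    ax.set_ylabel("artificial allele frequency")
    ax.set_title(f"r = {corr:.3f}" if np.isfinite(corr) else "r undefined")
    written.append(_save(fig, out / f"allele_freq.{fmt}"))

    try:
        decay = ld_decay(real, art)
    except ValueError:
        decay = None
    if decay is not None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(decay["bin_centers"], decay["real"], label="real")
        ax.plot(decay["bin_centers"], decay["art"], label="artificial")
        ax.set_xlabel("distance")
        ax.set_ylabel(r"mean $r^2$")
        ax.legend()
        written.append(_save(fig, out / f"ld_decay.{fmt}"))

    pw = pairwise_distance_distributions(real, art)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    bins = np.histogram_bin_edges(
        np.concatenate([pw["within_real"], pw["within_art"]]), bins=40
    )
    ax.hist(pw["within_real"], bins=bins, alpha=0.5, density=True, label="within real")
    ax.hist(pw["within_art"], bins=bins, alpha=0.5, density=True,
            label="within artificial")
    ax.set_xlabel("pairwise Hamming distance")
    ax.set_ylabel("density")
    ax.legend()
    written.append(_save(fig, out / f"pairwise_distances.{fmt}"))

    coords_real, coords_art = joint_pca([real, art], n_components=2)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(coords_real[:, 0], coords_real[:, 1], s=8, alpha=0.5,
               c="gray", label="real")
    ax.scatter(coords_art[:, 0], coords_art[:, 1], s=8, alpha=0.5,
               c="tab:red", label="artificial")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    written.append(_save(fig, out / f"joint_pca.{fmt}"))
    return written


def _save(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)
    return path
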