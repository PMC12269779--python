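"""Optional matplotlib figures for the validation report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .distances import BarcodingGapResult
from .similarity import SimilarityProfile


def plot_similarity_profile(
    profile: SimilarityProfile,
    path: str | Path,
    primer_sites: dict[str, tuple[int, int]] | None = None,
) -> None:
    """Two-track conservation figure: similarity index + sequence proportion."""
    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.fill_between(
        profile.window_start, profile.proportion, color="0.8", label="proportion of sequences"
    )
    ax.fill_between(
        profile.window_start, profile.index, color="seagreen", alpha=0.7,
        label="similarity index (1/D)",
    )
    if primer_sites:
        for name, (lo, hi) in primer_sites.items():
            ax.axvline(lo, ls="--", lw=0.8, color="crimson")
            ax.axvline(hi, ls="--", lw=0.8, color="crimson")
            ax.text(lo, 1.02, name, fontsize=7, rotation=90, va="bottom")
    ax.set_xlabel("alignment position (window start)")
    ax.set_ylabel("index / proportion")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_barcoding_gap(result: BarcodingGapResult, path: str | Path) -> None:
    """Overlaid intra/inter distance frequency histograms."""
    fig, ax = plt.subplots(figsize=(7, 4))
    centers = (result.bin_edges[:-1] + result.bin_edges[1:]) / 2
    width = result.bin_width * 0.9
    ax.bar(centers, result.intra_histogram, width=width, color="firebrick",
           alpha=0.7, label="intraspecific")
    ax.bar(centers, result.inter_histogram, width=width, color="steelblue",
           alpha=0.6, label="interspecific")
    ax.axvline(result.max_intra, ls="--", color="firebrick", lw=0.8)
    ax.axvline(result.min_inter, ls="--", color="steelblue", lw=0.8)
    ax.set_xlabel("K80 distance (substitutions/site)")
    ax.set_ylabel("pair count")
    ax.set_title(f"barcoding gap = {result.gap:.3f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
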