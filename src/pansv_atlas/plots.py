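"""Plain matplotlib views of window densities and saturation curves."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .enrichment import SaturationCurve
from .hotspots import WindowStat


def plot_window_density(
    windows: Sequence[WindowStat], path: str, flagged: Optional[Sequence[WindowStat]] = None
) -> None:
    """Per-chromosome SV density with hotspot windows highlighted."""
    chroms = sorted({w.interval.chrom for w in windows})
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2.2 * len(chroms)), squeeze=False)
    flagged_keys = {
        (w.interval.chrom, w.interval.start) for w in (flagged or [])
    }
    for ax, chrom in zip(axes[:, 0], chroms):
        ws = [w for w in windows if w.interval.chrom == chrom]
        xs = [w.interval.start / 1e6 for w in ws]
        ys = [w.value for w in ws]
        colors = [
            "crimson" if (chrom, w.interval.start) in flagged_keys else "steelblue"
            for w in ws
        ]
        ax.bar(xs, ys, width=(ws[0].interval.length / 1e6) * 0.9, color=colors)
        ax.set_ylabel("SV starts")
        ax.set_title(chrom, loc="left", fontsize=9)
    axes[-1, 0].set_xlabel("position (Mbp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_saturation(curve: SaturationCurve, path: str) -> None:
    """Mean +/- SD of distinct genes captured vs genomes sampled."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(curve.k, curve.mean_genes, yerr=curve.sd_genes, fmt="-o", ms=3, lw=1)
    ax.set_xlabel("genomes sampled")
    ax.set_ylabel("distinct genes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
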