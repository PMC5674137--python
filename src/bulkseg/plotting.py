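"""Per-scaffold track plots: pool SNP-indices, signed delta, |delta| with thresholds."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .windows import ThresholdSet, Window


def plot_scaffold_tracks(
    windows: Sequence[Window],
    scaffold: str,
    thresholds: ThresholdSet | None = None,
    path: str | Path | None = None,
):
    """Four stacked tracks over one scaffold (x in Mb): index A, index B, delta, |delta|.

    Threshold lines are drawn on the track matching ``thresholds.statistic``.
    Returns the figure; saves to ``path`` when given.
    """
    ws = [w for w in windows if w.scaffold == scaffold]
    if not ws:
        raise ValueError(f"no windows on scaffold {scaffold!r}")
    x = [(w.start + w.end) / 2 / 1e6 for w in ws]

    fig, axes = plt.subplots(4, 1, figsize=(9, 8), sharex=True)
    tracks = [
        ("SNP-index (pool A)", [w.mean_index_a for w in ws], (0, 1)),
        ("SNP-index (pool B)", [w.mean_index_b for w in ws], (0, 1)),
        ("Δ(SNP-index)", [w.mean_delta for w in ws], (-1, 1)),
        ("|Δ(SNP-index)|", [w.mean_abs_delta for w in ws], (0, 1)),
    ]
    for ax, (label, values, ylim) in zip(axes, tracks):
        ax.plot(x, values, lw=1.0, color="tab:blue")
        ax.set_ylabel(label, fontsize=8)
        ax.set_ylim(*ylim)
        ax.axhline(0.0, color="0.8", lw=0.5)
    if thresholds is not None:
        ax = axes[2] if thresholds.statistic == "delta" else axes[3]
        ax.axhline(thresholds.upper_value, color="tab:red", ls="--", lw=0.8)
        if thresholds.lower_quantile is not None and not math.isnan(thresholds.lower_value):
            ax.axhline(thresholds.lower_value, color="tab:red", ls="--", lw=0.8)
    axes[-1].set_xlabel(f"{scaffold} position (Mb)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
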