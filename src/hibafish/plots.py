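"""Diagnostic figures: distance jitter plots, proportion crossbars,
spot-count histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["jitter_plot", "crossbar_plot", "spot_count_plot"]


def jitter_plot(alleles_by_condition: dict[str, pd.DataFrame],
                threshold_px: float = 4.0,
                out: str | Path | None = None):
    """Per-condition jitter of per-Red minimum Red/Green distances.

    The dashed line marks the separation threshold; points above it are
    breakage events.
    """
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(alleles_by_condition), 4))
    rng = np.random.default_rng(0)
    for i, (label, df) in enumerate(alleles_by_condition.items()):
        y = df["rg_min_px"].to_numpy()
        x = i + rng.uniform(-0.25, 0.25, size=len(y))
        ax.plot(x, y, ".", ms=2, alpha=0.4)
        ax.annotate(f"n={len(y)}", (i, ax.get_ylim()[1]), ha="center", fontsize=7)
    ax.axhline(threshold_px, color="red", ls="--", lw=1)
    ax.set_xticks(range(len(alleles_by_condition)),
                  list(alleles_by_condition), rotation=30, ha="right")
    ax.set_ylabel("min Red/Green distance (px)")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def crossbar_plot(summary: pd.DataFrame, event_class: str,
                  out: str | Path | None = None):
    """Positive-cell frequency per condition with its 95% CI (crossbars)."""
    sub = summary[summary["event_class"] == event_class].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(sub), 4))
    for i, row in sub.iterrows():
        for v, lw in ((row["proportion"], 2), (row["ci_low"], 1), (row["ci_high"], 1)):
            ax.hlines(100 * v, i - 0.3, i + 0.3, lw=lw, color="k")
        ax.vlines(i, 100 * row["ci_low"], 100 * row["ci_high"], lw=0.8, color="k")
    ax.set_xticks(range(len(sub)), sub["condition"], rotation=30, ha="right")
    ax.set_ylabel(f"% cells with ≥ 1 {event_class} event")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def spot_count_plot(freqs_by_condition: dict[str, pd.Series],
                    channel: str, out: str | Path | None = None):
    """Spot-count histograms (relative frequency per count) per condition."""
    n = len(freqs_by_condition)
    fig, axes = plt.subplots(1, max(1, n), figsize=(3 * max(1, n), 3),
                             squeeze=False)
    for ax, (label, freq) in zip(axes[0], freqs_by_condition.items()):
        ax.bar(freq.index.astype(int), freq.values, width=0.9)
        ax.set_title(f"{label} ({channel})", fontsize=8)
        ax.set_xlabel("spots per nucleus")
        ax.set_ylabel("fraction of nuclei")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
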