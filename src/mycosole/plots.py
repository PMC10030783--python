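"""Figure export helpers (coverage maps, ISI histograms, amplitude summaries)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .measures import CoverageMap

__all__ = ["plot_coverage", "plot_isi_histograms", "plot_amplitude_differences"]


def plot_coverage(coverage: CoverageMap, path, title: str = "Coverage frequency") -> None:
    """Greyscale coverage-frequency map: never covered = black, maximum = white."""
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.imshow(coverage.normalized(), cmap="gray", vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_title(title)
    ax.set_xlabel("j (nodes)")
    ax.set_ylabel("i (nodes)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_isi_histograms(hist: pd.DataFrame, path) -> None:
    """Overlaid per-condition inter-spike-interval histograms on one axis."""
    fig, ax = plt.subplots(figsize=(6, 4))
    width = float(np.diff(hist.index)[0]) if len(hist) > 1 else 60.0
    for k, cond in enumerate(hist.columns):
        ax.bar(
            hist.index + 0.5 * width, hist[cond], width=width * 0.9,
            alpha=0.5, label=cond, zorder=2 + k,
        )
    ax.set_xlabel("inter-spike interval (s)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_amplitude_differences(diffs: pd.Series, path) -> None:
    """Per-channel signed mean amplitude difference (even - no-load), mV."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(diffs)), diffs.to_numpy())
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(range(len(diffs)), list(diffs.index), rotation=45, ha="right")
    ax.set_ylabel("even − no-load spike amplitude (mV)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
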