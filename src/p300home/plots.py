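"""Diagnostic plots: averaged ERPs and display/accuracy comparisons."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .preprocess import EpochSet, average_erps

__all__ = ["plot_average_erps", "plot_display_comparison"]


def plot_average_erps(epochs: EpochSet, out: str | Path, channel: str | None = "Pz"):
    """Target vs non-target grand-average ERP at one channel."""
    target, nontarget = average_erps(epochs)
    idx = epochs.channel_names.index(channel) if channel in epochs.channel_names else 0
    t = np.arange(epochs.samples_per_epoch) / epochs.sampling_rate * 1000
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t, target[idx], label="target", color="tab:red")
    ax.plot(t, nontarget[idx], label="non-target", color="tab:gray")
    ax.axvline(300, ls=":", color="k", lw=0.8)
    ax.set_xlabel("time after flash onset (ms)")
    ax.set_ylabel("amplitude (uV)")
    ax.set_title(f"Averaged ERPs at {epochs.channel_names[idx]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def plot_display_comparison(
    target_means: dict[str, np.ndarray], sampling_rate: float, out: str | Path
):
    """Overlay grand-average target ERPs of the two displays (one channel)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, wave in target_means.items():
        t = np.arange(len(wave)) / sampling_rate * 1000
        ax.plot(t, wave, label=label)
    ax.axvline(300, ls=":", color="k", lw=0.8)
    ax.set_xlabel("time after flash onset (ms)")
    ax.set_ylabel("amplitude (uV)")
    ax.set_title("Target ERP by display")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
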