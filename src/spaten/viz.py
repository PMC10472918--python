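"""Plots: relevance overlay on signal traces and QRS-locked average curves."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .relevance import EventLockedAverage, RelevanceMatrix  # noqa: E402

__all__ = ["plot_relevance_overlay", "plot_event_locked", "plot_kernels"]


def plot_relevance_overlay(
    data: np.ndarray,
    relevance: RelevanceMatrix,
    fs: float = 250.0,
    channel_labels=None,
    path=None,
):
    """Stacked signal traces with a signed red/blue relevance underlay.

    Red marks influence toward predicting female (negative relevance), blue
    toward male (positive).
    """
    n_ch, n_t = data.shape
    t = np.arange(n_t) / fs
    vmax = np.abs(relevance.values).max() or 1.0
    fig, ax = plt.subplots(figsize=(10, 0.45 * n_ch + 1))
    offset = 3.0 * data.std()
    for c in range(n_ch):
        base = -c * offset
        ax.imshow(
            relevance.values[c][None, :],
            aspect="auto",
            extent=(t[0], t[-1], base - 0.45 * offset, base + 0.45 * offset),
            cmap="bwr_r",
            vmin=-vmax,
            vmax=vmax,
            alpha=0.6,
        )
        ax.plot(t, data[c] + base, color="k", lw=0.5)
    ax.set_xlim(t[0], t[-1])
    ax.set_yticks([-c * offset for c in range(n_ch)])
    ax.set_yticklabels(channel_labels or [str(c) for c in range(n_ch)])
    ax.set_xlabel("time (s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_event_locked(avg: EventLockedAverage, fs: float = 250.0, path=None):
    """QRS-locked mean |R| with the mean ECG template for reference."""
    t_ms = avg.lags / fs * 1000.0
    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    axes[0].plot(t_ms, avg.mean_abs_relevance, color="purple")
    axes[0].set_ylabel("mean |R|")
    if avg.mean_ecg is not None:
        axes[1].plot(t_ms, avg.mean_ecg, color="k")
    axes[1].set_ylabel("mean ECG (uV)")
    axes[1].set_xlabel("lag from R peak (ms)")
    axes[0].set_title(f"QRS-locked average ({avg.n_events} events)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_kernels(model, path=None):
    """Montage of learned kernels, red frame = female weight, blue = male."""
    K = model.kernels
    n = K.shape[0]
    cols = min(n, 8)
    rows = -(-n // cols)
    vmax = np.abs(K).max() or 1.0
    fig, axes = plt.subplots(rows, cols, figsize=(1.6 * cols, 1.6 * rows),
                             squeeze=False)
    for k in range(rows * cols):
        ax = axes[k // cols][k % cols]
        ax.axis("off")
        if k < n:
            ax.imshow(K[k], aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            color = "tab:blue" if model.dense_weights[k] >= 0 else "tab:red"
            ax.set_title(f"w={model.dense_weights[k]:+.2f}", fontsize=7, color=color)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
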