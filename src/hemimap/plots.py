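"""Minimal rendering of composite histograms and V-plot matrices."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_composite(hist, peaks=None, path=None):
    """Stacked left/right end-count bars with optional called maxima."""
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(hist.offsets, hist.left, width=1.0, color="tab:blue", label="left ends")
    ax.bar(
        hist.offsets, hist.right, width=1.0, bottom=hist.left,
        color="tab:pink", label="right ends",
    )
    if peaks is not None:
        for off in peaks.offsets:
            ax.axvline(off, color="k", lw=0.5, ls="--")
    ax.set_xlabel("offset from mid-Cen (bp)")
    ax.set_ylabel("end count")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_vplot(matrix, path=None, overlay=None):
    """Density rendering of a V-plot count matrix, with optional overlay track."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(
        matrix.counts,
        origin="lower",
        aspect="auto",
        extent=[-matrix.flank, matrix.flank, 1, matrix.max_length],
        cmap="Blues",
    )
    if overlay is not None:
        ax2 = ax.twinx()
        ax2.plot(matrix.offsets, overlay, color="tab:green", lw=1)
    ax.set_xlabel(f"{matrix.mode} offset (bp)")
    ax.set_ylabel("fragment length (bp)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
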