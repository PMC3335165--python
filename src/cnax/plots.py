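"""Figure exports: genome frequency plot, call heatmap, binned correlation map.

Figures are derived artifacts regenerated from cached TSVs; nothing reads
them back.
"""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _chromosome_boundaries(clone_map: pd.DataFrame):
    chroms = clone_map["chromosome"].to_numpy()
    bounds, labels, centers = [], [], []
    start = 0
    for chrom in pd.unique(chroms):
        n = int((chroms == chrom).sum())
        bounds.append(start + n)
        labels.append(str(chrom))
        centers.append(start + n / 2)
        start += n
    return bounds, labels, centers


def frequency_plot(freq: pd.DataFrame, clone_map: pd.DataFrame, path) -> None:
    """Gains upward, losses downward, chromosome boundaries marked."""
    fig, ax = plt.subplots(figsize=(14, 4))
    x = np.arange(len(freq))
    if len(freq) == 0:
        warnings.warn("empty frequency table; writing empty axes", stacklevel=2)
    else:
        ax.bar(x, freq["frac_gain"].to_numpy(), width=1.0, color="firebrick", label="gain")
        ax.bar(x, -freq["frac_loss"].to_numpy(), width=1.0, color="seagreen", label="loss")
        bounds, labels, centers = _chromosome_boundaries(clone_map)
        for b in bounds[:-1]:
            ax.axvline(b - 0.5, color="purple", lw=0.6)
        ax.set_xticks(centers)
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
        ax.legend(loc="upper right", fontsize=8)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("fraction of samples")
    ax.set_ylim(-1, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def call_heatmap(calls: pd.DataFrame, path) -> None:
    """Per-sample aberration heatmap (samples as rows, genome order columns)."""
    fig, ax = plt.subplots(figsize=(14, 6))
    if calls.size:
        ax.imshow(
            calls.to_numpy(dtype=float).T, aspect="auto", cmap="RdYlGn_r",
            vmin=-2, vmax=2, interpolation="nearest",
        )
    else:
        warnings.warn("empty call matrix; writing empty axes", stacklevel=2)
    ax.set_xlabel("clone (genome order)")
    ax.set_ylabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def binned_correlation_heatmap(matrix: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 6))
    if matrix.size:
        im = ax.imshow(matrix.to_numpy(dtype=float), cmap="RdBu_r", vmin=-0.3, vmax=0.3,
                       interpolation="nearest")
        fig.colorbar(im, ax=ax, label="mean pairwise r")
    ax.set_xlabel("copy-number bin")
    ax.set_ylabel("expression bin")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
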