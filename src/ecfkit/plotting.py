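"""Matplotlib views of the core objects: crosstalk heatmaps, information
content profiles of bipartite models, and switch transfer functions."""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .crosstalk_analysis import CrosstalkMatrix
from .motif_model import PromoterModel, information_content
from .switch_titration import TransferFunction


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def crosstalk_heatmap(matrix: CrosstalkMatrix, ax=None, log: bool = True):
    """Heatmap of a sigma x promoter matrix (log2 colour scale for folds)."""
    ax = _ax(ax)
    values = matrix.data.values
    if log and matrix.kind.startswith("fold"):
        values = np.log2(values)
    im = ax.imshow(values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(matrix.promoter_ids)))
    ax.set_xticklabels(matrix.promoter_ids, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.sigma_ids)))
    ax.set_yticklabels(matrix.sigma_ids, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label=f"log2 {matrix.kind}" if log else matrix.kind)
    return ax


def model_information_profile(model: PromoterModel, ax=None):
    """Bar plot of per-position information content for both blocks, with
    consensus letters as tick labels (a minimal sequence-logo view)."""
    ax = _ax(ax)
    ic35, _ = information_content(model.pwm35)
    ic10, _ = information_content(model.pwm10)
    gap = 2
    x35 = np.arange(len(ic35))
    x10 = np.arange(len(ic10)) + len(ic35) + gap
    ax.bar(x35, ic35, color="tab:blue", label="-35 block")
    ax.bar(x10, ic10, color="tab:orange", label="-10 block")
    ticks = list(x35) + list(x10)
    labels = list(model.pwm35.consensus) + list(model.pwm10.consensus)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels)
    ax.set_ylabel("bits")
    ax.set_title(
        f"subgroup {model.subgroup}: modal spacer {model.spacer.modal_length} nt"
    )
    ax.legend()
    return ax


def transfer_curves(tfs: Sequence[TransferFunction], labels: Optional[Sequence[str]] = None, ax=None):
    """Overlay transfer functions on log-log axes."""
    ax = _ax(ax)
    for i, tf in enumerate(tfs):
        label = labels[i] if labels else None
        ax.plot(tf.inputs, tf.outputs, marker="o", label=label)
    ax.set_xscale("symlog")
    ax.set_yscale("log")
    ax.set_xlabel("input activity")
    ax.set_ylabel("output fluorescence")
    if labels:
        ax.legend()
    return ax
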