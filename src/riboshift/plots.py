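"""Minimal plotting helpers (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def te_scatter(rna_log2fc, ribo_log2fc, enhanced_mask, path,
               thresholds=None) -> None:
    """RNA vs Ribo log2 fold-change scatter with the enhanced-TE set
    highlighted; dashed lines mark the classification bounds."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(rna_log2fc, ribo_log2fc, s=6, c="0.7", label="other")
    ax.scatter(rna_log2fc[enhanced_mask], ribo_log2fc[enhanced_mask],
               s=10, c="crimson", label="enhanced TE")
    if thresholds is not None:
        for x in (-thresholds.rna_abs_log2fc, thresholds.rna_abs_log2fc):
            ax.axvline(x, ls="--", lw=0.8, c="k")
        for y in (-thresholds.ribo_abs_log2fc, thresholds.ribo_abs_log2fc):
            ax.axhline(y, ls="--", lw=0.8, c="k")
    ax.set_xlabel("RNA-seq log2 fold change")
    ax.set_ylabel("Ribo-seq log2 fold change")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
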