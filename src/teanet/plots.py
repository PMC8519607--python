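"""Optional static figures (PCA score plot, volcano plot).

Thin matplotlib wrappers; all statistics come from the analysis modules.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless: files only
import matplotlib.pyplot as plt

from .differential import DamResult, volcano_table
from .profiling import GroupAssignment, PCAResult

__all__ = ["pca_plot", "volcano_plot"]


def pca_plot(pca: PCAResult, groups: GroupAssignment | None, path) -> None:
    """PC1/PC2 score scatter, coloured by group, QC projections in grey."""
    fig, ax = plt.subplots(figsize=(6, 5))
    scores = pca.scores
    bio = scores.loc[pca.fitted_samples]
    if groups is not None:
        for g in sorted(set(groups.labels)):
            pts = bio.loc[groups.labels.index[groups.labels == g]]
            ax.scatter(pts["PC1"], pts["PC2"], s=18, label=f"group {g}")
        ax.legend(frameon=False)
    else:
        ax.scatter(bio["PC1"], bio["PC2"], s=18)
    qc = scores.drop(index=pca.fitted_samples)
    if len(qc):
        ax.scatter(qc["PC1"], qc["PC2"], s=24, c="0.4", marker="x", label="QC")
    ax.set_xlabel(f"PC1 ({pca.variance_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pca.variance_pct[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def volcano_plot(dam: DamResult, path) -> None:
    """log2 fold change vs -log10 q, DAMs highlighted."""
    tab = volcano_table(dam)
    fig, ax = plt.subplots(figsize=(6, 5))
    hit = tab["is_dam"]
    ax.scatter(tab.loc[~hit, "log2_fc"], tab.loc[~hit, "neg_log10_q"], s=10, c="0.6")
    ax.scatter(tab.loc[hit, "log2_fc"], tab.loc[hit, "neg_log10_q"], s=14, c="crimson")
    import numpy as np

    ax.axhline(-np.log10(dam.fdr_gate), ls=":", c="0.3", lw=0.8)
    for x in (-np.log2(dam.fc_gate), np.log2(dam.fc_gate)):
        ax.axvline(x, ls=":", c="0.3", lw=0.8)
    a, b = dam.pair
    ax.set_xlabel(f"log2 fold change (group {a} / group {b})")
    ax.set_ylabel("-log10 FDR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
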