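"""Evidence plots: chimeric heatmap with the two intragenic profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .model import ChimericHeatmap, IntragenicProfile

__all__ = ["plot_fusion_evidence"]


def plot_fusion_evidence(
    hm: ChimericHeatmap,
    prof_a: IntragenicProfile,
    prof_b: IntragenicProfile,
    breakpoint: tuple[int, int] | None = None,
):
    """Three-panel figure: exon-exon heatmap, 5' profile, 3' profile.

    ``breakpoint`` (i, j), if given, is marked on all panels.  Returns the
    matplotlib Figure.
    """
    fig, (ax_hm, ax_a, ax_b) = plt.subplots(
        1, 3, figsize=(11, 3.2), gridspec_kw={"width_ratios": [1.6, 1, 1]}
    )
    na, nb = hm.matrix.shape
    im = ax_hm.imshow(hm.matrix, aspect="auto", origin="upper", cmap="inferno")
    ax_hm.set_xlabel(f"{hm.variant_b.gene_symbol} first retained exon (j)")
    ax_hm.set_ylabel(f"{hm.variant_a.gene_symbol} last retained exon (i)")
    ax_hm.set_title(f"{hm.fusion_id} chimeric probes")
    ax_hm.set_xticks(np.arange(nb), [str(k) for k in range(1, nb + 1)], fontsize=6)
    ax_hm.set_yticks(np.arange(na), [str(k) for k in range(1, na + 1)], fontsize=6)
    fig.colorbar(im, ax=ax_hm, fraction=0.046, label="score")

    for ax, prof, label in ((ax_a, prof_a, "5' partner"), (ax_b, prof_b, "3' partner")):
        x = np.arange(1, prof.n_exons + 1)
        ax.bar(x, prof.exon_scores, color="#4472a8")
        ax.set_xlabel(f"{prof.gene} exon")
        ax.set_ylabel("score")
        ax.set_title(f"{label} profile")
    if breakpoint is not None:
        i, j = breakpoint
        ax_hm.plot(j - 1, i - 1, "c+", markersize=12, markeredgewidth=2)
        ax_a.axvline(i + 0.5, color="crimson", ls="--", lw=1)
        ax_b.axvline(j - 0.5, color="crimson", ls="--", lw=1)
    fig.tight_layout()
    return fig
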