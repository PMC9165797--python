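"""Matplotlib figures: ordination scatter with HPD envelopes, grain gallery."""

from __future__ import annotations

from typing import Dict, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ordination import HPDRegion, OrdinationResult

__all__ = ["plot_ordination", "plot_grains"]

_COLORS = {"leptospermum": "tab:red", "kunzea": "tab:grey"}


def plot_ordination(result: OrdinationResult, taxa, regions:
                    Optional[Dict[str, HPDRegion]] = None, path=None):
    """PC1-PC2 scatter coloured by taxon with optional HPD polygons."""
    fig, ax = plt.subplots(figsize=(6, 5))
    scores = result.scores.iloc[:, :2].to_numpy()
    taxa = np.asarray(taxa)
    for taxon in sorted(set(taxa)):
        pts = scores[taxa == taxon]
        ax.scatter(pts[:, 0], pts[:, 1], s=4, alpha=0.3,
                   color=_COLORS.get(taxon), label=taxon)
    if regions:
        for taxon, region in regions.items():
            for poly in region.polygons:
                closed = np.vstack([poly, poly[:1]])
                ax.plot(closed[:, 0], closed[:, 1], lw=1.5,
                        color=_COLORS.get(taxon, "k"))
    ve = 100.0 * result.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ve[1]:.1f}%)")
    ax.legend(markerscale=3)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_grains(images, path=None, ncols: int = 5):
    """Gallery of rendered grain images."""
    images = list(images)
    nrows = (len(images) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(2 * ncols, 2 * nrows))
    for ax in np.atleast_1d(axes).ravel():
        ax.set_axis_off()
    for ax, img in zip(np.atleast_1d(axes).ravel(), images):
        ax.imshow(img.pixels, cmap="gray", vmin=0, vmax=1, origin="lower")
        if img.grain_id:
            ax.set_title(img.grain_id, fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
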