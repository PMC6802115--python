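"""Fold-increase overlay plots (observed vs dimer and sheet models)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .spatial import FoldIncreaseCurve

__all__ = ["plot_fold_curves"]

_STYLE = {"observed": "magenta", "dimer": "green", "sheet": "blue", "null": "gray"}


def plot_fold_curves(curves: dict[str, FoldIncreaseCurve], path) -> None:
    """Overlay fold-increase curves with dashed ±SD bands and save to ``path``.

    ``curves`` maps a label (e.g. ``"observed"``, ``"dimer"``, ``"sheet"``)
    to its curve; conventional colours are used for known labels.
    """
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, curve in curves.items():
        edges = curve.bin_edges
        centers = 0.5 * (edges[:-1] + edges[1:])
        color = _STYLE.get(name)
        ax.plot(centers, curve.fold, color=color, label=name)
        ax.plot(centers, curve.fold + curve.sd, color=color, ls="--", lw=0.8)
        ax.plot(centers, curve.fold - curve.sd, color=color, ls="--", lw=0.8)
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xlabel("neighbour distance (nm)")
    ax.set_ylabel("fold increase vs random")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
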