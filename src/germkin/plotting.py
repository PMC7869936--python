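"""Optional figure rendering: weighted mass + velocity + phase panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_phase_panel(curve, seg, regressions=None, band=None, path=None,
                     title: str = ""):
    """One panel in the style of the germination-phase figures.

    Weighted mass on the main axis, velocity on a secondary axis, vertical
    lines at the phase boundaries, per-phase regression lines, and an
    optional bootstrap confidence band around the velocity curve.
    """
    fig, ax_m = plt.subplots(figsize=(7.0, 4.2))
    ax_v = ax_m.twinx()
    ax_m.plot(curve.grid, curve.m, color="goldenrod", lw=2, label="weighted mass")
    ax_v.plot(curve.grid, curve.v, color="steelblue", lw=1.5, label="velocity")
    if band is not None:
        ax_v.fill_between(curve.grid, np.atleast_1d(band.lower),
                          np.atleast_1d(band.upper), color="steelblue",
                          alpha=0.2, lw=0)
    for b in seg.boundaries:
        ax_v.axvline(b, color="black", lw=1)
    if regressions:
        for reg in regressions:
            _, a, b = seg.phases[reg.phase_index]
            tt = np.linspace(a, b, 20)
            ax_v.plot(tt, reg.beta0 + reg.beta * tt, color="crimson", lw=1.5)
    ax_m.set_xlabel("time (h)")
    ax_m.set_ylabel("weighted mass m(t)")
    ax_v.set_ylabel("velocity (1/h)")
    if title:
        ax_m.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_dendrogram(result, labels=None, path=None, title: str = ""):
    """Dendrogram of a Ward-Minkowski clustering with the cut height drawn."""
    from scipy.cluster.hierarchy import dendrogram

    fig, ax = plt.subplots(figsize=(6.0, 4.0))
    dendrogram(result.linkage, labels=labels, ax=ax)
    ax.axhline(result.cut_height, color="crimson", ls="--", lw=1,
               label=f"cut at {result.cut_fraction:.0%} of max height")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
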