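"""Heat-map rendering of interaction surfaces (thin optional layer)."""

from __future__ import annotations

import numpy as np

from .averaging import InteractionSurface


def plot_surface(surface: InteractionSurface, ax=None, vmax: float | None = None):
    """Render a surface as a diverging heat map; empty bins stay white.

    Returns the matplotlib axes.  The focal individual sits at the origin
    moving right along +x; red = anticlockwise turns / speed increases,
    blue = clockwise turns / speed decreases.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mean = surface.mean
    if vmax is None:
        vmax = np.nanmax(np.abs(mean)) if np.isfinite(mean).any() else 1.0
    c = surface.grid.c
    edges = np.concatenate([surface.x_centres - c / 2, [surface.x_centres[-1] + c / 2]])
    pcm = ax.pcolormesh(
        edges, edges, mean.T, cmap="RdBu_r", vmin=-vmax, vmax=vmax, shading="flat"
    )
    ax.figure.colorbar(pcm, ax=ax, label=surface.response)
    ax.set_xlabel("relative x (units)")
    ax.set_ylabel("relative y (units)")
    ax.set_aspect("equal")
    return ax
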