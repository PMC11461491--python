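"""Colour-coded rendering of zonal ET and difference maps."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle, Wedge

from .parameters import DiffMap
from .zonemap import SECTORS, ETMap, ZoneGrid

__all__ = ["render_map"]


def render_map(
    data: ETMap | DiffMap,
    grid: ZoneGrid,
    path=None,
    highlight: tuple[str, ...] = (),
    cmap: str = "viridis",
    title: str | None = None,
    ax=None,
):
    """Draw a 41-zone map as concentric annular sectors.

    ``highlight`` zones get a white border (used for the zones entering
    the localized parameter).  Returns the matplotlib Axes.
    """
    values = data.values
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        vmax = vmin + 1e-9
    norm = plt.Normalize(vmin, vmax)
    colors = plt.get_cmap(cmap)

    sector_mid = {s: 90.0 + 45.0 * i for i, s in enumerate(SECTORS)}
    for z in grid.zones:
        hl = z.alias in highlight
        edge = dict(edgecolor="white", linewidth=2.5) if hl else dict(
            edgecolor="0.3", linewidth=0.4
        )
        color = colors(norm(values[z.alias]))
        if z.ring == 0:
            ax.add_patch(Circle((0, 0), grid.ring_radii[0], facecolor=color, **edge))
        else:
            mid = sector_mid[z.sector]
            ax.add_patch(
                Wedge(
                    (0, 0),
                    grid.ring_radii[z.ring],
                    mid - 22.5,
                    mid + 22.5,
                    width=grid.ring_radii[z.ring] - grid.ring_radii[z.ring - 1],
                    facecolor=color,
                    **edge,
                )
            )
        # zone value annotation at the zone centre
        if z.ring == 0:
            x = y = 0.0
        else:
            r = 0.5 * (grid.ring_radii[z.ring - 1] + grid.ring_radii[z.ring])
            x = r * math.cos(math.radians(sector_mid[z.sector]))
            y = r * math.sin(math.radians(sector_mid[z.sector]))
        ax.text(x, y, f"{values[z.alias]:.1f}", ha="center", va="center", fontsize=5)

    lim = grid.ring_radii[-1] * 1.05
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    sm = plt.cm.ScalarMappable(norm=norm, cmap=colors)
    plt.colorbar(sm, ax=ax, shrink=0.8, label="µm")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
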