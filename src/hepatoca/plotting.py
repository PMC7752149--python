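"""Static snapshot and phase-map rendering.

Colors follow the convention used throughout the package's figures:
healthy cells green, stressed cells magenta, dead/empty sites black; the
unmodeled central vein is drawn in orange on hexagonal lobules.
"""

from __future__ import annotations

import numpy as np

from .core import CellState, TissueState
from .lattice import Lattice

__all__ = ["render_state", "render_phase_map"]

_STATE_COLORS = {
    int(CellState.H): "#2ca02c",  # green
    int(CellState.S): "#d62bd6",  # magenta
    int(CellState.D): "#000000",  # black
}

_HEX_DIRS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


def _axial_coords(nl: int):
    coords = []
    for k in range(1, nl + 1):
        q, r = k, 0
        for d in (2, 3, 4, 5, 0, 1):
            dq, dr = _HEX_DIRS[d]
            for _ in range(k):
                coords.append((q, r))
                q, r = q + dq, r + dr
    return coords


def render_state(lattice: Lattice, state: TissueState, ax=None, plane: int = 0):
    """Draw one tissue configuration; returns the matplotlib axes."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, RegularPolygon

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))

    if lattice.geometry == "chain":
        for i in range(lattice.n_sites):
            ax.add_patch(
                RegularPolygon(
                    (i, 0), 6, radius=0.55, orientation=np.pi / 6,
                    facecolor=_STATE_COLORS[int(state.states[i])], edgecolor="gray",
                )
            )
        ax.add_patch(Circle((-1.2, 0), 0.45, facecolor="#ff7f0e"))  # CV
        ax.set_xlim(-2, lattice.n_sites + 1)
        ax.set_ylim(-2, 2)
    else:
        per = lattice.n_sites // lattice.n_planes
        coords = _axial_coords(lattice.nl)
        off = plane * per
        for i, (q, r) in enumerate(coords):
            x = q + r / 2.0
            y = r * np.sqrt(3) / 2.0
            ax.add_patch(
                RegularPolygon(
                    (x, y), 6, radius=0.58,
                    facecolor=_STATE_COLORS[int(state.states[off + i])],
                    edgecolor="gray", linewidth=0.3,
                )
            )
        ax.add_patch(Circle((0, 0), 0.5, facecolor="#ff7f0e"))  # CV
        lim = lattice.nl + 1.5
        ax.set_xlim(-lim, lim)
        ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def render_phase_map(phase_map, ax=None):
    """Color the observed-outcome labels of a sweep grid."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    order = ["S", "SD", "SC", "SDC", "C", "DC", "D", ""]
    palette = ListedColormap(
        ["#ffd700", "#c8b400", "#ff8c69", "#b06050", "#d62728", "#4a7023", "#2ca02c", "#dddddd"]
    )
    code = np.vectorize(lambda s: order.index(s) if s in order else len(order) - 1)
    img = code(phase_map.labels)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.pcolormesh(
        phase_map.col_values, phase_map.row_values, img, cmap=palette,
        vmin=0, vmax=len(order) - 1, shading="nearest",
    )
    ax.set_xlabel("column timescale (h)")
    ax.set_ylabel("row timescale (h)")
    return ax
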