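"""Static heat-map rendering of interpolated plot grids.

One PNG per frame.  Sensor-equipped plots are outlined in red, plots whose
value was interpolated in green, and the color scale is fixed across the
whole series so frames are visually comparable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.patches as mpatches
import matplotlib.pyplot as plt
import numpy as np

from .analytics import ClimateGrid

MEASURED_EDGE = "red"
INTERPOLATED_EDGE = "green"


def render_heatmap(
    grids: Sequence[ClimateGrid],
    out_dir: str | Path,
    cmap: str = "viridis",
    dpi: int = 100,
) -> list[Path]:
    """Render each frame of a heat-map series to
    ``<out_dir>/<variable>_<YYYYMMDDTHHMMSSZ>.png`` and return the paths.

    Empty frames (no data in their window) are skipped.  ``vmin``/``vmax``
    are taken over the whole series, so identical grids render to
    pixel-identical files.
    """
    if not grids:
        raise ValueError("empty grid series")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    filled = [g for g in grids if not g.empty]
    if not filled:
        return []
    vmin = min(float(np.min(g.values)) for g in filled)
    vmax = max(float(np.max(g.values)) for g in filled)
    paths = []
    for grid in filled:
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(grid.values, cmap=cmap, vmin=vmin, vmax=vmax)
        n_rows, n_cols = grid.values.shape
        for r in range(n_rows):
            for c in range(n_cols):
                edge = MEASURED_EDGE if grid.measured_mask[r, c] else INTERPOLATED_EDGE
                ax.add_patch(
                    mpatches.Rectangle(
                        (c - 0.5, r - 0.5), 1, 1,
                        fill=False, edgecolor=edge, linewidth=1.5,
                    )
                )
        ax.set_xticks(range(n_cols))
        ax.set_yticks(range(n_rows))
        ax.set_title(f"{grid.variable} @ {grid.at:%Y-%m-%d %H:%M} UTC")
        fig.colorbar(im, ax=ax)
        stamp = grid.at.strftime("%Y%m%dT%H%M%SZ")
        path = out_dir / f"{grid.variable}_{stamp}.png"
        fig.savefig(path, dpi=dpi, metadata={"Software": None})
        plt.close(fig)
        paths.append(path)
    return paths
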