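"""Optional map rendering (cosmetic).

Draws the district canvas as colored circles; intended only as a quick
visual check of colorings, not a reproduction of any particular palette.
"""

from __future__ import annotations

from pathlib import Path

from .som import Coloring, MapTopology


def plot_coloring(topology: MapTopology, coloring: Coloring, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        topology.coords[:, 0],
        topology.coords[:, 1],
        c=coloring.district_value,
        cmap="coolwarm",
        s=400,
        edgecolors="gray",
    )
    fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_title(coloring.variable)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
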