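"""Rendering of element-wise conductivity / resistivity maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import matplotlib.tri as mtri
import numpy as np

from .mesh import TriMesh

__all__ = ["render_map"]


def render_map(
    mesh: TriMesh,
    values,
    path: str | Path,
    quantity: str = "conductivity",
    title: str | None = None,
    cmap: str = "viridis",
    dpi: int = 120,
) -> Path:
    """Render a per-element map as a filled-triangle image with a colorbar.

    ``quantity="resistivity"`` plots the reciprocal 1/sigma (ohm·m) of a
    conductivity vector; any other value plots the data as-is in S/m.
    """
    values = np.asarray(getattr(values, "sigma", values), dtype=float)
    if values.shape != (mesh.n_elements,):
        raise ValueError(
            f"value vector has shape {values.shape}, expected ({mesh.n_elements},)"
        )
    if quantity == "resistivity":
        data, unit = 1.0 / values, r"$\rho$ ($\Omega\,$m)"
    else:
        data, unit = values, r"$\sigma$ (S/m)"
    tri = mtri.Triangulation(
        mesh.node_coords[:, 0], mesh.node_coords[:, 1], mesh.elements
    )
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.tripcolor(tri, facecolors=data, cmap=cmap, edgecolors="none")
    fig.colorbar(im, ax=ax, label=unit)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if title:
        ax.set_title(title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path
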