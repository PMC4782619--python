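"""Structured triangular meshes of a circular 2-D domain.

The mesh family is polar-structured: a centre node, then ``m`` concentric
rings at radii ``i*R/m`` (``i = 1..m``), ring ``i`` carrying ``S*i`` equally
spaced nodes starting at angle 0 and running counter-clockwise.  The annulus
between rings ``i-1`` and ``i`` is triangulated into ``S*(2i-1)`` triangles,
so the whole disk has

* ``S * m**2``            elements, and
* ``1 + S * m * (m+1)/2`` nodes.

With ``S = 8`` sectors the series ``m = 8, 16, 32, 64`` gives the familiar
(512, 289), (2048, 1089), (8192, 4225), (32768, 16641) element/node pairs
used throughout this package's benchmarks.

Node ordering is deterministic: centre node is index 0, rings follow
inside-out, each ring counter-clockwise from angle 0.  All lengths are SI
(metres); the 2-D model assumes unit out-of-plane thickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TriMesh",
    "ElectrodeSet",
    "ElementGeometry",
    "build_disk_mesh",
    "refine_uniform",
    "select_electrodes",
    "element_geometry",
    "triangle_geometry",
    "element_geometry_arrays",
    "mesh_edges",
    "export_mesh",
    "import_mesh",
]


@dataclass(frozen=True)
class TriMesh:
    """Triangulated disk.

    Attributes
    ----------
    node_coords : (n, 2) float array, metres.
    elements : (t, 3) int array of node indices, counter-clockwise.
    boundary_nodes : int array of outer-circle nodes, counter-clockwise
        starting at angle 0.
    n_rings, n_sectors : the structured-grid parameters (m, S).
    radius : disk radius in metres.
    """

    node_coords: np.ndarray
    elements: np.ndarray
    boundary_nodes: np.ndarray
    n_rings: int
    n_sectors: int
    radius: float

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TriMesh(R={self.radius:g} m, m={self.n_rings}, S={self.n_sectors}, "
            f"{self.n_elements} elements, {self.n_nodes} nodes)"
        )


@dataclass(frozen=True)
class ElectrodeSet:
    """Equally spaced point electrodes on the mesh boundary.

    ``node_indices[k]`` is electrode ``E(k+1)``; electrode E1 sits at angle 0
    and the set runs counter-clockwise with exact angular spacing
    ``2*pi / n_electrodes``.
    """

    node_indices: np.ndarray

    @property
    def n_electrodes(self) -> int:
        return len(self.node_indices)


@dataclass(frozen=True)
class ElementGeometry:
    """Linear-triangle geometry: area, centroid and shape-function
    gradient coefficients with ``grad N_i = (b_i, c_i) / (2 A)``."""

    area: float
    centroid: np.ndarray
    b: np.ndarray
    c: np.ndarray


def build_disk_mesh(radius: float, n_rings: int, n_sectors: int = 8) -> TriMesh:
    """Build the polar structured triangulation of a disk.

    Parameters
    ----------
    radius : disk radius in metres (> 0).
    n_rings : number of concentric rings m (>= 1).
    n_sectors : number of angular sectors S (>= 3); the mesh is exactly
        invariant under rotation by ``2*pi/S``.
    """
    if not radius > 0:
        raise ValueError(f"radius must be positive, got {radius}")
    m, S = int(n_rings), int(n_sectors)
    if m < 1:
        raise ValueError(f"n_rings must be >= 1, got {n_rings}")
    if S < 3:
        raise ValueError(f"n_sectors must be >= 3, got {n_sectors}")

    # Nodes: centre, then rings inside-out, each CCW from angle 0.
    coords = [np.zeros((1, 2))]
    ring_start = np.zeros(m + 1, dtype=int)  # ring_start[i] = first node of ring i
    next_idx = 1
    for i in range(1, m + 1):
        ring_start[i] = next_idx
        k = np.arange(S * i)
        ang = 2.0 * np.pi * k / (S * i)
        r = radius * i / m
        coords.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
        next_idx += S * i
    node_coords = np.vstack(coords)

    elements = []
    # Innermost fan: centre node to ring 1.
    for k in range(S):
        elements.append((0, ring_start[1] + k, ring_start[1] + (k + 1) % S))
    # Annuli: merge the two concentric node chains sector by sector.  Within
    # a sector the inner chain has i-1 intervals and the outer i; advancing
    # whichever chain's next node comes first in angle yields 2i-1 CCW
    # triangles per sector and keeps the construction 2*pi/S periodic.
    for i in range(2, m + 1):
        n_in, n_out = S * (i - 1), S * i
        in0, out0 = ring_start[i - 1], ring_start[i]
        for s in range(S):
            a = b = 0
            while a < i - 1 or b < i:
                inner = in0 + (s * (i - 1) + a) % n_in
                outer = out0 + (s * i + b) % n_out
                advance_outer = b < i and (
                    a >= i - 1 or (b + 1) * (i - 1) <= (a + 1) * i
                )
                if advance_outer:
                    outer2 = out0 + (s * i + b + 1) % n_out
                    elements.append((outer, outer2, inner))
                    b += 1
                else:
                    inner2 = in0 + (s * (i - 1) + a + 1) % n_in
                    elements.append((inner, outer, inner2))
                    a += 1

    boundary = np.arange(ring_start[m], ring_start[m] + S * m)
    return TriMesh(
        node_coords=node_coords,
        elements=np.asarray(elements, dtype=np.int64),
        boundary_nodes=boundary,
        n_rings=m,
        n_sectors=S,
        radius=float(radius),
    )


def refine_uniform(mesh: TriMesh) -> TriMesh:
    """Uniformly refine a structured disk mesh (element count x4).

    Each triangle is split 1-to-4 at its edge midpoints, with every new node
    snapped onto the polar grid of the twice-as-fine ring family so that
    boundary nodes stay on the circle.  For this structured family the
    result is node-for-node the mesh built directly with ``2 * n_rings``
    rings, so refinement is realized by rebuilding on the doubled grid; the
    new node count equals the old node count plus the old edge count.
    """
    return build_disk_mesh(mesh.radius, 2 * mesh.n_rings, mesh.n_sectors)


def select_electrodes(mesh: TriMesh, n_electrodes: int = 16) -> ElectrodeSet:
    """Designate ``n_electrodes`` equally spaced boundary nodes as electrodes.

    Electrode E1 is the boundary node at angle 0; the rest follow
    counter-clockwise.  The boundary node count ``S*m`` must be divisible by
    ``n_electrodes``.
    """
    n_b = len(mesh.boundary_nodes)
    if n_electrodes < 1:
        raise ValueError(f"n_electrodes must be positive, got {n_electrodes}")
    if n_b % n_electrodes != 0:
        raise ValueError(
            f"boundary node count {n_b} (S={mesh.n_sectors}, m={mesh.n_rings}) "
            f"is not divisible by n_electrodes={n_electrodes}"
        )
    step = n_b // n_electrodes
    return ElectrodeSet(node_indices=mesh.boundary_nodes[::step].copy())


def triangle_geometry(coords: np.ndarray) -> ElementGeometry:
    """Geometry of a single linear triangle given its (3, 2) vertex array.

    The gradient coefficients are the standard cyclic differences
    ``b_i = y_j - y_k``, ``c_i = x_k - x_j`` with signed area
    ``A = (b_1 c_2 - b_2 c_1) / 2``; then ``grad N_i = (b_i, c_i) / (2A)``.
    """
    coords = np.asarray(coords, dtype=float)
    x, y = coords[:, 0], coords[:, 1]
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
    area = 0.5 * (b[0] * c[1] - b[1] * c[0])
    if area <= 0:
        raise ValueError(
            f"degenerate or clockwise triangle (signed area {area:g})"
        )
    return ElementGeometry(area=float(area), centroid=coords.mean(axis=0), b=b, c=c)


def element_geometry(mesh: TriMesh, element_index: int) -> ElementGeometry:
    """Area, centroid and shape-function gradient coefficients of one element."""
    t = mesh.n_elements
    if not 0 <= element_index < t:
        raise IndexError(f"element index {element_index} out of range [0, {t})")
    return triangle_geometry(mesh.node_coords[mesh.elements[element_index]])


def element_geometry_arrays(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized geometry for all elements.

    Returns ``(areas, b, c)`` with shapes ``(t,)``, ``(t, 3)``, ``(t, 3)``.
    """
    p = mesh.node_coords[mesh.elements]  # (t, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    areas = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise ValueError(f"element {bad} has non-positive signed area {areas[bad]:g}")
    return areas, b, c


def element_centroids(mesh: TriMesh) -> np.ndarray:
    """(t, 2) array of element centroids (vertex means)."""
    return mesh.node_coords[mesh.elements].mean(axis=1)


def mesh_edges(mesh: TriMesh) -> np.ndarray:
    """Unique undirected edges as a sorted (E, 2) int array."""
    e = mesh.elements
    pairs = np.vstack([e[:, [0, 1]], e[:, [1, 2]], e[:, [2, 0]]])
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def export_mesh(mesh: TriMesh, directory: str | Path) -> None:
    """Write ``nodes.csv`` (id,x,y), ``elements.csv`` (id,n1,n2,n3) and
    ``mesh.json`` (structured-grid metadata) into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "id": np.arange(mesh.n_nodes),
            "x": mesh.node_coords[:, 0],
            "y": mesh.node_coords[:, 1],
        }
    )
    nodes.to_csv(directory / "nodes.csv", index=False, float_format="%.17g")
    els = pd.DataFrame(
        {
            "id": np.arange(mesh.n_elements),
            "n1": mesh.elements[:, 0],
            "n2": mesh.elements[:, 1],
            "n3": mesh.elements[:, 2],
        }
    )
    els.to_csv(directory / "elements.csv", index=False)
    meta = {
        "radius": mesh.radius,
        "n_rings": mesh.n_rings,
        "n_sectors": mesh.n_sectors,
        "boundary_nodes": mesh.boundary_nodes.tolist(),
    }
    (directory / "mesh.json").write_text(json.dumps(meta))


def import_mesh(directory: str | Path) -> TriMesh:
    """Inverse of :func:`export_mesh` (bit-exact round trip of coordinates)."""
    directory = Path(directory)
    nodes = pd.read_csv(directory / "nodes.csv", float_precision="round_trip")
    els = pd.read_csv(directory / "elements.csv")
    meta = json.loads((directory / "mesh.json").read_text())
    return TriMesh(
        node_coords=nodes[["x", "y"]].to_numpy(dtype=float),
        elements=els[["n1", "n2", "n3"]].to_numpy(dtype=np.int64),
        boundary_nodes=np.asarray(meta["boundary_nodes"], dtype=np.int64),
        n_rings=int(meta["n_rings"]),
        n_sectors=int(meta["n_sectors"]),
        radius=float(meta["radius"]),
    )
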