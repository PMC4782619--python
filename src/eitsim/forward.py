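"""FEM forward solver: stiffness assembly and boundary-potential computation.

The governing equation div(sigma grad phi) = 0 is discretized with linear
triangles, giving the admittance system K(sigma) Phi = C.  Current is
injected at single electrode nodes (point-electrode model, Neumann data:
+I at the source node, -I at the sink node); the potential reference is a
ground node fixed to 0 V — by default the disk centre, which is equidistant
from all electrodes and preserves the mesh's rotational symmetry.

The element matrix is K^e_ij = sigma_e (b_i b_j + c_i c_j) / (4 A_e): for a
constant-gradient triangle the integral of sigma grad N_i . grad N_j needs
no quadrature.  K is symmetric with zero row sums before grounding; the
grounded (reduced) system is symmetric positive definite and is factorized
once (sparse LU) and reused across all right-hand sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import ElectrodeSet, ElementGeometry, TriMesh, element_geometry_arrays
from .phantom import ConductivityMap
from .protocol import (
    MeasurementFrame,
    Projection,
    brown_segar_channels,
    frame_labels,
    neighbouring_projections,
)

__all__ = [
    "StiffnessSystem",
    "local_stiffness",
    "assemble_stiffness",
    "current_matrix",
    "solve_forward",
    "extract_electrode_potentials",
]


def as_sigma(conductivity) -> np.ndarray:
    """Accept a ConductivityMap or a bare per-element array."""
    if isinstance(conductivity, ConductivityMap):
        return conductivity.sigma
    return np.asarray(conductivity, dtype=float)


@dataclass
class StiffnessSystem:
    """Assembled global stiffness (admittance) matrix with grounding.

    ``K`` is the full ungrounded n x n matrix (siemens, unit thickness);
    ``ground_node`` is the node whose potential is fixed to 0.  The reduced
    SPD system (ground row/column removed) is factorized lazily and cached.
    """

    K: sp.csr_matrix
    ground_node: int = 0
    _lu: object = field(default=None, repr=False)
    _keep: np.ndarray = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.K.shape[0]

    @property
    def keep(self) -> np.ndarray:
        if self._keep is None:
            self._keep = np.delete(np.arange(self.n_nodes), self.ground_node)
        return self._keep

    @property
    def lu(self):
        if self._lu is None:
            reduced = self.K[self.keep][:, self.keep].tocsc()
            self._lu = splu(reduced)
        return self._lu


def local_stiffness(geometry: ElementGeometry, sigma_e: float) -> np.ndarray:
    """3x3 element stiffness matrix for conductivity ``sigma_e`` (S/m).

    Symmetric, zero row sums (a constant potential carries no current).
    """
    if not sigma_e > 0:
        raise ValueError(f"element conductivity must be positive, got {sigma_e}")
    if not geometry.area > 0:
        raise ValueError("degenerate triangle")
    b, c = geometry.b, geometry.c
    return sigma_e * (np.outer(b, b) + np.outer(c, c)) / (4.0 * geometry.area)


def assemble_stiffness(
    mesh: TriMesh, conductivity, ground_node: int = 0
) -> StiffnessSystem:
    """Scatter-add all element matrices into the global sparse system."""
    sigma = as_sigma(conductivity)
    if sigma.shape != (mesh.n_elements,):
        raise ValueError(
            f"conductivity vector has shape {sigma.shape}, expected "
            f"({mesh.n_elements},)"
        )
    if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
        raise ValueError("conductivity must be finite and positive")
    areas, b, c = element_geometry_arrays(mesh)
    coef = sigma / (4.0 * areas)  # (t,)
    local = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) * coef[
        :, None, None
    ]
    e = mesh.elements
    rows = np.repeat(e, 3, axis=1).ravel()  # i index: 000111222 per element
    cols = np.tile(e, (1, 3)).ravel()  # j index: 012012012 per element
    n = mesh.n_nodes
    k = sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return StiffnessSystem(K=k, ground_node=ground_node)


def current_matrix(
    n_nodes: int,
    electrodes: ElectrodeSet,
    projections: list[Projection] | None = None,
    amplitude: float = 1e-3,
) -> np.ndarray:
    """Nodal current matrix C (amperes), one column per projection.

    Column p carries +I at the source electrode node and -I at the sink
    node; every column sums to zero.
    """
    if projections is None:
        projections = neighbouring_projections(electrodes.n_electrodes)
    c = np.zeros((n_nodes, len(projections)))
    for j, proj in enumerate(projections):
        c[electrodes.node_indices[proj.source - 1], j] += amplitude
        c[electrodes.node_indices[proj.sink - 1], j] -= amplitude
    return c


def solve_forward(system: StiffnessSystem, c: np.ndarray) -> np.ndarray:
    """Solve K Phi = C for all columns against one cached factorization.

    Returns the nodal potential matrix (n x P, volts) with the ground-node
    row identically zero.  Columns of C must sum to zero (conservation of
    injected current).
    """
    c = np.asarray(c, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != system.n_nodes:
        raise ValueError(
            f"current matrix has {c.shape[0]} rows, system has {system.n_nodes} nodes"
        )
    scale = max(1.0, float(np.abs(c).max()))
    colsum = np.abs(c.sum(axis=0))
    if np.any(colsum > 1e-9 * scale):
        raise ValueError(
            "current matrix columns must sum to zero "
            f"(max |sum| = {colsum.max():g} A)"
        )
    phi = np.zeros_like(c)
    phi[system.keep] = system.lu.solve(c[system.keep])
    if not np.all(np.isfinite(phi)):
        raise np.linalg.LinAlgError(
            "forward solve produced non-finite potentials "
            "(singular reduced system: disconnected mesh or bad grounding?)"
        )
    return phi


def extract_electrode_potentials(
    m_np: np.ndarray,
    electrodes: ElectrodeSet,
    mode: str = "grounded",
    projections: list[Projection] | None = None,
) -> MeasurementFrame:
    """Collect the boundary data of a scan from the nodal potential matrix.

    ``grounded``: electrode potentials against ground, projection-major,
    E1..E16 within each projection.  ``differential``: the Brown–Segar
    adjacent-pair differences, 13 per projection for 16 electrodes.
    """
    n = electrodes.n_electrodes
    if projections is None:
        projections = neighbouring_projections(n)
    if m_np.shape[1] != len(projections):
        raise ValueError(
            f"nodal potential matrix has {m_np.shape[1]} columns, expected "
            f"{len(projections)} projections"
        )
    ep = m_np[electrodes.node_indices, :]  # (n_electrodes, P)
    if mode == "grounded":
        values = ep.T.ravel()
    elif mode == "differential":
        vals = []
        for j, proj in enumerate(projections):
            for a, b in brown_segar_channels(proj, n):
                vals.append(ep[a - 1, j] - ep[b - 1, j])
        values = np.asarray(vals)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    proj_idx, labels = frame_labels(projections, mode, n)
    return MeasurementFrame(
        values=values,
        mode=mode,
        n_electrodes=n,
        projection=proj_idx,
        channel=labels,
    )
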