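"""Regularized Gauss-Newton reconstruction of element conductivities.

The inverse solver minimizes the Tikhonov objective

    s_r(sigma) = 1/2 ||Vm - f(sigma)||^2 + 1/2 lambda ||sigma||^2

where f is the forward map from element conductivities to the boundary-data
vector and the regularization operator is the identity.  Each Newton-Raphson
iteration solves the damped normal equations

    (J^T J + lambda I) d_sigma = J^T (Vm - f)                     ["eq20"]
    (J^T J + lambda I) d_sigma = J^T (Vm - f) - lambda sigma      ["eq19"]

(the second variant keeps the gradient of the penalty term; the first drops
it) and updates sigma <- max(sigma + d_sigma, floor).

The Jacobian is computed with the adjoint method: the sensitivity of a
measurement to element e is

    J[md, e] = - A_e * grad(phi_s) . grad(phi_d) |_e

with phi_s the drive-pair field (at the actual drive current) and phi_d the
field of a unit current driven through the measurement electrode pair (or
electrode-to-ground in grounded mode).  Gradients are constant per linear
element, so the element integral is exact.  One factorization serves the 16
drive solves and the 16 adjoint solves of a full scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .forward import as_sigma, assemble_stiffness, current_matrix, solve_forward
from .mesh import ElectrodeSet, TriMesh, element_geometry_arrays
from .protocol import MeasurementFrame, brown_segar_channels, neighbouring_projections

__all__ = [
    "InverseSettings",
    "ReconstructionResult",
    "compute_jacobian",
    "gn_update",
    "objective",
    "reconstruct",
]


@dataclass(frozen=True)
class InverseSettings:
    """Tunable parameters of the Gauss-Newton loop.

    regularization : positive scalar lambda, or ``"auto"`` for the scale-free
        rule ``lambda = auto_scale * max(diag(J^T J))`` evaluated at the
        first iteration and held fixed.
    variant : ``"eq20"`` (penalty gradient dropped from the right-hand side)
        or ``"eq19"`` (kept).
    max_iter : maximum number of conductivity updates (default 15).
    tol : stop when the relative misfit ||Vm - Vc|| / ||Vm|| falls below it.
    stagnation_rtol : stop when the misfit changes by less than this
        relative amount between iterations.
    sigma0 : initial conductivity, a scalar (uniform) or per-element vector.
    sigma_floor : positivity floor applied after every update (S/m).
    """

    regularization: float | str = "auto"
    variant: str = "eq20"
    max_iter: int = 15
    tol: float = 1e-6
    stagnation_rtol: float = 1e-6
    sigma0: float | np.ndarray = 1.0
    sigma_floor: float = 1e-6
    auto_scale: float = 1e-3

    def __post_init__(self):
        if self.variant not in ("eq19", "eq20"):
            raise ValueError(f"variant must be 'eq19' or 'eq20', got {self.variant!r}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if isinstance(self.regularization, str):
            if self.regularization != "auto":
                raise ValueError(
                    f"regularization must be a positive number or 'auto', "
                    f"got {self.regularization!r}"
                )
        elif not self.regularization > 0:
            raise ValueError("regularization must be positive")


@dataclass
class ReconstructionResult:
    """Iterate history of one reconstruction run.

    ``sigma_history[k]`` is the conductivity after k updates (entry 0 is the
    initial guess); ``misfit_history[k]`` is ||Vm - f(sigma_history[k])||.
    ``stop_reason`` is one of ``"tol"``, ``"stagnation"``, ``"max_iter"``,
    ``"diverged"``.
    """

    sigma_history: list[np.ndarray]
    misfit_history: np.ndarray
    converged: bool
    diverged: bool
    stop_reason: str
    regularization: float
    n_updates: int

    @property
    def sigma(self) -> np.ndarray:
        """Final conductivity estimate."""
        return self.sigma_history[-1]


def _gradient_operators(mesh: TriMesh) -> tuple[np.ndarray, sp.csr_matrix, sp.csr_matrix]:
    """Sparse operators mapping nodal values to per-element field gradients."""
    areas, b, c = element_geometry_arrays(mesh)
    t = mesh.n_elements
    rows = np.repeat(np.arange(t), 3)
    cols = mesh.elements.ravel()
    w = 1.0 / (2.0 * areas)
    gx = sp.coo_matrix(((b * w[:, None]).ravel(), (rows, cols)), shape=(t, mesh.n_nodes))
    gy = sp.coo_matrix(((c * w[:, None]).ravel(), (rows, cols)), shape=(t, mesh.n_nodes))
    return areas, gx.tocsr(), gy.tocsr()


def compute_jacobian(
    mesh: TriMesh,
    conductivity,
    electrodes: ElectrodeSet,
    mode: str = "grounded",
    amplitude: float = 1e-3,
) -> np.ndarray:
    """Adjoint-method sensitivity matrix, shape (measurements, elements).

    Units are volts per (S/m).  Row order matches the projection-major
    measurement frame of :func:`eitsim.protocol.run_scan`.
    """
    sigma = as_sigma(conductivity)
    if sigma.shape != (mesh.n_elements,):
        raise ValueError(
            f"conductivity vector has shape {sigma.shape}, expected "
            f"({mesh.n_elements},)"
        )
    n_e = electrodes.n_electrodes
    projections = neighbouring_projections(n_e)
    system = assemble_stiffness(mesh, sigma)

    # Drive fields at the actual amplitude, one column per projection.
    c_drive = current_matrix(mesh.n_nodes, electrodes, projections, amplitude)
    u = solve_forward(system, c_drive)  # (n, P)
    # Adjoint fields: unit current in at each electrode, out at ground.
    c_adj = np.zeros((mesh.n_nodes, n_e))
    c_adj[electrodes.node_indices, np.arange(n_e)] = 1.0
    c_adj[system.ground_node, :] -= 1.0
    w = solve_forward(system, c_adj)  # (n, n_e)

    areas, gx, gy = _gradient_operators(mesh)
    ux, uy = gx @ u, gy @ u  # (t, P)
    wx, wy = gx @ w, gy @ w  # (t, n_e)

    rows = []
    for j, proj in enumerate(projections):
        if mode == "grounded":
            for e in range(n_e):
                rows.append(-areas * (ux[:, j] * wx[:, e] + uy[:, j] * wy[:, e]))
        elif mode == "differential":
            for a, b in brown_segar_channels(proj, n_e):
                dwx = wx[:, a - 1] - wx[:, b - 1]
                dwy = wy[:, a - 1] - wy[:, b - 1]
                rows.append(-areas * (ux[:, j] * dwx + uy[:, j] * dwy))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return np.vstack(rows)


def gn_update(
    j: np.ndarray,
    dv: np.ndarray,
    lam: float,
    sigma: np.ndarray | None = None,
    variant: str = "eq20",
) -> np.ndarray:
    """One damped Gauss-Newton step: solve (J^T J + lambda I) d = rhs.

    ``rhs = J^T dv`` for variant ``"eq20"``; variant ``"eq19"`` subtracts
    the penalty gradient ``lambda * sigma`` (which shrinks the iterate
    toward zero even at zero misfit).
    """
    j = np.asarray(j, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if not (np.all(np.isfinite(j)) and np.all(np.isfinite(dv))):
        raise ValueError("non-finite Jacobian or residual")
    if not lam > 0:
        raise ValueError(f"regularization must be positive, got {lam}")
    t = j.shape[1]
    a = j.T @ j + lam * np.eye(t)
    rhs = j.T @ dv
    if variant == "eq19":
        if sigma is None:
            raise ValueError("variant 'eq19' needs the current sigma")
        rhs = rhs - lam * np.asarray(sigma, dtype=float)
    elif variant != "eq20":
        raise ValueError(f"variant must be 'eq19' or 'eq20', got {variant!r}")
    return scipy.linalg.solve(a, rhs, assume_a="pos")


def objective(vm: np.ndarray, vc: np.ndarray, sigma: np.ndarray, lam: float) -> float:
    """Regularized least-squares objective 1/2||Vm-Vc||^2 + 1/2 lambda||sigma||^2."""
    vm = np.asarray(vm, dtype=float)
    vc = np.asarray(vc, dtype=float)
    if vm.shape != vc.shape:
        raise ValueError("measured and computed vectors must have equal length")
    r = vm - vc
    return 0.5 * float(r @ r) + 0.5 * lam * float(np.asarray(sigma) @ np.asarray(sigma))


def reconstruct(
    frame: MeasurementFrame,
    mesh: TriMesh,
    electrodes: ElectrodeSet,
    settings: InverseSettings | None = None,
    amplitude: float = 1e-3,
) -> ReconstructionResult:
    """Iterative Gauss-Newton / Newton-Raphson reconstruction.

    Per iteration: forward-solve the current estimate, form the voltage
    mismatch dV = Vm - Vc, recompute the adjoint Jacobian, solve the damped
    normal equations and update with a positivity floor.  Stops on relative
    misfit <= tol, on misfit stagnation, at ``max_iter`` updates, or — with
    a flagged partial result — on divergence (misfit > 1e3 x initial).
    """
    from .protocol import run_scan

    settings = settings or InverseSettings()
    vm = frame.values
    vm_norm = float(np.linalg.norm(vm))
    if np.isscalar(settings.sigma0):
        sigma = np.full(mesh.n_elements, float(settings.sigma0))
    else:
        sigma = np.asarray(settings.sigma0, dtype=float).copy()
        if sigma.shape != (mesh.n_elements,):
            raise ValueError("sigma0 vector length must equal the element count")
    if np.any(sigma <= 0):
        raise ValueError("sigma0 must be positive")

    lam = None if settings.regularization == "auto" else float(settings.regularization)
    sigma_history = [sigma.copy()]
    misfits: list[float] = []
    converged = diverged = False
    stop_reason = "max_iter"
    n_updates = 0

    for _ in range(settings.max_iter):
        vc = run_scan(mesh, sigma, electrodes, frame.mode, amplitude).values
        dv = vm - vc
        misfit = float(np.linalg.norm(dv))
        misfits.append(misfit)
        if misfit <= settings.tol * vm_norm:
            converged, stop_reason = True, "tol"
            break
        if misfit > 1e3 * misfits[0]:
            diverged, stop_reason = True, "diverged"
            break
        if (
            len(misfits) > 1
            and abs(misfits[-2] - misfit) <= settings.stagnation_rtol * misfits[-2]
        ):
            converged, stop_reason = True, "stagnation"
            break
        j = compute_jacobian(mesh, sigma, electrodes, frame.mode, amplitude)
        if lam is None:
            lam = settings.auto_scale * float((j * j).sum(axis=0).max())
        d_sigma = gn_update(j, dv, lam, sigma, settings.variant)
        sigma = np.maximum(sigma + d_sigma, settings.sigma_floor)
        sigma_history.append(sigma.copy())
        n_updates += 1
    else:
        # Budget exhausted; record the final iterate's misfit.
        vc = run_scan(mesh, sigma, electrodes, frame.mode, amplitude).values
        misfits.append(float(np.linalg.norm(vm - vc)))

    return ReconstructionResult(
        sigma_history=sigma_history,
        misfit_history=np.asarray(misfits),
        converged=converged,
        diverged=diverged,
        stop_reason=stop_reason,
        regularization=float(lam) if lam is not None else float("nan"),
        n_updates=n_updates,
    )
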