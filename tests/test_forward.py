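"""FEM forward solver: element matrices, assembly, solves, physics checks."""

import numpy as np
import pytest

from eitsim import (
    assemble_stiffness,
    build_disk_mesh,
    current_matrix,
    extract_electrode_potentials,
    local_stiffness,
    neighbouring_projections,
    select_electrodes,
    solve_forward,
)
from eitsim.mesh import triangle_geometry

R = 0.075
SB = 0.21
I = 1e-3


def closed_form_disk_potential(points, source_xy, sink_xy, sigma, current):
    """Potential in a homogeneous disk driven by a boundary point source/sink
    pair: superposed half-plane-strength logarithms, zero at the centre."""
    points = np.atleast_2d(points)
    d_src = np.hypot(*(points - source_xy).T)
    d_snk = np.hypot(*(points - sink_xy).T)
    return (current / (np.pi * sigma)) * (np.log(d_snk) - np.log(d_src))


class TestLocalStiffness:
    def test_unit_right_triangle_closed_form(self):
        geom = triangle_geometry([(0, 0), (1, 0), (0, 1)])
        k = local_stiffness(geom, 1.0)
        expected = 0.5 * np.array([[2, -1, -1], [-1, 1, 0], [-1, 0, 1]])
        assert np.allclose(k, expected)

    def test_constant_field_carries_no_current(self):
        geom = triangle_geometry([(0.2, -0.1), (1.3, 0.4), (0.1, 1.7)])
        k = local_stiffness(geom, 3.7)
        assert np.allclose(k @ np.ones(3), 0, atol=1e-14)
        assert np.allclose(k, k.T)

    def test_matches_numerical_shape_function_gradients(self):
        """Oracle: differentiate the interpolated shape functions numerically
        and integrate sigma grad Ni . grad Nj over the (constant-gradient)
        element."""
        rng = np.random.default_rng(7)
        pts = rng.uniform(-1, 1, (3, 2))
        u, v = pts[1] - pts[0], pts[2] - pts[0]
        if u[0] * v[1] - u[1] * v[0] < 0:
            pts = pts[::-1]
        sigma_e = 0.42
        geom = triangle_geometry(pts)

        # Shape function N_i: linear, N_i(vertex j) = delta_ij.
        vander = np.column_stack([np.ones(3), pts])
        coeffs = np.linalg.solve(vander, np.eye(3))  # columns: (a, gx, gy) per N_i

        def grad_n(i, x, y, h=1e-6):
            def n(xx, yy):
                return coeffs[0, i] + coeffs[1, i] * xx + coeffs[2, i] * yy
            return np.array(
                [
                    (n(x + h, y) - n(x - h, y)) / (2 * h),
                    (n(x, y + h) - n(x, y - h)) / (2 * h),
                ]
            )

        cx, cy = geom.centroid
        expected = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                expected[i, j] = sigma_e * geom.area * (
                    grad_n(i, cx, cy) @ grad_n(j, cx, cy)
                )
        assert np.allclose(local_stiffness(geom, sigma_e), expected, rtol=1e-5)

    def test_rejects_non_positive_conductivity(self):
        geom = triangle_geometry([(0, 0), (1, 0), (0, 1)])
        with pytest.raises(ValueError):
            local_stiffness(geom, 0.0)


class TestAssembly:
    def test_rows_sum_to_zero_before_grounding(self, mesh_m8, offcentre_sigma_m8):
        system = assemble_stiffness(mesh_m8, offcentre_sigma_m8)
        rowsum = np.asarray(abs(system.K @ np.ones(mesh_m8.n_nodes)))
        assert rowsum.max() < 1e-12 * abs(system.K).max()

    def test_linearity_in_conductivity(self, mesh_m8, uniform_sigma_m8):
        k1 = assemble_stiffness(mesh_m8, uniform_sigma_m8).K
        k2 = assemble_stiffness(mesh_m8, 2 * uniform_sigma_m8).K
        assert np.allclose((k2 - 2 * k1).toarray(), 0, atol=1e-15)

    def test_reduced_system_is_spd(self, mesh_m8, uniform_sigma_m8):
        system = assemble_stiffness(mesh_m8, uniform_sigma_m8)
        reduced = system.K[system.keep][:, system.keep].toarray()
        np.linalg.cholesky(reduced)  # raises if not SPD

    def test_matches_dense_scatter_oracle_on_smallest_fan(self):
        mesh = build_disk_mesh(1.0, 1, 3)
        sigma = np.array([0.5, 1.0, 2.0])
        system = assemble_stiffness(mesh, sigma)
        dense = np.zeros((4, 4))
        for e in range(3):
            geom = triangle_geometry(mesh.node_coords[mesh.elements[e]])
            k_e = local_stiffness(geom, sigma[e])
            idx = mesh.elements[e]
            for i in range(3):
                for j in range(3):
                    dense[idx[i], idx[j]] += k_e[i, j]
        assert np.allclose(system.K.toarray(), dense, atol=1e-15)

    def test_rejects_non_positive_sigma(self, mesh_m8, uniform_sigma_m8):
        bad = uniform_sigma_m8.copy()
        bad[3] = 0.0
        with pytest.raises(ValueError):
            assemble_stiffness(mesh_m8, bad)


class TestSolve:
    def test_zero_current_gives_zero_potential(self, mesh_m8, uniform_sigma_m8):
        system = assemble_stiffness(mesh_m8, uniform_sigma_m8)
        phi = solve_forward(system, np.zeros((mesh_m8.n_nodes, 3)))
        assert np.all(phi == 0)

    def test_residual_and_ground_row(self, mesh_m8, electrodes_m8, uniform_sigma_m8):
        system = assemble_stiffness(mesh_m8, uniform_sigma_m8)
        c = current_matrix(mesh_m8.n_nodes, electrodes_m8, amplitude=I)
        phi = solve_forward(system, c)
        assert np.all(phi[system.ground_node] == 0)
        resid = system.K @ phi - c
        resid[system.ground_node] = 0  # ground row absorbs the reference current
        assert np.linalg.norm(resid) < 1e-10 * np.linalg.norm(c)

    def test_unbalanced_current_rejected(self, mesh_m8, uniform_sigma_m8):
        system = assemble_stiffness(mesh_m8, uniform_sigma_m8)
        c = np.zeros(mesh_m8.n_nodes)
        c[5] = 1e-3
        with pytest.raises(ValueError, match="sum to zero"):
            solve_forward(system, c)

    def test_antisymmetry_about_drive_pair_bisector(self):
        """Drive (E1, E2): the continuum solution is antisymmetric about the
        pair's bisecting diameter, so electrode potentials at mirrored
        positions must cancel.  The structured triangulation is chiral
        (strip quads are always split on the same diagonal), so the discrete
        cancellation is only up to discretization error; it must vanish
        under refinement at first order or better."""
        errs = []
        for m in (8, 16, 32):
            mesh = build_disk_mesh(R, m)
            el = select_electrodes(mesh)
            system = assemble_stiffness(mesh, np.full(mesh.n_elements, SB))
            c = np.zeros(mesh.n_nodes)
            c[el.node_indices[0]] = I
            c[el.node_indices[1]] = -I
            phi = solve_forward(system, c)[:, 0]
            v = phi[el.node_indices]
            # E(k) at angle (k-1)*pi/8 mirrors to E(2-k mod 16), 1-based.
            mirrored = v[(1 - np.arange(16)) % 16]
            probes = np.arange(2, 16)  # all but the drive pair
            errs.append(np.abs((v + mirrored)[probes]).max() / np.abs(v[probes]).max())
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert errs[-1] < 5e-4
        assert np.all(orders >= 1.0)

    def test_boundary_potentials_converge_to_closed_form(self):
        errs = []
        for m in (8, 16, 32):
            mesh = build_disk_mesh(R, m)
            el = select_electrodes(mesh)
            system = assemble_stiffness(mesh, np.full(mesh.n_elements, SB))
            c = np.zeros(mesh.n_nodes)
            c[el.node_indices[0]] = I
            c[el.node_indices[1]] = -I
            phi = solve_forward(system, c)[:, 0]
            probes = el.node_indices[2:]  # exclude the drive nodes
            exact = closed_form_disk_potential(
                mesh.node_coords[probes],
                mesh.node_coords[el.node_indices[0]],
                mesh.node_coords[el.node_indices[1]],
                SB,
                I,
            )
            errs.append(np.abs(phi[probes] - exact).max())
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 1.0)

    def test_sigma_and_current_scaling_laws(
        self, mesh_m8, electrodes_m8, uniform_sigma_m8
    ):
        c = current_matrix(mesh_m8.n_nodes, electrodes_m8, amplitude=I)
        phi = solve_forward(assemble_stiffness(mesh_m8, uniform_sigma_m8), c)
        phi_sigma = solve_forward(
            assemble_stiffness(mesh_m8, 3.0 * uniform_sigma_m8), c
        )
        scale = np.abs(phi).max()
        assert np.abs(phi_sigma - phi / 3.0).max() < 1e-12 * scale
        phi_current = solve_forward(
            assemble_stiffness(mesh_m8, uniform_sigma_m8), 5.0 * c
        )
        assert np.abs(phi_current - 5.0 * phi).max() < 5e-12 * scale

    def test_reciprocity_on_random_four_electrode_measurements(
        self, mesh_m8, electrodes_m8, offcentre_sigma_m8
    ):
        system = assemble_stiffness(mesh_m8, offcentre_sigma_m8)
        nodes = electrodes_m8.node_indices
        rng = np.random.default_rng(11)

        def transfer(src, snk, ma, mb):
            c = np.zeros(mesh_m8.n_nodes)
            c[nodes[src]], c[nodes[snk]] = I, -I
            phi = solve_forward(system, c)[:, 0]
            return phi[nodes[ma]] - phi[nodes[mb]]

        for _ in range(10):
            a, b, m1, m2 = rng.choice(16, size=4, replace=False)
            v_fwd = transfer(a, b, m1, m2)
            v_rev = transfer(m1, m2, a, b)
            assert abs(v_fwd - v_rev) < 1e-9 * abs(v_fwd)


class TestExtraction:
    def test_mode_lengths_and_labels(self, mesh_m8, electrodes_m8, uniform_sigma_m8):
        system = assemble_stiffness(mesh_m8, uniform_sigma_m8)
        c = current_matrix(mesh_m8.n_nodes, electrodes_m8, amplitude=I)
        m_np = solve_forward(system, c)
        fg = extract_electrode_potentials(m_np, electrodes_m8, "grounded")
        fd = extract_electrode_potentials(m_np, electrodes_m8, "differential")
        assert len(fg) == 256 and len(fd) == 208
        assert fg.channel[:2] == ("E1", "E2")
        assert fd.channel[0] == "E3-E4"
        with pytest.raises(ValueError, match="mode"):
            extract_electrode_potentials(m_np, electrodes_m8, "opposite")

    def test_grounded_restriction_reproduces_differential(
        self, mesh_m8, electrodes_m8, uniform_sigma_m8
    ):
        system = assemble_stiffness(mesh_m8, uniform_sigma_m8)
        c = current_matrix(mesh_m8.n_nodes, electrodes_m8, amplitude=I)
        m_np = solve_forward(system, c)
        fg = extract_electrode_potentials(m_np, electrodes_m8, "grounded")
        fd = extract_electrode_potentials(m_np, electrodes_m8, "differential")
        projs = neighbouring_projections(16)
        rebuilt = []
        for proj in projs:
            block = fg.block(proj.index)
            for a, b in proj.channels:
                rebuilt.append(block[a - 1] - block[b - 1])
        assert np.array_equal(np.asarray(rebuilt), fd.values)
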