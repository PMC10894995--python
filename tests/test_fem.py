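"""Hexahedral mesh construction, stiffness assembly, dipole loads, solves,
interpolation, and potential tables."""

import numpy as np
import pytest
import sympy

from seegvc import fem
from seegvc.analytic import Dipole, ShellModel, analytic_dipole_potential
from seegvc.errors import ConvergenceError, IncompatibleLoadError, OutsideMeshError
from seegvc.phantom import ConductivityProfile, LabeledVolume, build_sphere_phantom
from tests.conftest import SMALL_RADII


def block_volume(shape=(2, 2, 2), label=4, voxel=1.0):
    labels = np.full(shape, label, dtype=np.int16)
    return LabeledVolume(labels=labels, voxel_size_mm=voxel, origin_mm=np.zeros(3))


def unit_cube_mesh():
    return fem.voxels_to_hex_mesh(block_volume((1, 1, 1)), node_shift=0.0)


class TestMeshConstruction:
    def test_block_counts_and_lattice(self):
        mesh = fem.voxels_to_hex_mesh(block_volume(), node_shift=0.0)
        assert mesh.n_elements == 8
        assert mesh.n_nodes == 27
        # all nodes at exact voxel-corner coordinates (half-integer grid)
        frac = (mesh.nodes_mm + 0.5) % 1.0
        np.testing.assert_allclose(frac, 0.0, atol=1e-12)

    def test_element_count_equals_nonzero_voxels(self, small_phantom):
        mesh = fem.voxels_to_hex_mesh(small_phantom, node_shift=0.3)
        assert mesh.n_elements == int(np.count_nonzero(small_phantom.labels))

    def test_node_shift_keeps_jacobians_positive(self, small_phantom):
        mesh = fem.voxels_to_hex_mesh(small_phantom, node_shift=0.3)
        assert fem.min_jacobian(mesh) > 0

    def test_zero_shift_is_regular_lattice(self, small_phantom):
        mesh = fem.voxels_to_hex_mesh(small_phantom, node_shift=0.0)
        h = small_phantom.voxel_size_mm
        rel = (mesh.nodes_mm - small_phantom.origin_mm + 0.5 * h) / h
        np.testing.assert_allclose(rel, np.round(rel), atol=1e-12)

    def test_invalid_shift_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            fem.voxels_to_hex_mesh(small_phantom, node_shift=0.6)


@pytest.fixture(scope="module")
def sympy_unit_cube_stiffness():
    """Independent oracle: symbolic integration of grad(N_a).grad(N_b) over
    the unit cube with trilinear nodal bases."""
    x, y, z = sympy.symbols("x y z")
    fx = {0: 1 - x, 1: x}
    fy = {0: 1 - y, 1: y}
    fz = {0: 1 - z, 1: z}
    # lexicographic corner order, matching the mesh's global node numbering
    corners = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    N = [fx[i] * fy[j] * fz[k] for i, j, k in corners]
    K = np.empty((8, 8))
    for a in range(8):
        for b in range(a, 8):
            integrand = sum(sympy.diff(N[a], v) * sympy.diff(N[b], v) for v in (x, y, z))
            val = sympy.integrate(integrand, (x, 0, 1), (y, 0, 1), (z, 0, 1))
            K[a, b] = K[b, a] = float(val)
    return K


class TestStiffness:
    def test_single_element_matches_symbolic_integration(self, sympy_unit_cube_stiffness):
        mesh = unit_cube_mesh()
        K = fem.assemble_stiffness(mesh, ConductivityProfile("4C", {4: 1.0 / 1e-3}))
        # sigma chosen to cancel the mm->m scale: entries are the unit-cube integrals
        np.testing.assert_allclose(K.matrix.toarray(), sympy_unit_cube_stiffness, atol=1e-12)

    def test_row_sums_vanish(self, brain_system):
        K = brain_system.matrix
        resid = np.abs(K @ np.ones(K.shape[0]))
        assert resid.max() <= 1e-10 * np.abs(K.data).max()

    def test_symmetry(self, brain_system):
        K = brain_system.matrix
        assert abs(K - K.T).max() < 1e-14 * np.abs(K.data).max()

    def test_conductivity_scaling_is_linear(self, brain_sphere_mesh):
        k1 = fem.assemble_stiffness(brain_sphere_mesh, ConductivityProfile("4C", {4: 0.33}))
        k3 = fem.assemble_stiffness(brain_sphere_mesh, ConductivityProfile("4C", {4: 0.99}))
        assert abs(k3.matrix - 3.0 * k1.matrix).max() < 1e-12 * np.abs(k3.matrix.data).max()

    def test_positive_semidefinite_small_mesh(self):
        mesh = fem.voxels_to_hex_mesh(block_volume((2, 2, 2)), node_shift=0.0)
        K = fem.assemble_stiffness(mesh, ConductivityProfile("4C", {4: 0.33}))
        w = np.linalg.eigvalsh(K.matrix.toarray())
        assert w.min() > -1e-12 * w.max()

    def test_missing_label_rejected(self, brain_sphere_mesh):
        with pytest.raises(ValueError, match="labels"):
            fem.assemble_stiffness(brain_sphere_mesh, ConductivityProfile("4C", {1: 0.33}))


class TestDipoleLoad:
    def test_unit_cube_center_load_pattern(self):
        """Moment along +x at the element center: +1/4 on the x=1 face
        nodes, -1/4 on the x=0 face nodes (hand-evaluated gradients)."""
        mesh = unit_cube_mesh()
        # the single voxel is centered at the origin and spans +/-0.5 mm
        b = fem.dipole_load_vector(mesh, Dipole([0.0, 0.0, 0.0], [1e-3, 0.0, 0.0]))
        expected = np.where(mesh.nodes_mm[:, 0] > 0, 0.25, -0.25)
        np.testing.assert_allclose(b, expected, atol=1e-12)

    def test_load_sums_to_zero(self, brain_sphere_mesh, rng):
        for _ in range(5):
            pos = rng.uniform(-1, 1, size=3) * 10.0
            mom = rng.normal(size=3) * 1e-9
            b = fem.dipole_load_vector(brain_sphere_mesh, Dipole(pos, mom))
            assert abs(b.sum()) < 1e-12 * np.abs(b).max()

    def test_zero_moment_gives_zero_vector(self, brain_sphere_mesh):
        b = fem.dipole_load_vector(brain_sphere_mesh, Dipole([1.0, 2.0, 3.0], [0, 0, 0]))
        assert not b.any()

    def test_position_outside_mesh_rejected(self, brain_sphere_mesh):
        with pytest.raises(OutsideMeshError):
            fem.dipole_load_vector(brain_sphere_mesh, Dipole([0, 0, 25.0], [0, 0, 1e-9]))


class TestSolve:
    def test_zero_load_gives_zero_potential(self, brain_system):
        u = fem.solve_potential(brain_system, np.zeros(brain_system.n_nodes))
        assert not u.any()

    def test_residual_meets_tolerance(self, brain_sphere_mesh, brain_system):
        b = fem.dipole_load_vector(brain_sphere_mesh, Dipole([1.0, 0.5, 2.0], [0, 0, 1e-9]))
        u = fem.solve_potential(brain_system, b, rel_tol=1e-9)
        res = np.linalg.norm(brain_system.matrix @ u - (b - b.mean()))
        assert res <= 1e-8 * np.linalg.norm(b)
        assert abs(u.mean()) < 1e-15 * np.abs(u).max()

    def test_incompatible_load_rejected(self, brain_system):
        bad = np.zeros(brain_system.n_nodes)
        bad[0] = 1.0  # net current injection into an insulated conductor
        with pytest.raises(IncompatibleLoadError):
            fem.solve_potential(brain_system, bad)

    def test_iteration_cap_raises_convergence_error(self, brain_sphere_mesh, brain_system):
        b = fem.dipole_load_vector(brain_sphere_mesh, Dipole([1.0, 0.5, 2.0], [0, 0, 1e-9]))
        with pytest.raises(ConvergenceError):
            fem.solve_potential(brain_system, b, rel_tol=1e-12, maxiter=3)

    def test_central_dipole_matches_closed_form_within_5pct(
        self, brain_sphere_mesh, brain_system
    ):
        """Surface potential on the moment axis vs 3m/(4 pi sigma R^2)."""
        m, sigma, R = 3.5e-9, 0.33, 20.0
        b = fem.dipole_load_vector(brain_sphere_mesh, Dipole([0.0, 0.0, 0.0], [0, 0, m]))
        u = fem.solve_potential(brain_system, b)
        v = fem.interpolate_at_points(brain_sphere_mesh, u, [[0.0, 0.0, 18.9]])[0]
        closed_surface = 3 * m / (4 * np.pi * sigma * (R * 1e-3) ** 2)
        assert v == pytest.approx(closed_surface, rel=0.05)


class TestInterpolation:
    def test_nodal_values_reproduced(self, brain_sphere_mesh, rng):
        u = rng.normal(size=brain_sphere_mesh.n_nodes)
        # a deep interior node: every element sharing it exists
        k = int(np.argmin(np.linalg.norm(
            brain_sphere_mesh.nodes_mm - np.array([3.3, -2.1, 5.2]), axis=1)))
        v = fem.interpolate_at_points(brain_sphere_mesh, u, [brain_sphere_mesh.nodes_mm[k]])[0]
        assert v == pytest.approx(u[k], rel=1e-9, abs=1e-12)

    def test_constant_field_is_exact(self, brain_sphere_mesh, rng):
        u = np.full(brain_sphere_mesh.n_nodes, 3.7)
        pts = rng.uniform(-1, 1, size=(10, 3)) * 12.0
        np.testing.assert_allclose(
            fem.interpolate_at_points(brain_sphere_mesh, u, pts), 3.7, rtol=1e-12
        )

    def test_element_center_is_mean_of_corners(self, rng):
        mesh = fem.voxels_to_hex_mesh(block_volume((2, 2, 2)), node_shift=0.0)
        u = rng.normal(size=mesh.n_nodes)
        center = np.array([0.0, 0.0, 0.0])  # center of voxel (0,0,0)
        e, _ = fem._locate(mesh, center)
        v = fem.interpolate_at_points(mesh, u, [center])[0]
        assert v == pytest.approx(u[mesh.elements[e]].mean())

    def test_point_outside_rejected(self, brain_sphere_mesh):
        with pytest.raises(OutsideMeshError):
            fem.interpolate_at_points(
                brain_sphere_mesh, np.zeros(brain_sphere_mesh.n_nodes), [[40.0, 0, 0]]
            )

    def test_shifted_mesh_containment_round_trip(self, small_phantom, rng):
        mesh = fem.voxels_to_hex_mesh(small_phantom, node_shift=0.3)
        for _ in range(10):
            p = rng.uniform(-1, 1, size=3) * 4.0
            e, xi = fem._locate(mesh, p)
            back = fem._shape_functions(xi) @ mesh.nodes_mm[mesh.elements[e]]
            np.testing.assert_allclose(back, p, atol=1e-9)


class TestPotentialTable:
    def test_swapping_anode_and_cathode_negates_row(self, reciprocity_setup):
        volume, electrodes, plan = reciprocity_setup
        mesh = fem.voxels_to_hex_mesh(volume, node_shift=0.0)
        prof = ConductivityProfile("4C", {4: 0.33})
        t1 = fem.simulate_potential_table(mesh, prof, electrodes, plan)
        swapped = plan.pairs.rename(columns={"anode": "cathode", "cathode": "anode"})
        plan2 = type(plan)(pairs=swapped[["pair_id", "anode", "cathode"]], events=plan.events)
        t2 = fem.simulate_potential_table(mesh, prof, electrodes, plan2)
        np.testing.assert_allclose(t2.to_numpy(), -t1.to_numpy(), rtol=1e-6)

    def test_bipolar_entries_gauge_invariant(self, brain_sphere_mesh, rng):
        u = rng.normal(size=brain_sphere_mesh.n_nodes)
        pts = rng.uniform(-1, 1, size=(6, 3)) * 10.0
        va = fem.interpolate_at_points(brain_sphere_mesh, u, pts)
        vb = fem.interpolate_at_points(brain_sphere_mesh, u + 17.3, pts)
        np.testing.assert_allclose(np.diff(va), np.diff(vb), atol=1e-10)

    def test_fem_agrees_with_analytic_oracle_small_sphere(self, brain_sphere_mesh, brain_system):
        """Potential differences within a homogeneous sphere match the
        analytic series solution at 2 mm resolution."""
        dip = Dipole([0.3, 0.2, 0.1], [0, 0, 3.5e-9])
        pts = np.array([[0, 0, 18.0], [0, 0, -18.0], [12, 0, 6.0], [0, -12, -8.0]])
        b = fem.dipole_load_vector(brain_sphere_mesh, dip)
        u = fem.solve_potential(brain_system, b)
        v_fem = fem.interpolate_at_points(brain_sphere_mesh, u, pts)
        v_an = analytic_dipole_potential(ShellModel([20.0], [0.33], n_terms=300), dip, pts)
        d_fem = v_fem[1:] - v_fem[0]
        d_an = v_an[1:] - v_an[0]
        np.testing.assert_allclose(d_fem, d_an, rtol=0.05)
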