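"""Unit tests for the P1 finite-element layer."""

import numpy as np
import pytest
from scipy.integrate import dblquad

from mmpinv.fem import (AssemblyError, PeriodicReduction, SolverError,
                        assemble_load, assemble_mass, assemble_stiffness,
                        cell_average_poly, grad_basis, load_weights,
                        solve_constrained)
from mmpinv.mesh import NodalField, PeriodicMap, SimplicialMesh
from mmpinv.unitcell import BoxDomainSpec, UnitCellSpec, build_box_mesh, \
    build_unit_cell_mesh


class TestMass:
    def test_entries_sum_to_mesh_volume(self, unit_square_mesh,
                                        unit_cube_mesh):
        # partition of unity: 1^T M 1 = |Omega|
        for mesh, vol in ((unit_square_mesh, 1.0), (unit_cube_mesh, 1.0)):
            M = assemble_mass(mesh)
            assert np.isclose(M.sum(), vol, rtol=1e-13)

    def test_reference_triangle_closed_form(self, reference_triangle):
        M = assemble_mass(reference_triangle).toarray()
        area = 0.5
        expected = area / 12.0 * (np.ones((3, 3)) + np.eye(3))
        assert np.allclose(M, expected, rtol=1e-14)

    def test_lumped_preserves_row_sums(self, unit_square_mesh):
        M = assemble_mass(unit_square_mesh)
        L = assemble_mass(unit_square_mesh, lumped=True)
        assert np.allclose(np.asarray(M.sum(axis=1)).ravel(), L.diagonal(),
                           rtol=1e-13)

    def test_spd(self, unit_square_mesh):
        M = assemble_mass(unit_square_mesh).toarray()
        assert np.allclose(M, M.T)
        assert np.linalg.eigvalsh(M).min() > 0


class TestStiffness:
    def test_annihilates_constants(self, unit_square_mesh, unit_cube_mesh):
        for mesh in (unit_square_mesh, unit_cube_mesh):
            K = assemble_stiffness(mesh, 1.0)
            c = np.full(mesh.num_vertices, 3.7)
            assert np.max(np.abs(K @ c)) < 1e-12

    def test_energy_of_linear_field(self, unit_square_mesh):
        # int |grad x1|^2 over the unit square = 1
        K = assemble_stiffness(unit_square_mesh, 1.0)
        x1 = unit_square_mesh.vertices[:, 0]
        assert np.isclose(x1 @ (K @ x1), 1.0, rtol=1e-13)

    def test_zero_coefficient_gives_zero_operator(self, unit_square_mesh):
        K = assemble_stiffness(unit_square_mesh, 0.0)
        assert K.nnz == 0 or np.max(np.abs(K.data)) == 0

    def test_negative_coefficient_rejected_with_location(self,
                                                         unit_square_mesh):
        vals = np.ones(unit_square_mesh.num_vertices)
        vals[7] = -0.5
        with pytest.raises(AssemblyError, match="vertex 7"):
            assemble_stiffness(unit_square_mesh,
                               NodalField(unit_square_mesh, vals))

    def test_matrix_coefficient_anisotropic_energy(self, unit_square_mesh):
        A = np.diag([2.0, 5.0])
        K = assemble_stiffness(unit_square_mesh, A)
        x1 = unit_square_mesh.vertices[:, 0]
        x2 = unit_square_mesh.vertices[:, 1]
        assert np.isclose(x1 @ (K @ x1), 2.0, rtol=1e-13)
        assert np.isclose(x2 @ (K @ x2), 5.0, rtol=1e-13)


class TestExactIntegration:
    @pytest.mark.parametrize("nfactors", [1, 2, 3])
    def test_load_products_match_adaptive_quadrature(self, reference_triangle,
                                                     nfactors):
        """Products of P1 fields integrated exactly: compare against scipy
        adaptive 2d quadrature on the reference triangle."""
        rng = np.random.default_rng(42 + nfactors)
        fields = [rng.uniform(0.5, 2.0, 3) for _ in range(nfactors)]

        def p1(vals, x, y):
            return vals[0] * (1 - x - y) + vals[1] * x + vals[2] * y

        b = assemble_load(reference_triangle, *fields)
        for i, lam in enumerate([lambda x, y: 1 - x - y,
                                 lambda x, y: x, lambda x, y: y]):
            ref, _ = dblquad(
                lambda y, x: np.prod([p1(v, x, y) for v in fields])
                * lam(x, y), 0, 1, 0, lambda x: 1 - x, epsabs=1e-13)
            assert np.isclose(b[i], ref, atol=1e-11)

    def test_cell_average_cubic_matches_quadrature(self, reference_triangle):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.0, 1.0, 3)
        coeffs = (0.25, 0.33, 0.42, 0.1)

        def integrand(y, x):
            u = vals[0] * (1 - x - y) + vals[1] * x + vals[2] * y
            return ((coeffs[0] * u + coeffs[1]) * u + coeffs[2]) * u + coeffs[3]

        ref, _ = dblquad(integrand, 0, 1, 0, lambda x: 1 - x, epsabs=1e-13)
        got = cell_average_poly(reference_triangle, vals, coeffs)[0] * 0.5
        assert np.isclose(got, ref, atol=1e-12)


@pytest.fixture(scope="module")
def cell():
    return build_unit_cell_mesh(UnitCellSpec(2, 1, 0.2, mesh_size=1 / 16))


class TestPeriodic:
    def test_empty_map_is_identity(self, unit_square_mesh):
        M = assemble_mass(unit_square_mesh)
        red = PeriodicReduction(unit_square_mesh.num_vertices,
                                PeriodicMap(np.zeros((0, 2))))
        assert np.allclose(red.reduce_matrix(M).toarray(), M.toarray())

    def test_mass_total_preserved_under_identification(self, cell):
        mesh, pmap = cell
        M = assemble_mass(mesh)
        red = PeriodicReduction(mesh.num_vertices, pmap)
        assert np.isclose(red.reduce_matrix(M).sum(), M.sum(), rtol=1e-12)

    def test_constants_stay_in_reduced_kernel(self, cell):
        mesh, pmap = cell
        K = assemble_stiffness(mesh, 1.0)
        red = PeriodicReduction(mesh.num_vertices, pmap)
        Kr = red.reduce_matrix(K)
        c = np.ones(Kr.shape[0])
        assert np.max(np.abs(Kr @ c)) < 1e-11

    def test_out_of_range_pair_rejected(self, unit_square_mesh):
        with pytest.raises(AssemblyError):
            PeriodicReduction(unit_square_mesh.num_vertices,
                              PeriodicMap(np.array([[0, 10 ** 6]])))


class TestSolve:
    def test_zero_rhs_zero_mean_gives_zero(self, unit_square_mesh):
        K = assemble_stiffness(unit_square_mesh, 1.0)
        w = load_weights(unit_square_mesh)
        u = solve_constrained(K, np.zeros(K.shape[0]), "zero-mean", w)
        assert np.max(np.abs(u)) < 1e-12

    def test_mass_solve_is_identity(self, unit_square_mesh):
        M = assemble_mass(unit_square_mesh)
        rng = np.random.default_rng(3)
        v = rng.standard_normal(M.shape[0])
        u = solve_constrained(M, M @ v)
        assert np.allclose(u, v, atol=1e-10)

    def test_incompatible_rhs_detected(self, unit_square_mesh):
        K = assemble_stiffness(unit_square_mesh, 1.0)
        w = load_weights(unit_square_mesh)
        b = np.ones(K.shape[0])  # strongly non-orthogonal to constants
        with pytest.raises(SolverError, match="incompatible"):
            solve_constrained(K, b, "zero-mean", w)

    @pytest.mark.parametrize("method", ["direct", "cg"])
    def test_neumann_poisson_manufactured_solution(self, method):
        # -u'' = cos(2 pi x1), zero-flux: u = cos(2 pi x1) / (4 pi^2)
        errs, hs = [], []
        for m in (8, 16, 32):
            mesh = build_box_mesh(BoxDomainSpec(2, (0, 0), (1, 1), 1 / m))
            K = assemble_stiffness(mesh, 1.0)
            f = NodalField.from_function(
                mesh, lambda x: np.cos(2 * np.pi * x[:, 0]))
            b = assemble_load(mesh, f)
            b -= b.sum() / len(b)  # remove the interpolation-induced defect
            w = load_weights(mesh)
            u = solve_constrained(K, b, "zero-mean", w, method=method)
            exact = np.cos(2 * np.pi * mesh.vertices[:, 0]) / (4 * np.pi ** 2)
            exact -= exact.mean()
            M = assemble_mass(mesh)
            e = u - exact
            e -= (w @ e) / w.sum()
            errs.append(np.sqrt(e @ (M @ e)))
            hs.append(1 / m)
        slopes = np.diff(np.log(errs)) / np.diff(np.log(hs))
        assert np.all(slopes >= 1.7)


class TestGradients:
    def test_degenerate_cell_rejected(self):
        mesh = SimplicialMesh(2, np.array([[0, 0], [1, 0], [2, 0], [0, 1.0]]),
                              np.array([[0, 1, 3], [0, 1, 2]]))
        with pytest.raises(AssemblyError, match="cell 1"):
            grad_basis(mesh)
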