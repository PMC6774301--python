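"""poisson_solver: charging, boundaries, the grid solve and its evaluators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbforce import (
    Atom,
    GridSpec,
    SolverSettings,
    boundary_potential,
    distribute_charges,
    field_at_points,
    grid_energy,
    potential_at_points,
    solve_poisson,
)
from pbforce.constants import COULOMB_KT_ANGSTROM as C
from pbforce.constants import FOUR_PI_C
from pbforce.dielectric import uniform_map
from pbforce.errors import GridError
from pbforce.grids import ScalarField
from pbforce.solver import PotentialField


def _centered_grid(n=17, h=1.0):
    o = -(n - 1) * h / 2
    return GridSpec((o, o, o), h, (n, n, n))


def _q(x, y, z, q, serial=1):
    return Atom(serial, "A", "Q", (x, y, z), q, 1.5)


class TestDistributeCharges:
    def test_charge_on_node_stays_on_node(self):
        grid = _centered_grid()
        cg = distribute_charges([_q(1.0, -2.0, 0.0, 1.0)], grid)
        idx = grid.to_grid_coords(np.array([[1.0, -2.0, 0.0]]))[0].astype(int)
        assert cg.values[tuple(idx)] == pytest.approx(1.0)
        assert np.sum(cg.values != 0) == 1

    def test_cell_center_splits_equally(self):
        grid = _centered_grid()
        cg = distribute_charges([_q(0.5, 0.5, 0.5, 1.0)], grid)
        assert np.sum(cg.values > 0) == 8
        np.testing.assert_allclose(cg.values[cg.values > 0], 0.125)

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.floats(-4, 4), y=st.floats(-4, 4), z=st.floats(-4, 4),
        q=st.floats(-3, 3),
    )
    def test_total_charge_conserved(self, x, y, z, q):
        grid = _centered_grid()
        cg = distribute_charges([_q(x, y, z, q)], grid)
        assert np.sum(cg.values) == pytest.approx(q, abs=1e-12)

    def test_atom_near_boundary_rejected(self):
        grid = _centered_grid()
        with pytest.raises(GridError, match="boundary"):
            distribute_charges([_q(7.9, 0.0, 0.0, 1.0)], grid)


class TestBoundaryPotential:
    def test_no_charges_all_zero(self):
        grid = _centered_grid()
        assert np.all(boundary_potential([], grid, 80.0) == 0.0)

    def test_single_charge_face_value_is_screened_coulomb(self):
        grid = _centered_grid(n=41, h=1.0)
        vals = boundary_potential([_q(0.0, 0.0, 0.0, 1.0)], grid, 80.0)
        # face-center node on +x face: r = 20 Å
        assert vals[-1, 20, 20] == pytest.approx(C / (80.0 * 20.0), rel=1e-9)

    def test_antisymmetric_pair_cancels_at_face_center(self):
        grid = _centered_grid(n=33, h=1.0)
        atoms = [_q(0.0, 0.0, 3.0, 1.0), _q(0.0, 0.0, -3.0, -1.0, serial=2)]
        vals = boundary_potential(atoms, grid, 80.0)
        assert vals[-1, 16, 16] == pytest.approx(0.0, abs=1e-12)


def _loop_residual(phi, eps, q, h):
    """Independent 7-point flux residual, written with explicit loops."""
    def harm(a, b):
        return 2 * a * b / (a + b)

    nx, ny, nz = phi.shape
    res = np.zeros_like(phi)
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            for k in range(1, nz - 1):
                acc = 0.0
                for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                    e = harm(eps[i, j, k], eps[i + di, j + dj, k + dk])
                    acc += e * (phi[i + di, j + dj, k + dk] - phi[i, j, k])
                res[i, j, k] = acc + FOUR_PI_C * q[i, j, k] / h
    return res


class TestSolvePoisson:
    def test_zero_charges_zero_boundary_gives_zero(self):
        grid = _centered_grid()
        cg = distribute_charges([], grid)
        pot = solve_poisson(cg, uniform_map(grid, 80.0),
                            SolverSettings(boundary="zero"), atoms=[])
        assert np.all(pot.values == 0.0)
        assert pot.converged

    def test_solution_satisfies_stencil_independently(self):
        rng = np.random.default_rng(11)
        grid = _centered_grid(n=11, h=1.0)
        eps = ScalarField(grid, rng.uniform(2.0, 80.0, grid.shape))
        atoms = [_q(1.2, -0.7, 0.3, 1.0), _q(-2.0, 1.1, -1.4, -0.6, serial=2)]
        cg = distribute_charges(atoms, grid)
        pot = solve_poisson(cg, eps, SolverSettings(tolerance=1e-12), atoms=atoms)
        res = _loop_residual(pot.values, eps.values, cg.values, grid.spacing)
        scale = np.abs(FOUR_PI_C * cg.values / grid.spacing).max()
        assert np.abs(res).max() < 1e-8 * scale

    def test_uniform_medium_matches_coulomb(self):
        grid = _centered_grid(n=33, h=1.0)
        atoms = [_q(0.0, 0.0, 0.0, 1.0)]
        cg = distribute_charges(atoms, grid)
        pot = solve_poisson(cg, uniform_map(grid, 80.0), atoms=atoms)
        for r in (5.0, 8.0, 12.0):
            phi = potential_at_points(pot, np.array([[r, 0.0, 0.0]]))[0]
            assert phi == pytest.approx(C / (80.0 * r), rel=0.05)

    def test_superposition(self):
        grid = _centered_grid(n=15, h=1.0)
        eps = uniform_map(grid, 20.0)
        a1 = [_q(1.0, 0.0, 0.0, 1.0)]
        a2 = [_q(-2.0, 1.0, 0.5, -0.7, serial=2)]
        s = SolverSettings(tolerance=1e-10)
        p1 = solve_poisson(distribute_charges(a1, grid), eps, s, atoms=a1)
        p2 = solve_poisson(distribute_charges(a2, grid), eps, s, atoms=a2)
        p12 = solve_poisson(distribute_charges(a1 + a2, grid), eps, s, atoms=a1 + a2)
        np.testing.assert_allclose(p12.values, p1.values + p2.values, atol=1e-6)

    def test_sor_matches_cg(self):
        rng = np.random.default_rng(5)
        grid = _centered_grid(n=11, h=1.0)
        eps = ScalarField(grid, rng.uniform(2.0, 80.0, grid.shape))
        atoms = [_q(0.5, 0.5, -0.5, 1.0)]
        cg_grid = distribute_charges(atoms, grid)
        p_cg = solve_poisson(cg_grid, eps, SolverSettings(tolerance=1e-10), atoms=atoms)
        p_sor = solve_poisson(
            cg_grid, eps,
            SolverSettings(tolerance=1e-10, method="sor", relaxation=1.7,
                           max_iterations=100000),
            atoms=atoms,
        )
        np.testing.assert_allclose(p_sor.values, p_cg.values, atol=1e-7)

    def test_h_refinement_improves_coulomb_error(self):
        errors = []
        for n, h in [(13, 2.0), (25, 1.0), (49, 0.5)]:
            grid = _centered_grid(n=n, h=h)
            atoms = [_q(0.0, 0.0, 0.0, 1.0)]
            cg = distribute_charges(atoms, grid)
            pot = solve_poisson(cg, uniform_map(grid, 80.0), atoms=atoms)
            errs = []
            for r in (5.0, 7.0, 9.0):
                phi = potential_at_points(pot, np.array([[0.0, r, 0.0]]))[0]
                errs.append(abs(phi - C / (80 * r)) / (C / (80 * r)))
            errors.append(max(errs))
        assert errors[0] > errors[1] > errors[2]


class TestGridEnergyAndEvaluation:
    def test_zero_charges_zero_energy(self):
        grid = _centered_grid()
        cg = distribute_charges([], grid)
        pot = PotentialField(grid, np.random.default_rng(0).normal(size=grid.shape))
        assert grid_energy(pot, cg) == 0.0

    def test_grid_energy_quadratic_in_charge(self):
        grid = _centered_grid(n=15, h=1.0)
        eps = uniform_map(grid, 4.0)
        atoms = [_q(0.0, 0.0, 0.0, 1.0)]
        cg1 = distribute_charges(atoms, grid)
        e1 = grid_energy(solve_poisson(cg1, eps, atoms=atoms), cg1)
        atoms2 = [_q(0.0, 0.0, 0.0, 2.0)]
        cg2 = distribute_charges(atoms2, grid)
        e2 = grid_energy(solve_poisson(cg2, eps, atoms=atoms2), cg2)
        assert e2 == pytest.approx(4 * e1, rel=1e-6)

    def test_pair_energy_difference_recovers_screened_coulomb(self):
        # self-energies cancel between identical grids
        grid = _centered_grid(n=29, h=0.8)
        eps = uniform_map(grid, 2.0)
        s = SolverSettings()
        ap = _q(0.0, 0.0, 2.4, 1.0)
        am = _q(0.0, 0.0, -2.6, -1.0, serial=2)

        def energy(atoms):
            cg = distribute_charges(atoms, grid)
            return grid_energy(solve_poisson(cg, eps, s, atoms=atoms), cg)

        e_int = energy([ap, am]) - energy([ap]) - energy([am])
        assert e_int == pytest.approx(-C / (2.0 * 5.0), rel=0.05)

    def test_potential_interpolation_exact_on_nodes(self):
        grid = _centered_grid(n=11, h=1.0)
        values = np.random.default_rng(3).normal(size=grid.shape)
        pot = PotentialField(grid, values)
        pt = np.array([[2.0, -3.0, 1.0]])
        idx = grid.to_grid_coords(pt)[0].astype(int)
        assert potential_at_points(pot, pt)[0] == pytest.approx(values[tuple(idx)])

    def test_field_exact_for_linear_potential(self):
        grid = _centered_grid(n=11, h=1.0)
        z = grid.node_coords()[..., 2]
        pot = PotentialField(grid, z.copy())
        pts = np.array([[0.3, -1.2, 0.7], [2.0, 2.0, -2.0]])
        E = field_at_points(pot, pts)
        np.testing.assert_allclose(E, [[0.0, 0.0, -1.0]] * 2, atol=1e-12)

    def test_field_magnitude_single_charge(self):
        grid = _centered_grid(n=41, h=0.8)
        atoms = [_q(0.0, 0.0, 0.0, 1.0)]
        cg = distribute_charges(atoms, grid)
        pot = solve_poisson(cg, uniform_map(grid, 80.0), atoms=atoms)
        E = field_at_points(pot, np.array([[0.0, 0.0, 10.0]]))[0]
        assert np.linalg.norm(E) == pytest.approx(C / (80 * 100.0), rel=0.05)
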