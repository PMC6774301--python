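"""dielectric_models: Gaussian density maps and probe-closed sharp maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbforce import (
    Atom,
    DielectricParams,
    GridSpec,
    atomic_density,
    gaussian_dielectric_map,
    molecular_density,
    two_dielectric_map,
)


def _atom(x=0.0, y=0.0, z=0.0, r=2.0, q=0.0, serial=1):
    return Atom(serial, "A", "X", (x, y, z), q, r)


class TestAtomicDensity:
    def test_unity_at_center(self):
        assert atomic_density(_atom(), np.array([0.0, 0.0, 0.0]), sigma=0.96) == pytest.approx(1.0)

    def test_one_over_e_at_sigma_radius(self):
        a = _atom(r=2.0)
        sigma = 0.93
        point = np.array([sigma * 2.0, 0.0, 0.0])
        assert atomic_density(a, point, sigma) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_frozen_value(self):
        # sigma=0.96, R=2, r=4: exp(-16 / (0.9216 * 4))
        a = _atom(r=2.0)
        val = atomic_density(a, np.array([0.0, 0.0, 4.0]), sigma=0.96)
        assert val == pytest.approx(0.0130329, rel=1e-5)


class TestMolecularDensity:
    def test_single_atom_equals_atomic(self):
        a = _atom()
        pt = np.array([1.0, 1.0, 0.5])
        assert molecular_density([a], pt, 0.96) == pytest.approx(
            atomic_density(a, pt, 0.96)
        )

    def test_two_half_densities_combine_to_three_quarters(self):
        # place the probe point where each atom contributes exactly 0.5
        r_half = math.sqrt(-math.log(0.5)) * 0.96 * 2.0
        a = _atom(x=-r_half)
        b = _atom(x=+r_half, serial=2)
        val = molecular_density([a, b], np.zeros(3), 0.96)
        assert val == pytest.approx(0.75, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        xs=st.lists(st.floats(-5, 5), min_size=1, max_size=4),
        px=st.floats(-6, 6),
        sigma=st.floats(0.3, 2.0),
    )
    def test_density_bounded_in_unit_interval(self, xs, px, sigma):
        atoms = [_atom(x=x, serial=i + 1) for i, x in enumerate(xs)]
        val = molecular_density(atoms, np.array([px, 0.0, 0.0]), sigma)
        assert 0.0 <= val <= 1.0


def _grid(extent=16.0, spacing=0.5):
    n = int(extent / spacing) + 1
    if n % 2 == 0:
        n += 1
    o = -(n - 1) * spacing / 2
    return GridSpec((o, o, o), spacing, (n, n, n))


class TestGaussianMap:
    params = DielectricParams(model="gaussian", sigma=0.96)

    def test_limits_and_bounds(self):
        grid = _grid()
        field = gaussian_dielectric_map([_atom(r=2.0)], grid, self.params)
        center = tuple(s // 2 for s in grid.shape)
        assert field.values[center] < 3.0  # ~eps_in at an atom center
        assert field.values[0, 0, 0] == pytest.approx(80.0, abs=0.1)  # far corner
        assert np.all(field.values >= self.params.eps_in - 1e-9)
        assert np.all(field.values <= self.params.eps_out + 1e-9)

    def test_linear_mixing_of_density(self):
        # eps = rho*2 + (1-rho)*80; rho=0.5 -> 41
        rho = 0.5
        assert rho * 2 + (1 - rho) * 80 == 41.0

    def test_interior_volume_grows_with_sigma(self):
        grid = _grid()
        atoms = [_atom(r=2.0), _atom(x=3.0, serial=2, r=2.0)]
        volumes = []
        for sigma in (0.5, 0.7, 0.96, 1.2):
            p = DielectricParams(model="gaussian", sigma=sigma)
            field = gaussian_dielectric_map(atoms, grid, p)
            volumes.append(int(np.sum(field.values < 41.0)))
        assert volumes == sorted(volumes)

    def test_translation_equivariance(self):
        atoms = [_atom(x=0.7, y=-0.3, r=1.8)]
        g1 = _grid()
        field1 = gaussian_dielectric_map(atoms, g1, self.params)
        shift = np.array([2.0, -1.0, 0.5])
        g2 = GridSpec(tuple(np.asarray(g1.origin) + shift), g1.spacing, g1.shape)
        moved = [a.moved_to(np.asarray(a.coords) + shift) for a in atoms]
        field2 = gaussian_dielectric_map(moved, g2, self.params)
        np.testing.assert_allclose(field1.values, field2.values, rtol=1e-12)


def _probe_oracle_interior(atoms, node, probe, candidates):
    """Exhaustive sphere-rolling test: a node is solvent-reachable iff some
    probe position clears every atom by R_i + probe and covers the node."""
    centers = np.array([a.coords for a in atoms])
    radii = np.array([a.radius for a in atoms])
    inside_vdw = np.any(np.linalg.norm(node - centers, axis=1) <= radii)
    if inside_vdw:
        return True
    near = np.linalg.norm(candidates - node, axis=1) <= probe
    clears = np.all(
        np.linalg.norm(candidates[:, None, :] - centers[None, :, :], axis=-1)
        > (radii + probe)[None, :],
        axis=1,
    )
    return not np.any(near & clears)


class TestTwoDielectricMap:
    params = DielectricParams(model="two_dielectric", probe_radius=1.4)

    def test_inside_lone_atom_is_eps_in(self):
        grid = _grid()
        field = two_dielectric_map([_atom(r=2.0)], grid, self.params)
        idx = grid.to_grid_coords(np.array([[1.0, 0.0, 0.0]]))[0].round().astype(int)
        assert field.values[tuple(idx)] == self.params.eps_in

    def test_map_takes_exactly_two_values(self):
        grid = _grid()
        field = two_dielectric_map([_atom(r=2.0), _atom(x=3.0, serial=2)], grid, self.params)
        assert set(np.unique(field.values)) == {2.0, 80.0}

    @pytest.mark.parametrize("gap, expect_eps_in", [(2.0, True), (6.0, False)])
    def test_narrow_gap_closes_wide_gap_stays_open(self, gap, expect_eps_in):
        # Two dense sphere slabs separated along z.  A slit between slabs of
        # *discrete* spheres must be narrower than the tangent width before
        # the 1.4 Å probe is excluded everywhere, hence the 2 Å surface gap.
        atoms = []
        serial = 1
        lat = [-3.0, -1.5, 0.0, 1.5, 3.0]
        for zsign in (-1, 1):
            z = zsign * (gap / 2 + 1.8)  # surface-to-surface gap along z
            for x in lat:
                for y in lat:
                    atoms.append(_atom(x=x, y=y, z=z, r=1.8, serial=serial))
                    serial += 1
        grid = _grid(extent=18.0, spacing=0.5)
        field = two_dielectric_map(atoms, grid, self.params)
        mid = grid.to_grid_coords(np.zeros((1, 3)))[0].round().astype(int)
        got_interior = bool(field.values[tuple(mid)] == self.params.eps_in)
        assert got_interior == expect_eps_in
        # independent exhaustive sphere-rolling oracle at the midpoint
        candidates = grid.node_coords().reshape(-1, 3)
        half = candidates[np.abs(candidates).max(axis=1) <= 6.0]
        assert _probe_oracle_interior(atoms, np.zeros(3), 1.4, half) == expect_eps_in

    def test_zero_probe_equals_vdw_union(self):
        atoms = [_atom(r=2.0), _atom(x=2.5, serial=2, r=1.5)]
        grid = _grid(extent=12.0, spacing=0.5)
        p0 = DielectricParams(model="two_dielectric", probe_radius=0.0)
        field = two_dielectric_map(atoms, grid, p0)
        nodes = grid.node_coords().reshape(-1, 3)
        centers = np.array([a.coords for a in atoms])
        radii = np.array([a.radius for a in atoms])
        in_union = np.any(
            np.linalg.norm(nodes[:, None, :] - centers[None, :, :], axis=-1)
            <= radii[None, :],
            axis=1,
        )
        np.testing.assert_array_equal(
            field.values.reshape(-1) == p0.eps_in, in_union
        )

    def test_translation_equivariance(self):
        atoms = [_atom(x=0.3, r=1.8), _atom(x=3.1, y=0.4, serial=2, r=1.8)]
        g1 = _grid(extent=14.0, spacing=0.5)
        f1 = two_dielectric_map(atoms, g1, self.params)
        shift = np.array([1.0, 0.5, -0.75])
        g2 = GridSpec(tuple(np.asarray(g1.origin) + shift), g1.spacing, g1.shape)
        moved = [a.moved_to(np.asarray(a.coords) + shift) for a in atoms]
        f2 = two_dielectric_map(moved, g2, self.params)
        np.testing.assert_array_equal(f1.values, f2.values)


def test_opendx_export_is_parseable(tmp_path):
    from pbforce import write_opendx

    grid = _grid(extent=8.0, spacing=1.0)
    field = gaussian_dielectric_map(
        [_atom(r=2.0)], grid, DielectricParams(model="gaussian")
    )
    path = tmp_path / "eps.dx"
    write_opendx(field, path, name="dielectric")
    lines = path.read_text().splitlines()
    nx, ny, nz = grid.shape
    assert f"object 1 class gridpositions counts {nx} {ny} {nz}" in lines[1]
    data = [
        float(v)
        for line in lines
        if not line.startswith(("#", "object", "origin", "delta", "attribute"))
        for v in line.split()
    ]
    assert len(data) == nx * ny * nz
    assert np.allclose(sorted(data)[-1], field.values.max())
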