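"""Skin extraction and Hodgkin/ESD comparison against exhaustive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ems3d.pbgrid import GridGeometry, PotentialGrid, SolverConfig, solve_lpb
from ems3d.skin import (
    SkinError,
    SkinMask,
    SkinParams,
    compare_pair,
    compute_skin,
    hodgkin_index,
)
from ems3d.structure import make_point_charge


@pytest.fixture(scope="module")
def single_atom():
    return make_point_charge(1.0, 1.5)


@pytest.fixture(scope="module")
def small_geom():
    # 37^3 at 0.5 A: half-extent 9 A, covers sigma+delta = 7 A around the atom
    return GridGeometry.centered(np.zeros(3), 37, 0.5)


def brute_force_membership(molecule, geometry, params):
    """Exhaustive per-node scan, the oracle for compute_skin."""
    ax, ay, az = geometry.axes()
    members = np.zeros(geometry.dims, dtype=bool)
    coords = molecule.coordinates
    radii = molecule.radii
    for i, x in enumerate(ax):
        for j, y in enumerate(ay):
            for k, z in enumerate(az):
                d = min(
                    float(np.linalg.norm(np.array([x, y, z]) - c)) - r
                    for c, r in zip(coords, radii)
                )
                members[i, j, k] = params.sigma <= d < params.sigma + params.delta
    return members


class TestComputeSkin:
    def test_membership_thresholds(self, single_atom, small_geom):
        # atom r=1.5, sigma=3, delta=4: skin is 4.5 <= |p| < 8.5
        mask = compute_skin(single_atom, small_geom, SkinParams(3.0, 4.0))

        def member_at(r):
            idx = tuple(np.array([18, 18, 18]) + np.array([int(round(r / 0.5)), 0, 0]))
            return bool(mask.members[idx])

        assert not member_at(4.0)  # d = 2.5 < sigma
        assert member_at(5.0)  # d = 3.5 inside [3, 7)
        assert member_at(8.0)  # d = 6.5, still inside [3, 7)
        assert not member_at(8.5)  # d = 7.0: half-open upper edge excluded

    def test_sigma_zero_huge_delta_is_everything_outside_vdw(self, single_atom, small_geom):
        mask = compute_skin(single_atom, small_geom, SkinParams(0.0, 1e6))
        ax, ay, az = small_geom.axes()
        xs, ys, zs = np.meshgrid(ax, ay, az, indexing="ij")
        outside = np.sqrt(xs**2 + ys**2 + zs**2) - 1.5 >= 0.0
        np.testing.assert_array_equal(mask.members, outside)

    def test_matches_exhaustive_enumeration(self, single_atom, small_geom):
        params = SkinParams(3.0, 4.0)
        mask = compute_skin(single_atom, small_geom, params)
        oracle = brute_force_membership(single_atom, small_geom, params)
        np.testing.assert_array_equal(mask.members, oracle)
        assert mask.n_points == int(oracle.sum())

    def test_empty_skin_errors(self, single_atom):
        tiny = GridGeometry.centered(np.zeros(3), 5, 0.5)  # 1 A half-extent
        with pytest.raises(SkinError, match="empty skin"):
            compute_skin(single_atom, tiny, SkinParams(3.0, 4.0))


def _field_grid(geometry, fn):
    xs, ys, zs = geometry.node_coordinates()
    values = np.broadcast_to(np.asarray(fn(xs, ys, zs), dtype=float), geometry.dims)
    return PotentialGrid(tuple(geometry.origin), geometry.spacing, values.copy())


class TestHodgkinIndex:
    def test_identity_negation_and_scaling(self, single_atom, small_geom):
        mask = compute_skin(single_atom, small_geom, SkinParams(3.0, 4.0))
        grid = _field_grid(small_geom, lambda x, y, z: 1.0 / np.sqrt(x**2 + y**2 + z**2 + 1.0))
        same = hodgkin_index(grid, grid, mask)
        assert same.si == pytest.approx(1.0, abs=1e-12)
        assert same.esd == pytest.approx(0.0, abs=1e-12)
        neg = PotentialGrid(grid.origin, grid.spacing, -grid.values)
        flipped = hodgkin_index(grid, neg, mask)
        assert flipped.si == pytest.approx(-1.0, abs=1e-12)
        assert flipped.esd == pytest.approx(2.0, abs=1e-12)
        # b = c a  ->  SI = 2c / (1 + c^2); c = 2 gives 0.8
        doubled = PotentialGrid(grid.origin, grid.spacing, 2.0 * grid.values)
        scaled = hodgkin_index(grid, doubled, mask)
        assert scaled.si == pytest.approx(0.8, abs=1e-12)
        assert scaled.esd == pytest.approx(1.0 - 0.8, abs=1e-12)

    def test_disjoint_support_gives_esd_one(self, single_atom, small_geom):
        mask = compute_skin(single_atom, small_geom, SkinParams(3.0, 4.0))
        a = _field_grid(small_geom, lambda x, y, z: np.where(z > 0, 1.0, 0.0))
        b = _field_grid(small_geom, lambda x, y, z: np.where(z <= 0, 1.0, 0.0))
        res = hodgkin_index(a, b, mask)
        assert res.si == pytest.approx(0.0, abs=1e-12)
        assert res.esd == pytest.approx(1.0, abs=1e-12)

    def test_geometry_mismatch_and_zero_fields_error(self, single_atom, small_geom):
        mask = compute_skin(single_atom, small_geom, SkinParams(3.0, 4.0))
        grid = _field_grid(small_geom, lambda x, y, z: x)
        other_geom = GridGeometry.centered(np.ones(3), 33, 0.5)
        other = _field_grid(other_geom, lambda x, y, z: x)
        with pytest.raises(SkinError, match="geometr"):
            hodgkin_index(grid, other, mask)
        zero = _field_grid(small_geom, lambda x, y, z: 0.0 * x)
        with pytest.raises(SkinError, match="identically zero"):
            hodgkin_index(zero, zero, mask)

    def test_hodgkin_sums_match_explicit_enumeration(self, toy_molecules, toy_grids, toy_geometry):
        """Dipole-fixture SI equals the formula accumulated node by node."""
        params = SkinParams(3.0, 4.0)
        mol_a, mol_b = toy_molecules[2], toy_molecules[4]
        grid_a, grid_b = toy_grids[2], toy_grids[4]
        res = compare_pair(mol_a, grid_a, mol_b, grid_b, params)
        mask = compute_skin(mol_a, toy_geometry, params).intersect(
            compute_skin(mol_b, toy_geometry, params)
        )
        s_ab = s_aa = s_bb = 0.0
        n = 0
        it = np.nditer(mask.members, flags=["multi_index"])
        for member in it:
            if member:
                a = grid_a.values[it.multi_index]
                b = grid_b.values[it.multi_index]
                s_ab += a * b
                s_aa += a * a
                s_bb += b * b
                n += 1
        si = 2.0 * s_ab / (s_aa + s_bb)
        assert res.n_points == n
        assert res.si == pytest.approx(si, abs=1e-12)
        assert 0.0 < res.esd < 2.0


class TestComparePair:
    def test_identical_molecule_has_zero_esd(self, toy_molecules, toy_grids):
        res = compare_pair(
            toy_molecules[0], toy_grids[0], toy_molecules[0], toy_grids[0]
        )
        assert res.esd == pytest.approx(0.0, abs=1e-12)

    def test_opposite_ions_have_esd_two(self):
        cfg = SolverConfig(grid_points_per_side=49, spacing=0.6)
        geom = GridGeometry.centered(np.zeros(3), 49, 0.6)
        plus = make_point_charge(1.0, 1.5, label="plus")
        minus = make_point_charge(-1.0, 1.5, label="minus")
        g_plus = solve_lpb(plus, cfg, geom)
        g_minus = solve_lpb(minus, cfg, geom)
        res = compare_pair(plus, g_plus, minus, g_minus)
        assert res.esd == pytest.approx(2.0, abs=1e-9)

    def test_symmetry_self_distance_and_bounds(self, toy_panel):
        for i, (mol_a, grid_a) in enumerate(toy_panel):
            for mol_b, grid_b in toy_panel[i:]:
                ab = compare_pair(mol_a, grid_a, mol_b, grid_b)
                ba = compare_pair(mol_b, grid_b, mol_a, grid_a)
                assert ab.esd == ba.esd  # exact symmetry
                assert -1.0 - 1e-12 <= ab.si <= 1.0 + 1e-12
                assert 0.0 - 1e-9 <= ab.esd <= 2.0 + 1e-9
                if mol_a.label == mol_b.label:
                    assert ab.esd <= 1e-12

    def test_excluding_monomorphic_region_barely_moves_esd(self):
        """Two variants share the bottom pole charge and differ slightly at the
        top; excluding the bottom slab, where their fields are near-identical,
        changes the score by less than 0.05."""
        from ems3d.synthetic import make_toy_molecule

        cfg = SolverConfig(grid_points_per_side=49, spacing=0.6)
        geom = GridGeometry.centered(np.zeros(3), 49, 0.6)
        mol_a = make_toy_molecule("shared-a", [1.0, -1.0, 0.0, 0.0])
        mol_b = make_toy_molecule("shared-b", [0.8, -1.0, 0.0, 0.0])
        grid_a, grid_b = solve_lpb(mol_a, cfg, geom), solve_lpb(mol_b, cfg, geom)
        params = SkinParams(3.0, 4.0)
        full = compare_pair(mol_a, grid_a, mol_b, grid_b, params)
        mask = compute_skin(mol_a, geom, params).intersect(
            compute_skin(mol_b, geom, params)
        )
        _, _, zs = geom.node_coordinates()
        bottom_slab = np.broadcast_to(zs < -4.0, mask.members.shape)
        reduced = SkinMask(mask.origin, mask.spacing, mask.members & ~bottom_slab)
        trimmed = hodgkin_index(grid_a, grid_b, reduced)
        assert abs(trimmed.esd - full.esd) < 0.05


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(SkinError):
            SkinParams(-1.0, 4.0)
        with pytest.raises(SkinError):
            SkinParams(3.0, 0.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_hodgkin_bounds_hold_for_random_fields(seed):
    """|SI| <= 1 and ESD in [0, 2] for arbitrary nonzero fields on any mask."""
    rng = np.random.default_rng(seed)
    geom = GridGeometry.centered(np.zeros(3), 9, 1.0)
    a = PotentialGrid(tuple(geom.origin), 1.0, rng.normal(size=(9, 9, 9)))
    b = PotentialGrid(tuple(geom.origin), 1.0, rng.normal(size=(9, 9, 9)))
    members = rng.random((9, 9, 9)) < 0.3
    members[4, 4, 4] = True  # nonempty
    mask = SkinMask(tuple(geom.origin), 1.0, members)
    res = hodgkin_index(a, b, mask)
    assert -1.0 <= res.si <= 1.0
    assert 0.0 <= res.esd <= 2.0
    assert hodgkin_index(a, a, mask).esd == pytest.approx(0.0, abs=1e-12)
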