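"""Grid scan correctness: occupancy, PSP counting vs brute force, extraction."""

import numpy as np
import pytest

from crypticscreen.core_io import AtomRecord, Structure
from crypticscreen.errors import ContractError, ResourceError
from crypticscreen.pocket_detection import (
    PocketDetectionParams,
    PocketGrid,
    detect_pockets,
    extract_pockets,
    scan_psp,
    voxelize_structure,
)
from crypticscreen.synthetic import brute_force_psp_counts


def _structure(coords, radius=1.7, identifier="s"):
    atoms = tuple(
        AtomRecord("C", "CA", i + 1, "A", tuple(map(float, c)), radius)
        for i, c in enumerate(coords)
    )
    return Structure(identifier, atoms)


def _grid_from_occupancy(occ):
    g = PocketGrid(origin=np.zeros(3), step=1.0, occupancy=np.asarray(occ, dtype=bool))
    return scan_psp(g)


class TestVoxelize:
    def test_single_atom_occupancy_matches_distance_count(self):
        params = PocketDetectionParams(padding=3.0)
        s = _structure([(0.3, -0.2, 0.7)], radius=1.7)
        grid = voxelize_structure(s, params)
        # independent oracle: exhaustive lattice-point distance check
        expected = 0
        nx, ny, nz = grid.dims
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    c = grid.voxel_center((i, j, k))
                    if np.linalg.norm(c - np.array([0.3, -0.2, 0.7])) <= 1.7:
                        expected += 1
        assert int(grid.occupancy.sum()) == expected
        assert expected > 0

    def test_margin_voxels_unoccupied(self):
        params = PocketDetectionParams(padding=4.0)
        grid = voxelize_structure(_structure([(0, 0, 0)]), params)
        assert not grid.occupancy[0].any() and not grid.occupancy[-1].any()
        assert not grid.occupancy[:, 0, :].any() and not grid.occupancy[:, :, 0].any()

    def test_translation_by_one_step_preserves_lattice(self):
        params = PocketDetectionParams(padding=3.0)
        coords = [(0.2, 0.1, -0.4), (2.0, 1.0, 0.5)]
        g1 = voxelize_structure(_structure(coords), params)
        g2 = voxelize_structure(
            _structure([(x + 1.0, y, z) for x, y, z in coords]), params
        )
        np.testing.assert_array_equal(g1.occupancy, g2.occupancy)
        np.testing.assert_allclose(g2.origin - g1.origin, [1.0, 0.0, 0.0])

    def test_unset_radii_rejected(self):
        s = _structure([(0, 0, 0)], radius=None)
        with pytest.raises(ContractError, match="radii"):
            voxelize_structure(s, PocketDetectionParams())

    def test_voxel_budget_enforced(self):
        s = _structure([(0, 0, 0), (500.0, 500.0, 500.0)])
        with pytest.raises(ResourceError):
            voxelize_structure(s, PocketDetectionParams(voxel_budget=1000))


class TestScanPSP:
    def test_axis_line_both_sides_definition(self):
        occ = np.zeros((7, 1, 1), dtype=bool)
        occ[[0, 1, 5, 6], 0, 0] = True
        grid = _grid_from_occupancy(occ)
        # middle solvent voxels are enclosed along x only
        assert list(grid.psp_count[:, 0, 0]) == [0, 0, 1, 1, 1, 0, 0]

    def test_all_solvent_grid_has_zero_counts(self):
        grid = _grid_from_occupancy(np.zeros((5, 5, 5), dtype=bool))
        assert not grid.psp_count.any()

    def test_occupied_voxels_get_zero(self):
        occ = np.ones((4, 4, 4), dtype=bool)
        grid = _grid_from_occupancy(occ)
        assert not grid.psp_count.any()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(6, 13, size=3))
        occ = rng.random(shape) < 0.3
        grid = _grid_from_occupancy(occ)
        np.testing.assert_array_equal(grid.psp_count, brute_force_psp_counts(occ))


def _qualifying_grid(blobs, shape=(20, 20, 20)):
    """Build a grid whose psp_count is >= 6 exactly inside the given index sets."""
    grid = PocketGrid(origin=np.zeros(3), step=1.0,
                      occupancy=np.zeros(shape, dtype=bool))
    psp = np.zeros(shape, dtype=np.int8)
    for blob in blobs:
        for idx in blob:
            psp[idx] = 7
    grid.psp_count = psp
    return grid


def _cube(corner, size):
    x0, y0, z0 = corner
    return [(x0 + i, y0 + j, z0 + k)
            for i in range(size[0]) for j in range(size[1]) for k in range(size[2])]


class TestExtractPockets:
    def test_two_separated_blobs(self):
        big = _cube((1, 1, 1), (5, 4, 2))  # 40 voxels
        small = _cube((10, 10, 10), (5, 7, 1))  # 35 voxels
        grid = _qualifying_grid([big, small])
        pockets = extract_pockets(grid, PocketDetectionParams(), "s")
        assert [p.n_elements for p in pockets] == [40, 35]

    def test_blob_below_min_elements_dropped(self):
        blob = _cube((1, 1, 1), (29, 1, 1))  # 29 voxels
        grid = _qualifying_grid([blob], shape=(32, 8, 8))
        assert extract_pockets(grid, PocketDetectionParams(), "s") == []

    def test_volume_is_count_times_step_cubed(self):
        grid = _qualifying_grid([_cube((1, 1, 1), (4, 4, 4))])
        grid.step = 0.5
        (pocket,) = extract_pockets(grid, PocketDetectionParams(), "s")
        assert pocket.volume == pytest.approx(64 * 0.5**3)

    def test_psp_not_filled_rejected(self):
        grid = PocketGrid(origin=np.zeros(3), step=1.0,
                          occupancy=np.zeros((4, 4, 4), dtype=bool))
        with pytest.raises(ContractError):
            extract_pockets(grid, PocketDetectionParams(), "s")


class TestCavityOracle:
    def test_detection_equals_brute_force_enumeration(self, cavity_fixture,
                                                      default_params):
        structure, oracle = cavity_fixture
        pockets = detect_pockets(structure, default_params)
        assert len(pockets) == 1
        assert pockets[0].n_elements == oracle.n_elements
        assert pockets[0].voxel_indices == oracle.voxel_indices

    def test_min_psp_monotonicity(self, cavity_fixture, default_params):
        structure, _ = cavity_fixture
        grid = voxelize_structure(structure, default_params)
        scan_psp(grid)
        sets = {
            k: set(map(tuple, np.argwhere((grid.psp_count >= k) & ~grid.occupancy)))
            for k in (5, 6, 7)
        }
        assert sets[7] <= sets[6] <= sets[5]

    def test_integer_step_translation_invariance(self, cavity_fixture,
                                                 default_params):
        structure, _ = cavity_fixture
        shifted = Structure(
            "shifted",
            tuple(
                AtomRecord(a.element, a.name, a.residue_index, a.chain_id,
                           (a.position[0] + 3.0, a.position[1] - 2.0, a.position[2]),
                           a.radius)
                for a in structure.atoms
            ),
        )
        p0 = detect_pockets(structure, default_params)
        p1 = detect_pockets(shifted, default_params)
        assert [p.n_elements for p in p0] == [p.n_elements for p in p1]

    def test_occupied_voxels_never_in_pockets(self, cavity_fixture, default_params):
        structure, _ = cavity_fixture
        grid = voxelize_structure(structure, default_params)
        scan_psp(grid)
        for pocket in extract_pockets(grid, default_params, "s"):
            assert all(not grid.occupancy[idx] for idx in pocket.voxel_indices)
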