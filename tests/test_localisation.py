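"""Grid engine: δRMSD fields, localisation volumes, components, export."""

import numpy as np
import pytest

from pcsloc import (
    ChiTensor,
    LocalisationSpace,
    build_grid,
    connected_components,
    export_space,
    pcs,
    pcs_rmsd,
    rmsd_field,
    rmsd_volume,
    threshold_for_volume,
)
from pcsloc.io import read_dx

from conftest import random_tensor


@pytest.fixture
def small_case(rng):
    """Two generic tensors, observations exact at a point inside a small grid."""
    tensors = [random_tensor(rng, max_offset=4.0) for _ in range(2)]
    target = np.array([9.0, -1.0, 2.0])
    observed = [pcs(t, target) for t in tensors]
    grid = build_grid(125.0, 2.0, target)  # 10³ points, spacing 0.5 Å
    return tensors, observed, target, grid


class TestGrid:
    def test_fine_grid_bookkeeping(self):
        g = build_grid(1000.0, 5.0, (0, 0, 0))
        assert g.n_points == 125_000
        assert g.dv == pytest.approx(0.008)
        assert g.spacing == pytest.approx(0.2)

    def test_coarse_grid_bookkeeping(self):
        g = build_grid(1.0e6, 1.0, (0, 0, 0))
        assert g.n_points == 1_000_000
        assert g.dv == pytest.approx(1.0)

    def test_single_point_grid(self):
        g = build_grid(1.0, 1.0, (2.0, 2.0, 2.0))
        assert g.n_points == 1
        np.testing.assert_allclose(g.points(), [[2.0, 2.0, 2.0]])

    def test_grid_centred(self):
        g = build_grid(1000.0, 5.0, (1.0, -2.0, 3.0))
        np.testing.assert_allclose(g.points().mean(axis=0), [1.0, -2.0, 3.0], atol=1e-9)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            build_grid(-1.0, 5.0, (0, 0, 0))
        with pytest.raises(ValueError):
            build_grid(1000.0, 0.0, (0, 0, 0))


class TestRmsdField:
    def test_matches_per_point_oracle(self, small_case):
        tensors, observed, _, grid = small_case
        field = rmsd_field(tensors, observed, grid)
        pts = grid.points()
        oracle = np.array([pcs_rmsd(tensors, observed, p) for p in pts]).reshape(grid.shape)
        np.testing.assert_allclose(field, oracle, rtol=1e-12, atol=1e-15)

    def test_zero_at_generating_point(self, small_case):
        tensors, observed, target, _ = small_case
        # odd point count per axis: the grid centre is itself a grid point
        grid = build_grid(729.0, 1.0, target)
        field = rmsd_field(tensors, observed, grid)
        assert field[4, 4, 4] < 1e-10
        assert field.min() == field[4, 4, 4]

    def test_offset_observations_nonnegative(self, small_case):
        tensors, observed, _, grid = small_case
        field = rmsd_field(tensors, np.asarray(observed) + 0.05, grid)
        assert np.all(field >= 0.0)

    def test_metal_on_grid_point_is_inf(self):
        t = ChiTensor(position=[0.0, 0.0, 0.0], comps=[-1, -1, 0, 0, 0])
        grid = build_grid(27.0, 1.0, (0.0, 0.0, 0.0))  # 3³ grid, metal at centre point
        field = rmsd_field([t], [0.5], grid)
        assert np.isinf(field[1, 1, 1])
        space = rmsd_volume([t], [0.5], grid, threshold=1e9)
        assert not space.mask[1, 1, 1]


class TestRmsdVolume:
    def test_zero_threshold_empty(self, small_case):
        tensors, observed, _, grid = small_case
        assert rmsd_volume(tensors, observed, grid, 0.0).volume == 0.0

    def test_threshold_above_max_fills_grid(self, small_case):
        tensors, observed, _, grid = small_case
        field = rmsd_field(tensors, observed, grid)
        space = rmsd_volume(tensors, observed, grid, field.max() * 1.01, field=field)
        assert space.volume == pytest.approx(grid.n_points * grid.dv)
        assert space.boundary_truncated

    def test_volume_monotone_in_threshold(self, small_case):
        tensors, observed, _, grid = small_case
        field = rmsd_field(tensors, observed, grid)
        vols = [
            rmsd_volume(tensors, observed, grid, thr, field=field).volume
            for thr in np.linspace(0, field[np.isfinite(field)].max(), 25)
        ]
        assert np.all(np.diff(vols) >= 0.0)

    def test_strict_inequality_excludes_ties(self, small_case):
        tensors, observed, _, grid = small_case
        field = rmsd_field(tensors, observed, grid)
        tie = field[2, 3, 4]
        space = rmsd_volume(tensors, observed, grid, tie, field=field)
        assert not space.mask[2, 3, 4]

    def test_noise_free_space_contains_true_point(self, rng):
        """Exact observations: the grid point nearest the spin passes once the
        threshold exceeds the discretisation error."""
        for _ in range(5):
            tensors = [random_tensor(rng, max_offset=4.0) for _ in range(4)]
            target = rng.uniform(8, 12, 3)
            observed = [pcs(t, target) for t in tensors]
            grid = build_grid(1000.0, 5.0, target + rng.uniform(-0.1, 0.1, 3))
            pts = grid.points().reshape(*grid.shape, 3)
            idx = np.unravel_index(
                np.argmin(((pts - target) ** 2).sum(-1)), grid.shape
            )
            nearest = pts[idx]
            # local discretisation error bound from the analytic gradients
            from pcsloc import pcs_gradient

            gnorm = max(np.linalg.norm(pcs_gradient(t, target)) for t in tensors)
            thr = 2.0 * gnorm * np.linalg.norm(nearest - target) + 1e-9
            space = rmsd_volume(tensors, observed, grid, thr)
            assert space.mask[idx]


class TestThresholdForVolume:
    def test_target_full_grid(self, small_case):
        tensors, observed, _, grid = small_case
        thr = threshold_for_volume(tensors, observed, grid, grid.volume)
        field = rmsd_field(tensors, observed, grid)
        assert thr > field.max()

    def test_target_single_point_is_above_minimum(self, small_case):
        tensors, observed, _, grid = small_case
        field = rmsd_field(tensors, observed, grid)
        thr = threshold_for_volume(tensors, observed, grid, grid.dv)
        k_smallest = np.sort(field.ravel())[0]
        assert thr > k_smallest
        assert rmsd_volume(tensors, observed, grid, thr, field=field).volume == pytest.approx(grid.dv)

    def test_self_consistency_within_dv(self, small_case, rng):
        tensors, observed, _, grid = small_case
        field = rmsd_field(tensors, observed, grid)
        for target in rng.uniform(grid.dv, grid.volume, size=5):
            thr = threshold_for_volume(tensors, observed, grid, target, field=field)
            vol = rmsd_volume(tensors, observed, grid, thr, field=field).volume
            assert abs(vol - target) <= grid.dv * (1 + 1e-9)

    def test_invalid_target(self, small_case):
        tensors, observed, _, grid = small_case
        with pytest.raises(ValueError):
            threshold_for_volume(tensors, observed, grid, 0.0)
        with pytest.raises(ValueError):
            threshold_for_volume(tensors, observed, grid, grid.volume * 2)


def _space_from_mask(mask, grid):
    field = np.where(mask, 0.0, 1.0)
    return LocalisationSpace(
        grid=grid, rmsd_field=field, threshold=0.5, mask=mask,
        volume=float(mask.sum()) * grid.dv, boundary_truncated=False,
    )


class TestConnectedComponents:
    def test_empty_mask(self):
        grid = build_grid(1000.0, 1.0, (0, 0, 0))
        n, vols = connected_components(_space_from_mask(np.zeros(grid.shape, bool), grid))
        assert n == 0 and len(vols) == 0

    def test_single_block(self):
        grid = build_grid(1000.0, 1.0, (0, 0, 0))
        mask = np.zeros(grid.shape, bool)
        mask[2:5, 2:5, 2:5] = True
        n, vols = connected_components(_space_from_mask(mask, grid))
        assert n == 1
        assert vols[0] == pytest.approx(27 * grid.dv)

    def test_two_separated_blocks(self):
        grid = build_grid(1000.0, 1.0, (0, 0, 0))
        mask = np.zeros(grid.shape, bool)
        mask[0:2, 0:2, 0:2] = True
        mask[6:9, 6:9, 6:9] = True
        n, vols = connected_components(_space_from_mask(mask, grid))
        assert n == 2
        np.testing.assert_allclose(vols, [27 * grid.dv, 8 * grid.dv])

    def test_diagonal_touch_counts_as_connected(self):
        grid = build_grid(1000.0, 1.0, (0, 0, 0))
        mask = np.zeros(grid.shape, bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True  # 26-connectivity joins corner neighbours
        n, _ = connected_components(_space_from_mask(mask, grid))
        assert n == 1


class TestExport:
    def test_dx_round_trip(self, small_case, tmp_path):
        tensors, observed, _, grid = small_case
        space = rmsd_volume(tensors, observed, grid, 0.05)
        path = tmp_path / "field.dx"
        export_space(space, path, "dx")
        field, spacing, origin = read_dx(path)
        np.testing.assert_allclose(field, space.rmsd_field, rtol=1e-6, atol=1e-12)
        assert spacing == pytest.approx(grid.spacing)
        np.testing.assert_allclose(origin, grid.origin, atol=1e-6)

    def test_pseudoatom_count_matches_mask(self, small_case, tmp_path):
        tensors, observed, _, grid = small_case
        field = rmsd_field(tensors, observed, grid)
        space = rmsd_volume(tensors, observed, grid, np.percentile(field, 10.0), field=field)
        path = tmp_path / "space.pdb"
        export_space(space, path, "pdb")
        n_atoms = sum(1 for line in path.read_text().splitlines() if line.startswith("HETATM"))
        assert n_atoms == space.n_points > 0

    def test_empty_mask_valid_file(self, small_case, tmp_path):
        tensors, observed, _, grid = small_case
        space = rmsd_volume(tensors, observed, grid, 0.0)
        path = tmp_path / "empty.pdb"
        export_space(space, path, "pdb")
        assert path.read_text().strip() == "END"

    def test_unknown_format(self, small_case, tmp_path):
        tensors, observed, _, grid = small_case
        space = rmsd_volume(tensors, observed, grid, 0.05)
        with pytest.raises(ValueError, match="format"):
            export_space(space, tmp_path / "x", "ccp4")
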