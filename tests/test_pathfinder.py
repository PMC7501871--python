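"""Least-action paths, functional dual-landscape routes, frames, back-projection."""

import numpy as np
import pytest
from oracles import enumerate_optimal_action, random_masked_energies

from cryoscape import (
    GridSpec,
    OccupancyGrid,
    backproject_frame,
    bresenham_path,
    dual_landscape_path,
    energy_from_occupancy,
    least_action_path,
    path_action,
    path_frames,
    project_volume,
    transition_map,
)
from cryoscape.landscape import EnergyLandscape


def _landscape(energies, kT=1.0, n_total=1000, condition="minus"):
    energies = np.asarray(energies, dtype=float)
    return EnergyLandscape(
        condition=condition,
        grid=GridSpec(*energies.shape),
        energies=energies,
        mask=np.isnan(energies),
        kT=kT,
        n_total=n_total,
    )


class TestLeastActionPath:
    def test_flat_landscape_has_zero_action(self):
        land = _landscape(np.zeros((4, 4)))
        cells, action = least_action_path(land, (0, 0), (3, 3))
        assert action == 0.0
        assert cells[0] == (0, 0) and cells[-1] == (3, 3)
        for a, b in zip(cells[:-1], cells[1:]):
            assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1

    def test_start_equals_end(self):
        land = _landscape(np.ones((3, 3)))
        cells, action = least_action_path(land, (1, 1), (1, 1))
        assert cells == [(1, 1)]
        assert action == 0.0

    def test_path_threads_the_ridge_gap(self):
        e = np.zeros((4, 4))
        e[2, :] = 50.0
        e[2, 3] = 0.0  # the only gap
        land = _landscape(e)
        cells, action = least_action_path(land, (0, 0), (3, 0))
        assert (2, 3) in cells
        oracle = enumerate_optimal_action(e, (0, 0), (3, 0))
        assert action == pytest.approx(oracle[0], rel=1e-12)

    @pytest.mark.parametrize("mode", ["integral", "minimax"])
    def test_random_grids_match_exhaustive_enumeration(self, mode):
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 40:
            n1, n2 = rng.integers(2, 6, 2)
            e = random_masked_energies(rng, n1, n2)
            occ = np.argwhere(~np.isnan(e))
            if len(occ) < 2:
                continue
            start, end = map(tuple, occ[rng.choice(len(occ), 2, replace=False)])
            oracle = enumerate_optimal_action(e, start, end, mode)
            land = _landscape(e)
            try:
                cells, action = least_action_path(land, start, end, mode)
            except ValueError:
                assert oracle is None
                checked += 1
                continue
            assert oracle is not None
            if mode == "integral":
                assert action == pytest.approx(oracle[0], abs=1e-9)
            else:
                got_max = path_action(cells, np.nan_to_num(e, nan=np.inf), "minimax")
                assert got_max == pytest.approx(oracle[0], abs=1e-9)
                assert action == pytest.approx(oracle[1], abs=1e-9)
            checked += 1

    def test_masked_route_raises_with_explanation(self):
        e = np.zeros((3, 3))
        e[1, :] = np.nan  # full wall
        land = _landscape(e)
        with pytest.raises(ValueError, match="no route"):
            least_action_path(land, (0, 0), (2, 2))

    def test_crossing_flag_admits_masked_cells(self):
        e = np.zeros((3, 3))
        e[1, :] = np.nan
        land = _landscape(e)
        cells, _ = least_action_path(land, (0, 0), (2, 2), allow_unobserved=True)
        assert cells[0] == (0, 0) and cells[-1] == (2, 2)

    def test_optimal_action_bounded_by_bresenham(self):
        rng = np.random.default_rng(33)
        for _ in range(30):
            e = rng.random((5, 5)) * 4
            e -= e.min()
            land = _landscape(e)
            start, end = (0, 0), (4, 3)
            _, action = least_action_path(land, start, end)
            bres = bresenham_path(start, end)
            assert action <= path_action(bres, e) + 1e-12


class TestBresenham:
    def test_straight_line_cells(self):
        assert bresenham_path((0, 0), (0, 3)) == [(0, 0), (0, 1), (0, 2), (0, 3)]

    def test_diagonal(self):
        assert bresenham_path((0, 0), (2, 2)) == [(0, 0), (1, 1), (2, 2)]


class TestDualLandscapePath:
    def _simple_pair(self):
        rng = np.random.default_rng(5)
        nm = rng.integers(1, 30, (6, 6))
        npl = rng.integers(1, 30, (6, 6))
        nm[1, 1] = 200  # minus minimum
        npl[4, 4] = 200  # plus minimum
        nm[3, 3] = 150
        npl[3, 3] = 150  # shared high-occupancy hotspot
        occ_m = OccupancyGrid("minus", GridSpec(6, 6), nm)
        occ_p = OccupancyGrid("plus", GridSpec(6, 6), npl)
        return (
            energy_from_occupancy(occ_m),
            energy_from_occupancy(occ_p),
            transition_map(occ_m, occ_p),
            occ_m,
        )

    def test_identical_landscapes_shared_minimum_single_cell(self):
        counts = np.ones((4, 4), dtype=int)
        counts[2, 2] = 50
        occ_m = OccupancyGrid("minus", GridSpec(4, 4), counts)
        occ_p = OccupancyGrid("plus", GridSpec(4, 4), counts)
        em, ep = energy_from_occupancy(occ_m), energy_from_occupancy(occ_p)
        tm = transition_map(occ_m, occ_p)
        path = dual_landscape_path(em, ep, tm, hotspot=(2, 2))
        assert path.cells == [(2, 2)]
        assert path.action == 0.0
        assert path.switch_index == 0

    def test_endpoints_are_the_two_minima(self):
        em, ep, tm, _ = self._simple_pair()
        path = dual_landscape_path(em, ep, tm)
        assert path.cells[0] == (1, 1)
        assert path.cells[-1] == (4, 4)
        assert path.side[0] == "minus" and path.side[-1] == "plus"
        # exactly one switch, iso-conformational at the hotspot
        switches = sum(
            1 for a, b in zip(path.side[:-1], path.side[1:]) if a != b
        )
        assert switches == 1
        assert path.cells[path.switch_index] == path.hotspot

    def test_consecutive_cells_are_8_adjacent(self):
        em, ep, tm, _ = self._simple_pair()
        path = dual_landscape_path(em, ep, tm)
        for a, b in zip(path.cells[:-1], path.cells[1:]):
            assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1

    def test_summaries_match_direct_recomputation(self):
        from cryoscape import region_fraction

        em, ep, tm, occ_m = self._simple_pair()
        path = dual_landscape_path(em, ep, tm, hot_window_halfwidth=1)
        hs = path.hotspot
        window = [
            (i, j)
            for i in range(max(0, hs[0] - 1), min(6, hs[0] + 2))
            for j in range(max(0, hs[1] - 1), min(6, hs[1] + 2))
        ]
        expected = region_fraction(occ_m, window)
        assert path.summaries["hot_region_occupancy_minus"] == pytest.approx(
            expected, abs=1e-12
        )
        assert path.summaries["hotspot_transition_probability"] == pytest.approx(
            tm.t[hs], abs=1e-15
        )

    def test_unoccupied_hotspot_rejected(self):
        em, ep, tm, _ = self._simple_pair()
        em.mask[0, 5] = True
        with pytest.raises(ValueError, match="hotspot"):
            dual_landscape_path(em, ep, tm, hotspot=(0, 5))


class TestPathFrames:
    def _path(self):
        em, ep, tm, _ = TestDualLandscapePath()._simple_pair()
        return dual_landscape_path(em, ep, tm), GridSpec(6, 6)

    def test_two_frames_sit_at_endpoints(self):
        path, grid = self._path()
        cc = np.random.default_rng(0).random((20, 2))
        cond = np.array(["minus", "plus"] * 10)
        frames = path_frames(path, cc, cond, grid, n_frames=2)
        assert frames.frame_cells[0] == path.cells[0]
        assert frames.frame_cells[-1] == path.cells[-1]

    def test_window_covering_grid_catches_all_same_side_snapshots(self):
        path, grid = self._path()
        rng = np.random.default_rng(1)
        cc = rng.random((40, 2))
        cond = np.array(["minus"] * 20 + ["plus"] * 20)
        frames = path_frames(path, cc, cond, grid, n_frames=5, window_halfwidth=10)
        for cell, side, members in zip(
            frames.frame_cells, frames.frame_side, frames.members
        ):
            assert len(members) == 20
            assert all(cond[m] == side for m in members)

    def test_members_verified_inside_windows_by_direct_scan(self):
        path, grid = self._path()
        rng = np.random.default_rng(2)
        cc = rng.random((200, 2))
        cond = np.array(["minus", "plus"] * 100)
        hw = 1
        frames = path_frames(path, cc, cond, grid, n_frames=10, window_halfwidth=hw)
        w = hw / 6.0
        for cell, side, members in zip(
            frames.frame_cells, frames.frame_side, frames.members
        ):
            lo1, hi1 = cell[0] / 6 - w, (cell[0] + 1) / 6 + w
            lo2, hi2 = cell[1] / 6 - w, (cell[1] + 1) / 6 + w
            expected = {
                i
                for i in range(200)
                if cond[i] == side
                and lo1 <= cc[i, 0] < hi1
                and lo2 <= cc[i, 1] < hi2
            }
            assert set(members) == expected

    def test_empty_frame_warns(self):
        path, grid = self._path()
        cc = np.full((4, 2), 0.99)
        cond = np.array(["minus"] * 4)
        with pytest.warns(UserWarning, match="no member"):
            path_frames(path, cc, cond, grid, n_frames=3, window_halfwidth=0)

    def test_too_few_frames_rejected(self):
        path, grid = self._path()
        with pytest.raises(ValueError):
            path_frames(path, np.zeros((1, 2)), np.array(["minus"]), grid, n_frames=1)


class TestBackprojection:
    def test_single_axis_projection_smears_to_line(self):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 1.0
        img = project_volume(vol, [0, 0, 0])
        rec = backproject_frame(img[None], np.array([[0.0, 0.0, 0.0]]))
        line = rec[:, 4, 4]
        np.testing.assert_allclose(line, 1.0)
        rec[:, 4, 4] = 0.0
        assert rec.sum() == 0.0

    def test_duplicate_views_equal_single_view(self):
        rng = np.random.default_rng(3)
        img = rng.random((8, 8))
        eul = np.array([[25.0, 60.0, 0.0]])
        one = backproject_frame(img[None], eul)
        two = backproject_frame(np.stack([img, img]), np.vstack([eul, eul]))
        np.testing.assert_allclose(one, two, atol=1e-12)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            backproject_frame(np.zeros((0, 8, 8)), np.zeros((0, 3)))

    def test_many_views_recover_phantom_shape(self, phantom):
        from cryoscape.synthetic import euler_from_direction, fibonacci_directions

        vol = phantom.base_map
        dirs = fibonacci_directions(60)
        eulers = np.array([euler_from_direction(d) for d in dirs])
        images = np.stack([project_volume(vol, e) for e in eulers])
        rec = backproject_frame(images, eulers)
        corr = np.corrcoef(rec.ravel(), vol.ravel())[0, 1]
        assert corr > 0.7
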