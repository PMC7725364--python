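"""Relative coordinates and overlapping-bin averaging."""

import numpy as np
import pandas as pd
import pytest

import swarminfer as si
from swarminfer.averaging import GridSpec, bin_responses, pooled_surface
from swarminfer.trajectory import Trajectory


def pair_table(x, y, values, speeds=None):
    n = len(x)
    return pd.DataFrame(
        {
            "x_rel": x,
            "y_rel": y,
            "dtheta_dt": values,
            "ds_dt": values,
            "s_focal": speeds if speeds is not None else np.ones(n),
        }
    )


def brute_force_surface(x, y, values, grid):
    """Independent oracle: test every (sample, bin) pair for containment."""
    centres = grid.centres
    n = len(centres)
    count = np.zeros((n, n))
    total = np.zeros((n, n))
    for xs, ys, vs in zip(x, y, values):
        for i, cx in enumerate(centres):
            if not (cx - grid.w / 2 <= xs < cx + grid.w / 2):
                continue
            for j, cy in enumerate(centres):
                if cy - grid.w / 2 <= ys < cy + grid.w / 2:
                    count[i, j] += 1
                    total[i, j] += vs
    with np.errstate(invalid="ignore"):
        return count, np.where(count > 0, total / count, np.nan)


class TestRelativeCoordinates:
    @staticmethod
    def _two_agent_track(partner_offset):
        # focal at origin moving +y at 10 units/s; partner riding alongside
        pos = np.zeros((3, 2, 2))
        for t in range(3):
            pos[t, 0] = [0.0, t]
            pos[t, 1] = np.array([0.0, t]) + partner_offset
        return Trajectory(pos, dt=0.1)

    def test_partner_dead_ahead(self):
        pairs = si.relative_coordinates(self._two_agent_track([0.0, 2.0]))
        row = pairs[(pairs.focal == 0) & (pairs.t == 0)].iloc[0]
        assert (row.x_rel, row.y_rel) == pytest.approx((2.0, 0.0))
        assert row.vartheta == pytest.approx(0.0)

    def test_partner_to_the_right(self):
        pairs = si.relative_coordinates(self._two_agent_track([2.0, 0.0]))
        row = pairs[(pairs.focal == 0) & (pairs.t == 0)].iloc[0]
        assert row.phi == pytest.approx(90.0)
        assert row.zeta == -1
        assert row.vartheta == pytest.approx(-90.0)
        assert (row.x_rel, row.y_rel) == pytest.approx((0.0, -2.0), abs=1e-12)

    def test_partner_directly_behind_collinear_branch(self):
        pairs = si.relative_coordinates(self._two_agent_track([0.0, -2.0]))
        row = pairs[(pairs.focal == 0) & (pairs.t == 0)].iloc[0]
        assert row.phi == pytest.approx(180.0)
        assert row.zeta == 0
        assert row.vartheta == pytest.approx(180.0)
        assert (row.x_rel, row.y_rel) == pytest.approx((-2.0, 0.0), abs=1e-12)

    def test_polar_and_rectangular_agree(self):
        traj = si.run_zonal(si.ZonalParams(N=5, n_steps=30, seed=2))
        pairs = si.relative_coordinates(traj)
        assert np.allclose(np.hypot(pairs.x_rel, pairs.y_rel), pairs.d)
        nz = pairs[pairs.zeta != 0]
        assert (np.sign(nz.vartheta) == nz.zeta).all()

    def test_stationary_focal_yields_no_rows(self):
        traj = si.make_fixture("two_stationary", n_steps=6)
        assert len(si.relative_coordinates(traj)) == 0


class TestBinning:
    def test_single_sample_hits_every_containing_bin(self):
        surf = bin_responses(pair_table([0.2], [0.2], [5.0]), GridSpec(1.0, 0.5, 2.0))
        assert surf.count.sum() == 4  # 2 bins per axis for w/c = 2
        means = surf.mean[surf.count > 0]
        assert np.allclose(means, 5.0)

    def test_two_samples_average_in_shared_bin(self):
        surf = bin_responses(
            pair_table([0.1, 0.15], [0.1, 0.1], [4.0, 6.0]), GridSpec(1.0, 0.5, 2.0)
        )
        assert np.allclose(surf.mean[surf.count == 2], 5.0)

    def test_streaming_accumulation_equals_brute_force(self, rng):
        n = 1000
        x = rng.uniform(-3.5, 3.5, n)
        y = rng.uniform(-3.5, 3.5, n)
        v = rng.normal(0, 10, n)
        grid = GridSpec(1.0, 0.5, 3.0)
        surf = bin_responses(pair_table(x, y, v), grid)
        count, mean = brute_force_surface(x, y, v, grid)
        assert np.array_equal(surf.count, count)
        assert np.allclose(surf.mean, mean, equal_nan=True)

    def test_empty_input_warns_and_emits_surface(self):
        with pytest.warns(UserWarning, match="no samples"):
            surf = bin_responses(pair_table([50.0], [50.0], [1.0]), GridSpec(1, 0.5, 2))
        assert surf.count.sum() == 0
        assert np.isnan(surf.mean).all()

    def test_speed_classes_partition_the_samples(self, rng):
        n = 500
        tab = pair_table(
            rng.uniform(-2, 2, n), rng.uniform(-2, 2, n), rng.normal(size=n),
            speeds=rng.uniform(0, 4, n),
        )
        grid = GridSpec(1.0, 0.5, 3.0)
        surfs = bin_responses(tab, grid, speed_classes=5)
        assert len(surfs) == 5
        total = sum(s.count for s in surfs)
        assert np.array_equal(total, bin_responses(tab, grid).count)


class TestPooling:
    def test_pooling_with_itself_doubles_counts_keeps_means(self, rng):
        tab = pair_table(rng.uniform(-2, 2, 50), rng.uniform(-2, 2, 50),
                         rng.normal(size=50))
        grid = GridSpec(1.0, 0.5, 3.0)
        surf = bin_responses(tab, grid)
        pooled = pooled_surface([surf, surf])
        assert np.array_equal(pooled.count, 2 * surf.count)
        assert np.allclose(pooled.mean, surf.mean, equal_nan=True)

    def test_disjoint_support_unions(self):
        grid = GridSpec(1.0, 0.5, 3.0)
        a = bin_responses(pair_table([-2.0], [0.0], [1.0]), grid)
        b = bin_responses(pair_table([2.0], [0.0], [3.0]), grid)
        pooled = pooled_surface([a, b])
        assert pooled.count.sum() == a.count.sum() + b.count.sum()
        assert ((pooled.count > 0) == ((a.count > 0) | (b.count > 0))).all()

    def test_mismatched_grids_rejected(self):
        a = bin_responses(pair_table([0.0], [0.0], [1.0]), GridSpec(1, 0.5, 3))
        b = bin_responses(pair_table([0.0], [0.0], [1.0]), GridSpec(1, 0.5, 4))
        with pytest.raises(ValueError, match="mismatched"):
            pooled_surface([a, b])

    def test_half_windows_partition_full_window(self):
        trajs = [si.run_zonal(si.ZonalParams(N=6, n_steps=50, seed=s)) for s in (0, 1)]
        grid = GridSpec(1.0, 0.5, 15.0)
        full = si.surface_from_trajectories(trajs, grid, window="full")
        first = si.surface_from_trajectories(trajs, grid, window="first_half")
        second = si.surface_from_trajectories(trajs, grid, window="second_half")
        assert np.array_equal(first.count + second.count, full.count)
        assert np.allclose(first.value_sum + second.value_sum, full.value_sum)


class TestSurfaceIO:
    def test_write_read_round_trip(self, tmp_path, rng):
        tab = pair_table(rng.uniform(-2, 2, 200), rng.uniform(-2, 2, 200),
                         rng.normal(size=200))
        grid = GridSpec(1.0, 0.5, 3.0)
        surf = bin_responses(tab, grid)
        path = tmp_path / "surface.csv"
        si.averaging.write_surface(surf, path)
        back = si.averaging.read_surface(path, grid=grid)
        assert np.array_equal(back.count, surf.count)
        assert np.allclose(back.mean, surf.mean, equal_nan=True)
        assert np.allclose(back.var, surf.var, equal_nan=True, atol=1e-9)


def test_turn_surface_mirror_antisymmetry_on_mirrored_ensemble():
    """Mirroring every track about the x-axis flips the turn-rate surface."""
    trajs = [si.run_zonal(si.ZonalParams(N=8, n_steps=120, seed=s)) for s in (3, 4)]
    mirrored = [
        Trajectory(t.positions * np.array([1.0, -1.0]), t.dt) for t in trajs
    ]
    grid = GridSpec(1.0, 0.5, 15.0)
    a = si.surface_from_trajectories(trajs, grid, "turn_rate")
    b = si.surface_from_trajectories(mirrored, grid, "turn_rate")
    assert np.allclose(b.mean[:, ::-1], -a.mean, equal_nan=True)
    sa = si.surface_from_trajectories(trajs, grid, "speed_change")
    sb = si.surface_from_trajectories(mirrored, grid, "speed_change")
    assert np.allclose(sb.mean[:, ::-1], sa.mean, equal_nan=True)
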