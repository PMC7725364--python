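"""Zonal model: visibility, steering rules, stepping, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swarminfer as si
from swarminfer.zonal import (
    ZonalParams,
    desired_direction,
    initial_conditions,
    step,
    visible_neighbours,
)

P = ZonalParams(N=25, r_r=2.0, delta_r_o=1.0, delta_r_a=11.0, omega_blind=90.0)
EAST = np.array([1.0, 0.0])
NORTH = np.array([0.0, 1.0])


def bearing_vec(deg):
    return np.array([np.cos(np.radians(deg)), np.sin(np.radians(deg))])


class TestVisibility:
    def test_partner_directly_behind_is_hidden(self):
        idx = visible_neighbours(np.zeros(2), EAST, [[-1.0, 0.0]], "ZOR", P)
        assert len(idx) == 0

    def test_no_blind_angle_sees_behind(self):
        p0 = ZonalParams(N=25, r_r=2.0, delta_r_o=1.0, delta_r_a=11.0, omega_blind=0.0)
        idx = visible_neighbours(np.zeros(2), EAST, [[-1.0, 0.0]], "ZOR", p0)
        assert list(idx) == [0]

    def test_blind_scope_spares_the_repulsion_zone(self):
        p = ZonalParams(N=25, r_r=2.0, delta_r_o=1.0, delta_r_a=11.0,
                        omega_blind=90.0, blind_scope="orientation_and_attraction_only")
        behind_close = [[-1.0, 0.0]]
        assert list(visible_neighbours(np.zeros(2), EAST, behind_close, "ZOR", p)) == [0]
        behind_mid = [[-2.5, 0.0]]
        assert len(visible_neighbours(np.zeros(2), EAST, behind_mid, "ZOO", p)) == 0
        behind_far = [[-5.0, 0.0]]
        assert len(visible_neighbours(np.zeros(2), EAST, behind_far, "ZOA", p)) == 0

    def test_zone_annuli_are_half_open(self):
        # distance exactly r_r belongs to ZOR, not ZOO
        at_rr = [[P.r_r, 0.0]]
        assert list(visible_neighbours(np.zeros(2), EAST, at_rr, "ZOR", P)) == [0]
        assert len(visible_neighbours(np.zeros(2), EAST, at_rr, "ZOO", P)) == 0

    def test_coincident_partner_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="coincident"):
            idx = visible_neighbours(np.zeros(2), EAST, [[0.0, 0.0]], "ZOR", P)
        assert len(idx) == 0

    def test_blind_wedge_edge_at_half_angle(self):
        # edge of the 90 deg wedge lies at bearing 135 deg
        just_visible = [1.4 * bearing_vec(134.0)]
        just_hidden = [1.4 * bearing_vec(136.0)]
        assert len(visible_neighbours(np.zeros(2), EAST, just_visible, "ZOR", P)) == 1
        assert len(visible_neighbours(np.zeros(2), EAST, just_hidden, "ZOR", P)) == 0


class TestDesiredDirection:
    def test_single_repulsion_partner_drives_directly_away(self):
        pos = np.array([[0.0, 0.0], bearing_vec(45.0)])
        head = np.array([EAST, EAST])
        d = desired_direction(0, pos, head, P)
        assert np.allclose(d, bearing_vec(-135.0))

    def test_no_partner_in_range_gives_no_preference(self):
        pos = np.array([[0.0, 0.0], [100.0, 0.0]])
        head = np.array([EAST, EAST])
        assert desired_direction(0, pos, head, P) is None

    def test_orientation_and_attraction_average(self):
        # one ZOO partner heading east, one ZOA partner due north of the focal
        pos = np.array([[0.0, 0.0], [2.5, 0.0], [0.0, 5.0]])
        head = np.array([EAST, EAST, EAST])
        d = desired_direction(0, pos, head, P)
        expected = (EAST + NORTH) / np.linalg.norm(EAST + NORTH)
        assert np.allclose(d, expected)

    def test_repulsion_overrides_attraction(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 5.0]])
        head = np.array([EAST, EAST, EAST])
        d = desired_direction(0, pos, head, P)
        assert np.allclose(d, -EAST)

    def test_balanced_repulsion_is_no_preference(self):
        # two ZOR partners at exactly opposite bearings cancel
        pos = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        head = np.array([EAST, EAST, EAST])
        assert desired_direction(0, pos, head, P) is None


class TestStep:
    def test_lone_agent_moves_straight_at_constant_speed(self):
        p = ZonalParams(N=1, eta=0.0)
        pos, head = np.zeros((1, 2)), EAST[None, :].copy()
        new_pos, new_head = step(pos, head, p, np.random.default_rng(0))
        assert np.allclose(new_head, EAST)
        assert np.allclose(new_pos, [[0.3, 0.0]])  # s * dt = 3 * 0.1

    def test_turn_saturates_at_theta_max_dt(self):
        # desired direction 135 deg away: only 4 deg achieved this step
        p = ZonalParams(N=2, eta=0.0, r_r=2.0, delta_r_o=1.0, delta_r_a=11.0)
        pos = np.array([[0.0, 0.0], bearing_vec(45.0)])
        head = np.array([EAST, bearing_vec(45.0)])
        _, new_head = step(pos, head, p, np.random.default_rng(0))
        turned = np.degrees(np.arctan2(new_head[0, 1], new_head[0, 0]))
        assert turned == pytest.approx(-4.0, abs=1e-9)

    def test_antipodal_desired_direction_turns_anticlockwise(self):
        p = ZonalParams(N=2, eta=0.0, r_r=2.0, delta_r_o=1.0, delta_r_a=11.0)
        pos = np.array([[0.0, 0.0], [1.0, 0.0]])  # repulsion pushes due west
        head = np.array([EAST, EAST])
        _, new_head = step(pos, head, p, np.random.default_rng(0))
        turned = np.degrees(np.arctan2(new_head[0, 1], new_head[0, 0]))
        assert turned == pytest.approx(+4.0, abs=1e-9)

    def test_speed_conserved_every_step(self):
        p = ZonalParams(N=8, n_steps=40, seed=3)
        traj = si.run_zonal(p)
        steps = np.diff(traj.positions, axis=0)
        assert np.allclose(np.hypot(steps[..., 0], steps[..., 1]), p.s * p.dt)

    def test_repulsion_separates_close_pair(self):
        p = ZonalParams(N=2, eta=0.0, r_r=2.0, delta_r_o=1.0, delta_r_a=11.0,
                        n_steps=80, seed=0, init_box=1.0)
        # place manually: one agent dead ahead of the other, inside the ZOR
        pos = np.array([[0.0, 0.0], [1.0, 0.1]])
        head = np.array([EAST, EAST])
        dists = []
        rng = np.random.default_rng(0)
        for _ in range(60):
            pos, head = step(pos, head, p, rng)
            dists.append(np.hypot(*(pos[1] - pos[0])))
        dists = np.array(dists)
        assert dists[-1] > 2.0  # escaped the repulsion zone
        # monotone separation while the partner is still inside the ZOR
        inside = dists <= p.r_r
        assert (np.diff(dists[inside]) > -1e-9).all()


class TestRunZonal:
    def test_same_seed_bitwise_identical(self):
        p = ZonalParams(N=6, n_steps=30, seed=42)
        a, b = si.run_zonal(p), si.run_zonal(p)
        assert np.array_equal(a.positions, b.positions)

    def test_independent_pair_goes_straight(self):
        p = ZonalParams(N=2, eta=0.0, n_steps=25, seed=1, init_box=200.0)
        traj = si.run_zonal(p)
        v = np.diff(traj.positions, axis=0)
        assert np.allclose(v, v[0], atol=1e-12)

    def test_mirrored_initial_conditions_mirror_the_noise_free_run(self):
        p = ZonalParams(N=5, eta=0.0, n_steps=40, seed=7)
        rng = np.random.default_rng(0)
        pos, head = initial_conditions(p, rng)
        flip = np.array([1.0, -1.0])
        a_pos, a_head = pos.copy(), head.copy()
        b_pos, b_head = pos * flip, head * flip
        r = np.random.default_rng(0)
        for _ in range(40):
            a_pos, a_head = step(a_pos, a_head, p, r)
            b_pos, b_head = step(b_pos, b_head, p, r)
            assert np.allclose(b_pos, a_pos * flip, atol=1e-10)

    def test_invalid_zone_ordering_rejected(self):
        with pytest.raises(ValueError):
            ZonalParams(r_r=2.0, delta_r_o=0.0, delta_r_a=0.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_per_step_turn_bounded_without_noise(seed):
    p = ZonalParams(N=6, eta=0.0, n_steps=5, seed=seed,
                    r_r=1.0, delta_r_o=2.0, delta_r_a=11.0)
    traj = si.run_zonal(p)
    v = np.diff(traj.positions, axis=0)
    h = v / np.hypot(v[..., 0], v[..., 1])[..., None]
    dots = np.clip(np.einsum("tij,tij->ti", h[:-1], h[1:]), -1, 1)
    assert np.degrees(np.arccos(dots)).max() <= p.theta_max * p.dt + 1e-9
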