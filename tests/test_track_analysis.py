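import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_track, straight_track
from confinetrack.cell_sim import simulate_rigid_particles
from confinetrack.collision_model import DEFAULT_PARAMS
from confinetrack.track_analysis import (
    OUTCOME_PASS,
    OUTCOME_PUSH,
    OUTCOME_REFLECT,
    OUTCOME_UNRESOLVED,
    CollisionEvent,
    angle_histogram,
    collision_angles,
    detect_collisions,
    mean_velocity,
    pre_post_velocity,
)


class TestMeanVelocity:
    def test_constant_speed_straight_line(self):
        # 0.65 um per 10-s frame = 3.9 um/min
        tr = straight_track(0, (0, 0), (1, 0), 0.65, 30)
        assert mean_velocity(tr) == pytest.approx(3.9)

    def test_stationary_track(self):
        tr = make_track(0, np.zeros((20, 2)))
        assert mean_velocity(tr) == 0.0

    def test_circular_orbit_chord_speed(self):
        # chord length 2 r sin(dtheta/2) per frame; closed-form oracle
        r, dth, n = 10.0, 0.1, 100
        ang = dth * np.arange(n)
        xy = r * np.column_stack([np.cos(ang), np.sin(ang)])
        tr = make_track(0, xy)
        expected = 2.0 * r * math.sin(dth / 2.0) / 10.0 * 60.0
        assert mean_velocity(tr) == pytest.approx(expected)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            mean_velocity(make_track(0, [[0.0, 0.0]]))

    @settings(max_examples=30, derandomize=True)
    @given(
        rot=st.floats(0, 2 * math.pi),
        dx=st.floats(-100, 100),
        dy=st.floats(-100, 100),
        seed=st.integers(0, 100),
    )
    def test_invariant_under_rigid_motion(self, rot, dx, dy, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(0, 0.5, size=(30, 2)), axis=0)
        R = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])
        moved = xy @ R.T + (dx, dy)
        assert mean_velocity(make_track(0, moved)) == pytest.approx(
            mean_velocity(make_track(0, xy)), rel=1e-9
        )


def brute_force_episode_count(xy_a, xy_b, threshold, hysteresis):
    """Independent episode counter by direct distance scan."""
    d = np.linalg.norm(np.asarray(xy_a) - np.asarray(xy_b), axis=1)
    episodes, in_ep, apart = 0, False, 0
    for dist in d:
        if dist < threshold:
            if not in_ep:
                episodes += 1
                in_ep = True
            apart = 0
        elif in_ep:
            apart += 1
            if apart >= hysteresis:
                in_ep, apart = False, 0
    return episodes


class TestDetectCollisions:
    def test_distant_stationary_cells_no_events(self):
        a = make_track(0, np.zeros((30, 2)))
        b = make_track(1, np.full((30, 2), [100.0, 0.0]))
        assert detect_collisions([a, b], contact_distance=5.0) == []

    def test_single_crossing_is_one_event(self):
        a = straight_track(0, (-20, 0), (1, 0), 1.0, 40)
        b = make_track(1, np.tile([0.0, 0.0], (41, 1)))
        events = detect_collisions([a, b], contact_distance=4.0)
        assert len(events) == 1
        assert events[0].cell_a == 0  # the moving cell approaches

    def test_two_separate_approaches_of_same_pair(self):
        # approach, retreat well beyond hysteresis, approach again
        xs = np.concatenate([
            np.linspace(-20, 0, 21), np.linspace(1, 15, 15),
            np.linspace(14, 0, 15),
        ])
        a = make_track(0, np.column_stack([xs, np.zeros_like(xs)]))
        b = make_track(1, np.tile([0.0, 0.0], (len(xs), 1)))
        events = detect_collisions([a, b], contact_distance=4.0)
        expected = brute_force_episode_count(
            a.xy, b.xy, threshold=4.0, hysteresis=2
        )
        assert len(events) == expected == 2

    def test_mismatched_clocks_rejected(self):
        a = make_track(0, np.zeros((10, 2)), dt=10.0)
        b = make_track(1, np.zeros((10, 2)), dt=5.0)
        with pytest.raises(ValueError, match="clock"):
            detect_collisions([a, b], contact_distance=1.0)

    def test_matches_rigid_particle_internal_count(self):
        # two independent code paths must agree exactly
        from confinetrack.cell_sim import RIGID_HYSTERESIS_FRAMES

        for seed in (0, 1, 2):
            n_internal, tracks = simulate_rigid_particles(
                DEFAULT_PARAMS, N=10, duration_h=0.5, seed=seed, record_tracks=True
            )
            events = detect_collisions(
                tracks, DEFAULT_PARAMS.L, hysteresis_frames=RIGID_HYSTERESIS_FRAMES
            )
            assert len(events) == n_internal


def _scripted_event(theta_in_deg, theta_out_deg):
    """Tracks for cell A approaching stationary B at (0, 0) from the left,
    entering at ``theta_in_deg`` to B's tangent and leaving at
    ``theta_out_deg`` (positive = back to A's side). Returns (event, tracks).

    B sits at origin; contact occurs along the -x normal, so B's perimeter
    tangent at contact is the y axis and A's side is x < 0.
    """
    dt, step, n = 10.0, 1.0, 6
    ti, to = math.radians(theta_in_deg), math.radians(theta_out_deg)
    u_in = np.array([math.sin(ti), math.cos(ti)])  # theta_in from the y tangent
    contact = np.array([-4.0, 0.0])
    approach = contact - u_in * step * np.arange(n, 0, -1)[:, None]
    u_out = np.array([-math.sin(to), math.cos(to)])
    depart = contact + u_out * step * np.arange(1, n + 1)[:, None]
    xy_a = np.vstack([approach, [contact], depart])
    a = make_track(0, xy_a, dt=dt)
    b = make_track(1, np.tile([0.0, 0.0], (len(xy_a), 1)), dt=dt)
    t_contact = n * dt
    event = CollisionEvent(
        cell_a=0, cell_b=1, start_t=t_contact, end_t=t_contact,
        contact_point=(-2.0, 0.0),
    )
    return event, [a, b]


class TestCollisionAngles:
    def test_head_on_entering_angle_is_90(self):
        event, tracks = _scripted_event(90.0, 90.0)
        collision_angles(event, tracks)
        assert event.entering_angle == pytest.approx(90.0, abs=1e-6)

    def test_grazing_entering_angle_is_0(self):
        event, tracks = _scripted_event(0.0, 0.0)
        collision_angles(event, tracks)
        assert event.entering_angle == pytest.approx(0.0, abs=1e-6)

    def test_mirror_reflection_at_45(self):
        event, tracks = _scripted_event(45.0, 45.0)
        collision_angles(event, tracks)
        assert event.entering_angle == pytest.approx(45.0, abs=1e-6)
        assert event.exiting_angle == pytest.approx(45.0, abs=1e-6)
        assert event.outcome == OUTCOME_REFLECT

    def test_straight_pass_through(self):
        event, tracks = _scripted_event(45.0, -45.0)
        collision_angles(event, tracks)
        assert event.exiting_angle == pytest.approx(-45.0, abs=1e-6)
        assert event.outcome == OUTCOME_PASS

    def test_push_through_beyond_minus_90(self):
        event, tracks = _scripted_event(45.0, -120.0)
        collision_angles(event, tracks)
        assert event.exiting_angle == pytest.approx(-120.0, abs=1e-6)
        assert event.outcome == OUTCOME_PUSH

    def test_insufficient_window_flags_unresolved(self):
        event, tracks = _scripted_event(45.0, 45.0)
        event.start_t = 0.0  # no pre-contact window exists
        collision_angles(event, tracks)
        assert event.outcome == OUTCOME_UNRESOLVED

    def test_angle_ranges_on_simulated_events(self):
        _, tracks = simulate_rigid_particles(
            DEFAULT_PARAMS, N=10, duration_h=0.5, seed=7, record_tracks=True
        )
        events = detect_collisions(tracks, DEFAULT_PARAMS.L)
        resolved = 0
        for e in events:
            collision_angles(e, tracks)
            if e.outcome == OUTCOME_UNRESOLVED:
                continue
            resolved += 1
            assert 0.0 <= e.entering_angle <= 90.0
            assert -180.0 < e.exiting_angle <= 90.0
        hist = angle_histogram(events, which="exiting")
        assert hist.n_events == resolved


class TestPrePostVelocity:
    def test_constant_speed_unchanged(self):
        event, tracks = _scripted_event(45.0, 45.0)
        res = pre_post_velocity(event, tracks, window=30.0)
        assert res is not None
        v_pre, v_post = res
        assert v_post == pytest.approx(v_pre)

    def test_halved_speed_after_contact(self):
        dt, n = 10.0, 14
        before = np.column_stack([np.arange(n) * 1.0, np.zeros(n)])
        after = before[-1] + np.column_stack(
            [np.cumsum(np.full(n, 0.5)), np.zeros(n)]
        )
        a = make_track(0, np.vstack([before, after]), dt=dt)
        b = make_track(1, np.tile([100.0, 0.0], (2 * n, 1)), dt=dt)
        t_mid = (n - 1) * dt
        event = CollisionEvent(0, 1, t_mid, t_mid, (0.0, 0.0))
        v_pre, v_post = pre_post_velocity(event, [a, b], window=120.0)
        assert v_post == pytest.approx(v_pre / 2.0)

    def test_truncated_window_excluded(self):
        event, tracks = _scripted_event(45.0, 45.0)
        assert pre_post_velocity(event, tracks, window=1000.0) is None
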