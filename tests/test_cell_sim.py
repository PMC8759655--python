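import json
import math

import numpy as np
import pytest

import confinetrack as ct
from confinetrack.cell_sim import (
    DivisionConfig,
    OverPackedError,
    SimConfig,
    sample_lineage,
    simulate,
    simulate_rigid_particles,
)
from confinetrack.collision_model import DEFAULT_PARAMS
from confinetrack.geometry import Disk, Rectangle
from confinetrack.io import read_lineage, read_tracks
from confinetrack.track_analysis import mean_velocity


class TestSimulateBasics:
    def test_single_cell_one_hour_has_361_frames_inside_region(self):
        cfg = SimConfig(n_cells=1, duration=3600.0, seed=1)
        res = simulate(cfg)
        assert len(res.tracks) == 1
        tr = res.tracks[0]
        assert len(tr) == 361
        assert cfg.region.contains_many(tr.xy).all()

    def test_determinism_bit_identical(self):
        cfg = SimConfig(n_cells=8, duration=600.0, seed=42)
        a, b = simulate(cfg), simulate(SimConfig(n_cells=8, duration=600.0, seed=42))
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.y, tb.y)
        assert a.n_collision_episodes == b.n_collision_episodes

    def test_different_seed_differs(self):
        a = simulate(SimConfig(n_cells=2, duration=600.0, seed=1))
        b = simulate(SimConfig(n_cells=2, duration=600.0, seed=2))
        assert not np.allclose(a.tracks[0].x, b.tracks[0].x)

    def test_confinement_with_collisions_and_boundary(self):
        cfg = SimConfig(n_cells=40, duration=1800.0, seed=5)
        res = simulate(cfg)
        pts = np.vstack([t.xy for t in res.tracks])
        assert cfg.region.contains_many(pts).all()

    def test_confinement_in_rectangle(self):
        region = Rectangle((0.0, 0.0), 40.0, 40.0)
        cfg = SimConfig(region=region, n_cells=5, duration=1800.0, seed=3)
        res = simulate(cfg)
        pts = np.vstack([t.xy for t in res.tracks])
        assert region.contains_many(pts).all()

    def test_overpacked_placement_raises(self):
        with pytest.raises(OverPackedError):
            simulate(SimConfig(region=Disk((0, 0), 10.0), n_cells=50, duration=60.0))

    def test_frame_interval_must_divide_duration(self):
        with pytest.raises(ValueError):
            SimConfig(duration=3605.0)


class TestSpeedCalibration:
    def test_step_speed_recovers_speed_mean_within_2pct(self):
        # collisions off, fixed per-cell speed: boundary handling must not
        # bias the realised step speed
        cfg = SimConfig(n_cells=10, duration=14400.0, speed_sd=0.0,
                        collisions_enabled=False, seed=3)
        res = simulate(cfg)
        speeds = [mean_velocity(t) for t in res.tracks]
        assert np.mean(speeds) == pytest.approx(3.9, rel=0.02)

    def test_high_density_does_not_slow_cells(self):
        cfg = SimConfig(n_cells=250, duration=900.0, seed=7)
        res = simulate(cfg)
        speeds = [mean_velocity(t) for t in res.tracks]
        assert np.mean(speeds) == pytest.approx(3.9, rel=0.10)


class TestDivision:
    def test_deterministic_lifetime_divides_exactly_once(self):
        cfg = SimConfig(
            n_cells=1,
            duration=10.0 * 3600.0,
            frame_interval=60.0,
            collisions_enabled=False,
            division=DivisionConfig(enabled=True, doubling_mean_h=9.3,
                                    doubling_sd_h=0.0),
            seed=1,
        )
        res = simulate(cfg)
        lineage = res.lineage
        divided = [n for n in lineage.nodes.values() if n.divided]
        assert len(divided) == 1
        parent = divided[0]
        assert len(parent.child_ids) == 2
        assert parent.rounding_s < parent.abscission_s
        for cid in parent.child_ids:
            assert lineage.nodes[cid].birth_s == parent.abscission_s
        # division time is the next frame boundary after 9.3 h
        assert parent.abscission_s == pytest.approx(9.3 * 3600.0, abs=60.0)
        assert len(res.tracks) == 3

    def test_child_tracks_start_at_abscission_frame(self):
        cfg = SimConfig(
            n_cells=1, duration=6.0 * 3600.0, frame_interval=60.0,
            collisions_enabled=False,
            division=DivisionConfig(enabled=True, doubling_mean_h=4.0,
                                    doubling_sd_h=0.0),
            seed=2,
        )
        res = simulate(cfg)
        parent = next(n for n in res.lineage.nodes.values() if n.divided)
        child_tracks = [t for t in res.tracks if t.track_id in parent.child_ids]
        for tr in child_tracks:
            assert tr.t[0] == pytest.approx(parent.abscission_s)


class TestSampleLineage:
    def test_deterministic(self):
        div = DivisionConfig(enabled=True)
        a = sample_lineage(div, 4, 30.0, seed=9)
        b = sample_lineage(div, 4, 30.0, seed=9)
        assert {n.track_id: n.abscission_s for n in a.nodes.values()} == {
            n.track_id: n.abscission_s for n in b.nodes.values()
        }

    def test_structure_valid_and_binary(self):
        lineage = sample_lineage(DivisionConfig(enabled=True), 8, 40.0, seed=1)
        lineage.validate()
        for node in lineage.nodes.values():
            assert len(node.child_ids) in (0, 2)

    def test_matches_spatial_simulation_division_law(self):
        # the spatial simulator's lifetimes follow the same truncated normal
        div = DivisionConfig(enabled=True, doubling_mean_h=2.0, doubling_sd_h=0.3,
                             min_lifetime_h=0.5)
        cfg = SimConfig(n_cells=4, duration=6.0 * 3600.0, frame_interval=60.0,
                        collisions_enabled=False, division=div, seed=4)
        res = simulate(cfg)
        spatial = [
            (n.abscission_s - n.birth_s) / 3600.0
            for n in res.lineage.nodes.values()
            if n.divided
        ]
        sampled = [
            (n.abscission_s - n.birth_s) / 3600.0
            for n in sample_lineage(div, 64, 6.0, seed=4).nodes.values()
            if n.divided
        ]
        assert len(spatial) >= 8
        assert abs(np.mean(spatial) - np.mean(sampled)) < 0.3


class TestRigidParticles:
    @pytest.mark.parametrize("n", [0, 1])
    def test_lone_particles_never_collide(self, n):
        assert simulate_rigid_particles(DEFAULT_PARAMS, N=n, duration_h=0.25, seed=1) == 0

    def test_tunnelling_dt_rejected(self):
        with pytest.raises(ValueError, match="tunnel"):
            simulate_rigid_particles(DEFAULT_PARAMS, N=2, duration_h=0.1, dt_s=600.0)

    def test_overpacked_rejected(self):
        with pytest.raises(ValueError, match="over-packed"):
            simulate_rigid_particles(DEFAULT_PARAMS, N=150, duration_h=0.1)

    def test_deterministic(self):
        a = simulate_rigid_particles(DEFAULT_PARAMS, N=10, duration_h=0.5, seed=3)
        b = simulate_rigid_particles(DEFAULT_PARAMS, N=10, duration_h=0.5, seed=3)
        assert a == b

    def test_recorded_tracks_stay_in_arena(self):
        _, tracks = simulate_rigid_particles(
            DEFAULT_PARAMS, N=5, duration_h=0.25, seed=2, record_tracks=True
        )
        arena_r = math.sqrt(DEFAULT_PARAMS.A / math.pi)
        for tr in tracks:
            assert np.all(np.hypot(tr.x, tr.y) <= arena_r - DEFAULT_PARAMS.L / 2.0 + 1e-6)


class TestFixtures:
    def test_fig3_division_preset(self, tmp_path):
        ct.generate_fixture("fig3_division", tmp_path, seed=1)
        tracks = read_tracks(tmp_path / "tracks.tsv")
        lineage = read_lineage(tmp_path / "lineage.tsv")
        assert len(lineage) > 0
        disk = Disk((0.0, 0.0), 50.0)
        for tr in tracks:
            assert disk.contains_many(tr.xy).all()
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 1

    def test_lattice_preset_one_cell_per_square(self, tmp_path):
        ct.generate_fixture("lattice_single_cells", tmp_path, seed=0)
        tracks = read_tracks(tmp_path / "tracks.tsv")
        assert len(tracks) == 9
        pitch, side = 65.0, 15.0
        for i, tr in enumerate(sorted(tracks, key=lambda t: t.track_id)):
            gx, gy = i % 3, i // 3
            square = Rectangle((gx * pitch, gy * pitch), side, side)
            assert square.contains_many(tr.xy).all()

    def test_fig4_preset_produces_detectable_collisions(self, tmp_path):
        from confinetrack.track_analysis import detect_collisions

        ct.generate_fixture("fig4_collisions", tmp_path, seed=2)
        tracks = read_tracks(tmp_path / "tracks.tsv")
        radius = tracks[0].radius
        events = detect_collisions(tracks, 2.0 * radius)
        assert len(events) >= 1

    def test_unknown_preset_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown preset"):
            ct.generate_fixture("fig99", tmp_path)
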