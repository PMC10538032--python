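"""Fusion, filtering, gap interpolation, velocity and stress-label tests."""

import math

import numpy as np
import pytest

from zootrack.motion_core import ConfigurationError, Rect, RegionPolygon
from zootrack.panda_analysis import (
    FREEZING_OR_MISSING,
    RUNNING,
    STATIONARY,
    WALKING1,
    WALKING2,
    WALKING3,
    StressParams,
    TrackEntry,
    VelocityThresholds,
    classify_stress,
    compute_velocities,
    fill_gaps,
    filter_pass_compaction,
    select_view,
    smooth_attributes,
)
from zootrack.panda_tracking import (
    FREEZING,
    MOVEMENT,
    CameraConfig,
    FrameObservation,
    Zone,
)

from oracles import windowed_vote_oracle


def flat_config(camera_id, zones=None, general=False, basin=None, weight=1.0,
                resolution=(200, 150)):
    w, h = resolution
    zones = zones or [
        Zone(RegionPolygon([(0, 0), (w, 0), (w, h), (0, h)], "main"),
             "main", "full", 0)
    ]
    return CameraConfig(
        camera_id=camera_id,
        resolution=resolution,
        info_polygon=RegionPolygon([(0, 0), (w, 0), (w, h), (0, h)], "info"),
        visible_zones=zones,
        general_view=general,
        basin_zone=basin,
        velocity_weight=weight,
    )


def obs(cam, x, y, attr=MOVEMENT, tech=0, frame=0):
    return FrameObservation(frame, cam, Rect(int(x) - 10, int(y) - 10, 20, 20),
                            attr, tech, True)


def entry(i, cam=None, x=None, y=None, attr=FREEZING_OR_MISSING, v=None):
    return TrackEntry(i, cam, x, y, attr, velocity=v)


class TestSelectView:
    cfgs = {5: flat_config(5), 6: flat_config(6, general=True)}

    def test_single_candidate_selected(self):
        out = select_view({5: obs(5, 50, 50)}, None, self.cfgs, 0)
        assert out.camera_id == 5
        assert out.position == (50.0, 50.0)

    def test_tie_keeps_previous_camera(self):
        cfgs = {5: flat_config(5), 8: flat_config(8)}
        prev = entry(0, 8, 60.0, 60.0, MOVEMENT)
        out = select_view({5: obs(5, 50, 50), 8: obs(8, 60, 60)}, prev, cfgs, 1)
        assert out.camera_id == 8

    def test_technician_candidate_dropped(self):
        out = select_view({5: obs(5, 50, 50, tech=1)}, None, self.cfgs, 0)
        assert out.camera_id is None
        assert out.attribute == FREEZING_OR_MISSING

    def test_out_of_zone_candidate_dropped(self):
        zones = [Zone(RegionPolygon([(0, 0), (40, 0), (40, 40), (0, 40)], "z"),
                      "z", "full", 0)]
        cfgs = {5: flat_config(5, zones=zones)}
        out = select_view({5: obs(5, 120, 120)}, None, cfgs, 0)
        assert out.camera_id is None

    def test_larger_rectangle_preferred_at_equal_rank(self):
        cfgs = {5: flat_config(5), 8: flat_config(8)}
        small = FrameObservation(0, 8, Rect(55, 55, 6, 6), MOVEMENT, 0, True)
        out = select_view({5: obs(5, 50, 50), 8: small}, None, cfgs, 0)
        assert out.camera_id == 5


class TestFuseViews:
    def test_length_is_minimum_stream_length(self):
        from zootrack.panda_analysis import fuse_views

        cfgs = {5: flat_config(5), 6: flat_config(6)}
        per_cam = {
            5: [obs(5, 50, 50, frame=i) for i in range(500)],
            6: [obs(6, 50, 50, frame=i) for i in range(520)],
        }
        fused = fuse_views(per_cam, cfgs)
        assert len(fused) == 500


class TestCompaction:
    cfgs = {1: flat_config(1), 2: flat_config(2)}

    def run_entries(self, pattern):
        """pattern: list of (camera, length); positions = frame index."""
        out = []
        i = 0
        for cam, ln in pattern:
            for _ in range(ln):
                if cam is None:
                    out.append(entry(i))
                else:
                    out.append(entry(i, cam, float(i), 0.0, MOVEMENT))
                i += 1
        return out

    def test_short_interleaved_run_substituted(self):
        entries = self.run_entries([(1, 60), (2, 5), (1, 60)])
        tracks = {1: [obs(1, i, 0, frame=i) for i in range(125)]}
        out = filter_pass_compaction(entries, tracks, self.cfgs)
        assert all(e.camera_id == 1 for e in out)
        # substituted frames take camera 1's own per-camera positions
        assert out[62].x == pytest.approx(62.0)

    def test_long_interleaved_run_untouched(self):
        entries = self.run_entries([(1, 60), (2, 200), (1, 60)])
        out = filter_pass_compaction(entries, None, self.cfgs)
        assert [e.camera_id for e in out] == [e.camera_id for e in entries]

    def test_single_camera_identity(self):
        entries = self.run_entries([(1, 150)])
        out = filter_pass_compaction(entries, None, self.cfgs)
        assert [e.camera_id for e in out] == [1] * 150


class TestFillGaps:
    def test_linear_interpolation_closed_form(self):
        entries = [entry(i) for i in range(20)]
        entries[10] = entry(10, 5, 0.0, 0.0, MOVEMENT)
        entries[14] = entry(14, 5, 8.0, 8.0, MOVEMENT)
        out = fill_gaps(entries)
        for k in range(1, 4):
            assert out[10 + k].x == pytest.approx(2.0 * k)
            assert out[10 + k].y == pytest.approx(2.0 * k)
            assert out[10 + k].camera_id == 5
            assert out[10 + k].attribute == MOVEMENT

    @pytest.mark.parametrize("gap", [2, 50, 100])
    def test_gap_lengths_inside_range_filled(self, gap):
        entries = [entry(i) for i in range(gap + 2)]
        entries[0] = entry(0, 5, 0.0, 0.0, MOVEMENT)
        entries[gap] = entry(gap, 5, float(gap), 0.0, MOVEMENT)
        out = fill_gaps(entries)
        for k in range(1, gap):
            assert out[k].x == pytest.approx(float(k))

    def test_gap_of_101_untouched(self):
        entries = [entry(i) for i in range(102)]
        entries[0] = entry(0, 5, 0.0, 0.0, MOVEMENT)
        entries[101] = entry(101, 5, 101.0, 0.0, MOVEMENT)
        out = fill_gaps(entries)
        assert all(out[k].camera_id is None for k in range(1, 101))

    def test_cross_camera_gap_untouched(self):
        entries = [entry(i) for i in range(6)]
        entries[0] = entry(0, 5, 0.0, 0.0, MOVEMENT)
        entries[5] = entry(5, 6, 5.0, 0.0, MOVEMENT)
        out = fill_gaps(entries)
        assert all(out[k].camera_id is None for k in range(1, 5))

    def test_freezing_bounds_give_freezing_fill(self):
        entries = [entry(i) for i in range(5)]
        entries[0] = entry(0, 5, 0.0, 0.0, FREEZING)
        entries[4] = entry(4, 5, 4.0, 0.0, FREEZING)
        out = fill_gaps(entries)
        assert all(out[k].attribute == FREEZING for k in range(1, 4))

    def test_idempotent(self):
        entries = [entry(i) for i in range(20)]
        entries[3] = entry(3, 5, 0.0, 0.0, MOVEMENT)
        entries[9] = entry(9, 5, 6.0, 6.0, MOVEMENT)
        once = fill_gaps(entries)
        twice = fill_gaps(once)
        for a, b in zip(once, twice):
            assert (a.x, a.y, a.camera_id, a.attribute) == (
                b.x, b.y, b.camera_id, b.attribute)


class TestSmoothAttributes:
    def test_uniform_unchanged(self):
        entries = [entry(i, 5, 0.0, 0.0, MOVEMENT) for i in range(10)]
        out = smooth_attributes(entries, 5)
        assert all(e.attribute == MOVEMENT for e in out)

    def test_single_outlier_voted_out(self):
        entries = [entry(i, 5, 0.0, 0.0, MOVEMENT) for i in range(11)]
        entries[5].attribute = FREEZING
        out = smooth_attributes(entries, 5)
        assert out[5].attribute == MOVEMENT

    def test_tie_keeps_current(self):
        # window 5 at index 2: votes movement 2, freezing 2, no_information 1
        # → a 2-2 tie that the current (freezing) attribute must survive
        entries = [entry(0, 5, 0.0, 0.0, MOVEMENT),
                   entry(1, 5, 0.0, 0.0, MOVEMENT),
                   entry(2, 5, 0.0, 0.0, FREEZING),
                   entry(3, 5, 0.0, 0.0, FREEZING),
                   entry(4, 5, 0.0, 0.0, "no_information")]
        out = smooth_attributes(entries, 5)
        assert out[2].attribute == FREEZING

    def test_matches_vote_oracle(self):
        rng = np.random.default_rng(5)
        labels = rng.choice([MOVEMENT, FREEZING, "no_information"], size=500)
        entries = [entry(i, 5, 0.0, 0.0, str(lab)) for i, lab in enumerate(labels)]
        out = smooth_attributes(entries, 7)
        want = windowed_vote_oracle([str(l) for l in labels], 7)
        assert [e.attribute for e in out] == want

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            smooth_attributes([], 4)


class TestVelocities:
    cfgs = {5: flat_config(5), 6: flat_config(6, weight=0.5)}

    def test_closed_form_displacement(self):
        entries = [entry(0, 5, 0.0, 0.0, MOVEMENT),
                   entry(1, 5, 3.0, 4.0, MOVEMENT)]
        out = compute_velocities(entries, self.cfgs, window=1)
        assert out[1].velocity == pytest.approx(5.0)

    def test_static_zero(self):
        entries = [entry(i, 5, 7.0, 7.0, FREEZING) for i in range(5)]
        out = compute_velocities(entries, self.cfgs, window=1)
        assert all(v.velocity == 0.0 for v in out[1:])

    def test_camera_switch_missing(self):
        entries = [entry(0, 5, 0.0, 0.0, MOVEMENT),
                   entry(1, 6, 30.0, 40.0, MOVEMENT)]
        out = compute_velocities(entries, self.cfgs, window=1)
        assert out[1].velocity is None

    def test_camera_weight_applied(self):
        entries = [entry(0, 6, 0.0, 0.0, MOVEMENT),
                   entry(1, 6, 3.0, 4.0, MOVEMENT)]
        out = compute_velocities(entries, self.cfgs, window=1)
        assert out[1].velocity == pytest.approx(2.5)

    def test_windowed_average_matches_direct_mean(self):
        rng = np.random.default_rng(3)
        xs = np.cumsum(rng.uniform(-2, 2, 50))
        ys = np.cumsum(rng.uniform(-2, 2, 50))
        entries = [entry(i, 5, float(xs[i]), float(ys[i]), MOVEMENT)
                   for i in range(50)]
        out = compute_velocities(entries, self.cfgs, window=5)
        raw = [None] + [
            math.dist((xs[i], ys[i]), (xs[i + 1], ys[i + 1])) for i in range(49)
        ]
        for i in range(50):
            vals = [raw[j] for j in range(max(0, i - 2), min(50, i + 3))
                    if raw[j] is not None]
            assert out[i].velocity == pytest.approx(float(np.mean(vals)))


class TestClassifyStress:
    def make_cfgs(self):
        zones = [
            Zone(RegionPolygon([(0, 0), (60, 0), (60, 60), (0, 60)], "housing"),
                 "housing", "housing", 1),
            Zone(RegionPolygon([(0, 0), (200, 0), (200, 150), (0, 150)], "main"),
                 "main", "full", 0),
        ]
        return {
            5: flat_config(5, zones=zones),
            8: flat_config(8, zones=zones, basin=Rect(150, 100, 40, 40)),
        }

    def test_invalid_thresholds(self):
        with pytest.raises(ConfigurationError):
            VelocityThresholds(1.0, 2.0, 3.0)

    def test_running_by_velocity(self):
        cfgs = self.make_cfgs()
        entries = [entry(i, 5, 100.0 + 12 * i, 100.0, MOVEMENT, v=12.0)
                   for i in range(20)]
        out, eps = classify_stress(entries, VelocityThresholds(9, 4, 1.5), cfgs, 10)
        assert all(e.stress == RUNNING for e in out)
        assert len(eps) == 1 and eps[0].stress_class == RUNNING

    def test_low_velocity_away_from_basin_unlabeled(self):
        cfgs = self.make_cfgs()
        entries = [entry(i, 5, 100.0, 100.0, FREEZING, v=0.5) for i in range(20)]
        out, eps = classify_stress(entries, VelocityThresholds(9, 4, 1.5), cfgs, 10)
        assert all(e.stress is None for e in out)
        assert eps == []

    def walk_after_still(self, still_pos, walk_v):
        """30 still frames at still_pos then 40 moving frames at walk_v."""
        entries = [entry(i, 5, still_pos[0], still_pos[1], FREEZING, v=0.0)
                   for i in range(30)]
        x = still_pos[0]
        for i in range(30, 70):
            x += walk_v
            entries.append(entry(i, 5, x, still_pos[1] + (30 if i == 50 else 0),
                                 MOVEMENT, v=walk_v))
        return entries

    def test_walking1_after_full_zone_rest(self):
        cfgs = self.make_cfgs()
        entries = self.walk_after_still((100.0, 100.0), 5.0)  # rest in "main"
        out, _ = classify_stress(entries, VelocityThresholds(9, 4, 1.5), cfgs, 10)
        assert {e.stress for e in out[30:]} == {WALKING1}

    def test_walking2_after_housing_still(self):
        cfgs = self.make_cfgs()
        entries = self.walk_after_still((30.0, 30.0), 5.0)  # still in housing
        out, _ = classify_stress(entries, VelocityThresholds(9, 4, 1.5), cfgs, 10)
        assert {e.stress for e in out[30:]} == {WALKING2}

    def test_walking3_needs_housing_and_height(self):
        cfgs = self.make_cfgs()
        entries = self.walk_after_still((30.0, 30.0), 2.5)  # slow, one height
        out, _ = classify_stress(entries, VelocityThresholds(9, 4, 1.5), cfgs, 10)
        assert WALKING3 in {e.stress for e in out[30:]}

    def test_walking3_without_height_unlabeled(self):
        cfgs = self.make_cfgs()
        entries = [entry(i, 5, 30.0, 30.0, FREEZING, v=0.0) for i in range(30)]
        x = 30.0
        for i in range(30, 70):
            x += 2.5
            entries.append(entry(i, 5, x, 30.0, MOVEMENT, v=2.5))  # dead straight
        out, _ = classify_stress(entries, VelocityThresholds(9, 4, 1.5), cfgs, 10)
        assert all(e.stress is None for e in out[30:])

    def test_stationary_requires_duration_and_camera8(self):
        cfgs = self.make_cfgs()
        thr = VelocityThresholds(9, 4, 1.5)
        basin_pos = (170.0, 120.0)
        long_dwell = [entry(i, 8, *basin_pos, MOVEMENT, v=0.5) for i in range(70)]
        out, eps = classify_stress(long_dwell, thr, cfgs, 10)
        assert eps and eps[0].stress_class == STATIONARY
        short_dwell = [entry(i, 8, *basin_pos, MOVEMENT, v=0.5) for i in range(30)]
        _, eps2 = classify_stress(short_dwell, thr, cfgs, 10)
        assert all(e.stress_class != STATIONARY for e in eps2)
        cam5_dwell = [entry(i, 5, *basin_pos, MOVEMENT, v=0.5) for i in range(70)]
        _, eps3 = classify_stress(cam5_dwell, thr, cfgs, 10)
        assert all(e.stress_class != STATIONARY for e in eps3)

    def test_scale_invariance_of_labels(self):
        """Uniformly rescaling coordinates and thresholds preserves labels."""
        cfgs = self.make_cfgs()
        thr = VelocityThresholds(9, 4, 1.5)
        entries = self.walk_after_still((30.0, 30.0), 5.0)
        out1, _ = classify_stress(entries, thr, cfgs, 10)
        k = 2.0
        zones2 = [
            Zone(RegionPolygon([(0, 0), (120, 0), (120, 120), (0, 120)], "housing"),
                 "housing", "housing", 1),
            Zone(RegionPolygon([(0, 0), (400, 0), (400, 300), (0, 300)], "main"),
                 "main", "full", 0),
        ]
        cfgs2 = {5: flat_config(5, zones=zones2, resolution=(400, 300)),
                 8: flat_config(8, zones=zones2, basin=Rect(300, 200, 80, 80),
                                resolution=(400, 300))}
        scaled = [
            TrackEntry(e.frame_index, e.camera_id,
                       None if e.x is None else e.x * k,
                       None if e.y is None else e.y * k,
                       e.attribute, velocity=None if e.velocity is None else e.velocity * k)
            for e in entries
        ]
        thr2 = VelocityThresholds(9 * k, 4 * k, 1.5 * k)
        params2 = StressParams(height_dist=20.0 * k, basin_margin=10.0 * k)
        out2, _ = classify_stress(scaled, thr2, cfgs2, 10, params2)
        assert [e.stress for e in out1] == [e.stress for e in out2]
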