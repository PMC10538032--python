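"""Rat pipeline tests: scene walls, blob/head detection, visits."""

import numpy as np
import pytest

from zootrack.motion_core import ConfigurationError, GrayFrame
from zootrack.rat_behavior import (
    CageParams,
    HeadDecision,
    UnresolvedSessionError,
    analyze_visits,
    compute_cage_params,
    compute_scene_walls,
    detect_rat_blob,
    locate_head,
    resolve_trajectory,
    run_stage1,
)
from zootrack.synthetic_scenes import (
    RAT2_GEOM,
    Scenario,
    make_rat1_script,
    make_rat2_script,
    render_rat_scene,
)


def five_band_frame(extra_occluder=False):
    """Bright frame with five dark column bands at known positions."""
    img = np.full((240, 320), 200.0)
    bands = [(4, 10), (100, 108), (150, 170), (210, 218), (309, 315)]
    for s, e in bands:
        img[:, s : e + 1] = 30.0
    if extra_occluder:
        img[:, 100:170] = 200.0  # wipe bands 2-3: only four clusters remain
    return img, bands


class TestSceneWalls:
    def test_five_band_midpoints(self):
        img, bands = five_band_frame()
        walls = compute_scene_walls(img)
        assert walls is not None
        assert walls.b1 == (bands[1][0] + bands[1][1]) // 2
        assert walls.b2 == (bands[3][0] + bands[3][1]) // 2

    def test_uniform_frame_gives_none(self):
        assert compute_scene_walls(np.full((240, 320), 200.0)) is None

    def test_four_band_frame_gives_none(self):
        img, _ = five_band_frame(extra_occluder=True)
        assert compute_scene_walls(img) is None

    def test_ordering_invariant_on_accepted_frames(self):
        img, _ = five_band_frame()
        walls = compute_scene_walls(img)
        flat = [v for se in walls.cluster_bounds for v in se]
        assert flat == sorted(flat)
        assert walls.b1 < walls.b2


class TestRatBlob:
    def synthetic_frame(self, rx=30, ry=10):
        img, bands = five_band_frame()
        img[:, 150:171] = 200.0  # clear the middle band, use a rat instead
        ys, xs = np.mgrid[0:240, 0:320]
        inside = ((xs - 160) / rx) ** 2 + ((ys - 120) / ry) ** 2 <= 1
        img[inside] = 45.0
        return img

    def test_horizontal_ellipse(self):
        img = self.synthetic_frame(rx=30, ry=10)
        walls = compute_scene_walls(img)
        body = detect_rat_blob(img, walls)
        assert body is not None
        assert body.aspect == "horizontal"
        assert abs(body.box.x - 130) <= 3 and abs(body.box.x + body.box.w - 190) <= 3

    def test_empty_middle_room_gives_none(self):
        img, bands = five_band_frame()
        walls = compute_scene_walls(img)
        assert walls is not None  # the middle band acts as the "rat" cluster
        img[:, 150:171] = 200.0  # remove it: empty room
        assert detect_rat_blob(img, walls) is None

    def test_near_circular_blob_square_aspect(self):
        img = self.synthetic_frame(rx=11, ry=10)
        walls = compute_scene_walls(img)
        body = detect_rat_blob(img, walls)
        assert body.aspect == "square"


class TestLocateHead:
    def make_body_frame(self, head_side="left", tail=True, taper=True):
        """Horizontal dark body in a bright frame with optional taper/tail."""
        img = np.full((100, 200), 200.0)
        ys, xs = np.mgrid[0:100, 0:200]
        rx, ry = 25, 10
        t = (xs - 100 + rx) / (2 * rx)
        if taper:
            f = 1.0 - 0.45 * (t if head_side == "right" else 1 - t)
        else:
            f = np.ones_like(t, dtype=float)
        inside = ((xs - 100) / rx) ** 2 + ((ys - 50) / np.maximum(10 * f, 1e-6)) ** 2 <= 1
        img[inside] = 40.0
        if tail:
            if head_side == "left":
                img[49:51, 125:145] = 40.0
            else:
                img[49:51, 55:75] = 40.0
        return img

    def body_of(self, img):
        from zootrack.rat_behavior import BodyBox
        from zootrack.motion_core import Rect
        ys, xs = np.nonzero(img < 100)
        # bounding box of the main mass without the tail line
        from scipy import ndimage
        lab, n = ndimage.label(ndimage.binary_erosion(img < 100, np.ones((3, 3))))
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        ys, xs = np.nonzero(lab == best)
        box = Rect(int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1),
                   int(ys.max() - ys.min() + 1))
        return BodyBox(box=box, aspect="horizontal",
                       mass_center=(float(xs.mean()), float(ys.mean())))

    def test_taper_and_tail_agree(self):
        img = self.make_body_frame("left", tail=True, taper=True)
        body = self.body_of(img)
        d = locate_head(GrayFrame(img), body, [], bin_thr=100.0)
        assert d.status == "certain"
        assert d.candidates[0][0] < body.mass_center[0]

    def test_tail_only_decides_when_projections_symmetric(self):
        img = self.make_body_frame("left", tail=True, taper=False)
        body = self.body_of(img)
        d = locate_head(GrayFrame(img), body, [], bin_thr=100.0)
        assert d.status == "certain"
        assert d.candidates[0][0] < body.mass_center[0]

    def test_contradiction_resolved_by_tail_method(self):
        """Taper says right, tail strip also on the right: tail vote wins."""
        img = self.make_body_frame("right", tail=False, taper=True)
        img[49:51, 130:150] = 40.0  # tail on the right ⇒ head left per vote 2
        body = self.body_of(img)
        d = locate_head(GrayFrame(img), body, [], bin_thr=100.0)
        assert d.status == "certain"
        assert d.candidates[0][0] < body.mass_center[0]

    def test_no_information_defers(self):
        img = self.make_body_frame("left", tail=False, taper=False)
        body = self.body_of(img)
        d = locate_head(GrayFrame(img), body, [], bin_thr=100.0)
        assert d.status == "deferred"


class TestResolveTrajectory:
    def test_ambiguous_resolved_by_next_certain(self):
        dec = [
            HeadDecision(0, [(10.0, 5.0)], "certain"),
            HeadDecision(1, [(11.0, 5.0), (40.0, 5.0)], "ambiguous"),
            HeadDecision(2, [(12.0, 5.0)], "certain"),
        ]
        out = resolve_trajectory(dec)
        assert out[1][1] == (11.0, 5.0)

    def test_ambiguous_run_resolved_toward_wall(self):
        dec = [HeadDecision(i, [(5.0 + i, 50.0), (90.0 - i, 50.0)], "ambiguous")
               for i in range(3)]
        dec.append(HeadDecision(3, [(2.0, 50.0)], "certain"))
        out = resolve_trajectory(dec)
        for i in range(3):
            assert out[i][1][0] < 20  # candidate nearest the left-wall position

    def test_all_certain_identity(self):
        dec = [HeadDecision(i, [(float(i), 0.0)], "certain") for i in range(4)]
        out = resolve_trajectory(dec)
        assert out == [(i, (float(i), 0.0)) for i in range(4)]

    def test_deferred_interpolated(self):
        dec = [
            HeadDecision(0, [(0.0, 0.0)], "certain"),
            HeadDecision(1, [], "deferred"),
            HeadDecision(2, [(10.0, 0.0)], "certain"),
        ]
        out = resolve_trajectory(dec)
        assert out[1][1] == (5.0, 0.0)

    def test_no_certain_raises(self):
        with pytest.raises(UnresolvedSessionError):
            resolve_trajectory([HeadDecision(0, [], "deferred")])


class TestCageParams:
    def test_synthetic_side_view(self):
        s = Scenario("rat2", 15, 1, seed=0,
                     script=make_rat2_script([("middle", 1.0)], fps=15))
        frames, _ = render_rat_scene(s)
        p = compute_cage_params(frames[0])
        assert p is not None
        assert abs(p.b1 - RAT2_GEOM["b1"]) <= 2 and abs(p.b2 - RAT2_GEOM["b2"]) <= 2
        assert abs(p.c11 - RAT2_GEOM["left_cage"][0]) <= 2
        assert abs(p.c22 - RAT2_GEOM["right_cage"][1]) <= 2

    def test_occluded_left_cage_gives_none(self):
        s = Scenario("rat2", 15, 1, seed=0,
                     script=make_rat2_script([("middle", 1.0)], fps=15))
        frames, _ = render_rat_scene(s)
        img = np.array(frames[0].pixels)
        c = RAT2_GEOM["left_cage"]
        img[:, c[0] : c[1] + 1] = RAT2_GEOM["floor"]
        assert compute_cage_params(img) is None

    def test_ordering_violation_rejected(self):
        with pytest.raises(ConfigurationError):
            CageParams(c11=10, c12=120, c21=260, c22=310, b1=111, b2=211)


class TestAnalyzeVisits:
    params = CageParams(c11=10, c12=60, c21=260, c22=310, b1=111, b2=211)

    def test_track_entirely_in_middle(self):
        track = [(i, (160.0, 50.0)) for i in range(100)]
        visits, entries = analyze_visits(track, self.params, fps=25)
        assert len(visits) == 1 and visits[0].compartment == "middle"
        assert entries == {"left_cage": 0, "middle": 0, "right_cage": 0}

    def test_scripted_left_visit_duration(self):
        track = (
            [(i, (160.0, 50.0)) for i in range(50)]
            + [(50 + i, (80.0, 50.0)) for i in range(100)]
            + [(150 + i, (160.0, 50.0)) for i in range(50)]
        )
        visits, entries = analyze_visits(track, self.params, fps=25)
        assert entries["left_cage"] == 1
        left = [v for v in visits if v.compartment == "left_cage"][0]
        assert left.duration_s == pytest.approx(4.0)

    def test_jitter_debounced(self):
        track = [(i, (120.0, 50.0)) for i in range(20)]
        track += [(20, (105.0, 50.0)), (21, (105.0, 50.0))]  # 2-frame excursion
        track += [(22 + i, (120.0, 50.0)) for i in range(20)]
        visits, entries = analyze_visits(track, self.params, fps=25, debounce=5)
        assert entries["left_cage"] == 0
        assert len(visits) == 1

    def test_empty_track(self):
        visits, entries = analyze_visits([], self.params, fps=25)
        assert visits == [] and sum(entries.values()) == 0


class TestStage1EndToEnd:
    def test_determinism(self):
        script = make_rat1_script(fps=15, duration_s=3, n_turns=1)
        s = Scenario("rat1", 15, 3, seed=9, script=script)
        f1, _ = render_rat_scene(s)
        f2, _ = render_rat_scene(s)
        np.testing.assert_array_equal(f1[10].pixels, f2[10].pixels)

    def test_static_script_constant_frames(self):
        script = {"frames": [{"x": 160.0, "y": 120.0, "heading": "right",
                              "square": False}] * 5, "noise_sigma": 0.0}
        s = Scenario("rat1", 15, 1, seed=0, script=script)
        frames, _ = render_rat_scene(s)
        np.testing.assert_array_equal(frames[0].pixels, frames[4].pixels)

    def test_head_side_accuracy_short_run(self):
        script = make_rat1_script(fps=15, duration_s=20, n_turns=4)
        s = Scenario("rat1", 15, 20, seed=2, script=script)
        frames, gt = render_rat_scene(s)
        decisions, bodies = run_stage1(frames)
        resolved = resolve_trajectory(decisions)
        err = n = 0
        for (fi, (hx, _)), g, b in zip(resolved, gt.frames, bodies):
            if b is None:
                continue
            n += 1
            pred = "right" if hx > b.mass_center[0] else "left"
            err += pred != g["head_side"]
        assert n > 0 and err / n <= 0.05
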