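"""End-to-end evaluation of the pipelines against synthetic ground truth.

Each function renders a scripted scenario, runs the corresponding pipeline
and scores the result against the generator's ground truth. These are the
package's own benchmarks: they quantify entry-count and visit-duration
accuracy (rat), position recovery and the confidence gate (monkey), and
per-frame stress-label agreement plus episode recovery (panda).
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from zootrack.motion_core import RegionPolygon
from zootrack.synthetic_scenes import (
    MONKEY_GEOM,
    Scenario,
    make_monkey_script,
    make_panda_script,
    make_rat1_script,
    make_rat2_script,
    render_monkey_scene,
    render_panda_scene,
    render_rat_scene,
)

__all__ = [
    "evaluate_rat_head",
    "evaluate_rat_visits",
    "DEFAULT_VISIT_SCRIPTS",
    "example_quadrant_regions",
    "evaluate_monkey_tracking",
    "evaluate_orientation_sweep",
    "evaluate_panda_scenario",
]


# ---------------------------------------------------------------------------
# Rat stage 1: head-side accuracy and the offline resolution pass
# ---------------------------------------------------------------------------

def evaluate_rat_head(
    seed: int,
    duration_s: float = 60.0,
    fps: float = 15.0,
    n_turns: int = 5,
) -> Dict[str, float]:
    """Head-side accuracy before and after the offline resolution pass."""
    from zootrack.rat_behavior import resolve_trajectory, run_stage1

    script = make_rat1_script(fps=fps, duration_s=duration_s, n_turns=n_turns)
    scen = Scenario("rat1", fps, duration_s, seed=seed, script=script)
    frames, gt = render_rat_scene(scen)
    decisions, bodies = run_stage1(frames)
    resolved = resolve_trajectory(decisions)

    def side(hx: float, cx: float) -> str:
        return "right" if hx > cx else "left"

    post_err = pre_err = n = 0
    prev_certain: Optional[Tuple[float, float]] = None
    for (fi, (hx, _)), d, g, b in zip(resolved, decisions, gt.frames, bodies):
        if b is None:
            continue
        n += 1
        if side(hx, b.mass_center[0]) != g["head_side"]:
            post_err += 1
        # pre-resolution prediction: first candidate, or carry the last certain
        if d.status in ("certain", "ambiguous"):
            p = d.candidates[0]
        elif prev_certain is not None:
            p = prev_certain
        else:
            p = (b.mass_center[0], b.mass_center[1])
        if side(p[0], b.mass_center[0]) != g["head_side"]:
            pre_err += 1
        if d.status == "certain":
            prev_certain = d.candidates[0]
    return {
        "n_frames": n,
        "n_turns": n_turns,
        "accuracy_pct": 100.0 * (1 - post_err / max(1, n)),
        "pre_resolution_errors": pre_err,
        "post_resolution_errors": post_err,
    }


# ---------------------------------------------------------------------------
# Rat stage 2: entry counts and visit durations
# ---------------------------------------------------------------------------

DEFAULT_VISIT_SCRIPTS: List[List[Tuple[str, float]]] = [
    [("middle", 10), ("left_cage", 65), ("middle", 8), ("right_cage", 20), ("middle", 10)],
    [("middle", 5), ("right_cage", 70), ("middle", 15), ("left_cage", 15), ("middle", 8)],
    [("middle", 12), ("left_cage", 30), ("right_cage", 62), ("middle", 9)],
    [("middle", 6), ("right_cage", 25), ("middle", 65), ("left_cage", 12)],
    [("middle", 10), ("left_cage", 20), ("middle", 10), ("right_cage", 66), ("middle", 6)],
]


def _gt_visits(compartments: Sequence[str], fps: float):
    """Maximal runs of the scripted per-frame compartment."""
    runs = []
    start = 0
    for i in range(1, len(compartments) + 1):
        if i == len(compartments) or compartments[i] != compartments[start]:
            runs.append((compartments[start], start, i - 1, (i - start) / fps))
            start = i
    return runs


def evaluate_rat_visits(
    seed: int,
    visits: Optional[Sequence[Tuple[str, float]]] = None,
    fps: float = 15.0,
) -> Dict[str, object]:
    """Entry-count exactness and long-visit duration errors on one fixture."""
    from zootrack.rat_behavior import analyze_visits, track_stage2

    visits = list(visits or DEFAULT_VISIT_SCRIPTS[0])
    script = make_rat2_script(visits, fps=fps)
    scen = Scenario("rat2", fps, len(script["frames"]) / fps, seed=seed,
                    script=script)
    frames, gt = render_rat_scene(scen)
    track, params = track_stage2(frames)
    got_visits, got_entries = analyze_visits(track, params, fps)

    comps = gt.column("compartment")
    gt_entries = {"left_cage": 0, "middle": 0, "right_cage": 0}
    for a, b in zip(comps, comps[1:]):
        if a != b:
            gt_entries[b] += 1
    entry_errors = sum(
        abs(got_entries[k] - gt_entries[k]) for k in gt_entries
    )

    long_visit_errors: List[float] = []
    for comp, s, e, dur in _gt_visits(comps, fps):
        if dur <= 60.0:
            continue
        best = None
        for v in got_visits:
            if v.compartment != comp:
                continue
            overlap = min(e, v.end_frame) - max(s, v.start_frame)
            if overlap > 0 and (best is None or overlap > best[0]):
                best = (overlap, v)
        err = abs(best[1].duration_s - dur) if best else dur
        long_visit_errors.append(err)
    return {
        "n_frames": len(frames),
        "entry_errors": entry_errors,
        "gt_entries": gt_entries,
        "got_entries": got_entries,
        "long_visit_duration_errors_s": long_visit_errors,
    }


# ---------------------------------------------------------------------------
# Monkey: position recovery, confidence gate
# ---------------------------------------------------------------------------

def example_quadrant_regions():
    """Example four-region reliability map (quadrants of the 320x240 cage)."""
    from zootrack.monkey_behavior import RegionReliability

    return RegionReliability(
        polygons=[
            RegionPolygon([(0, 0), (160, 0), (160, 120), (0, 120)], "nw"),
            RegionPolygon([(160, 0), (320, 0), (320, 120), (160, 120)], "ne"),
            RegionPolygon([(0, 120), (160, 120), (160, 240), (0, 240)], "sw"),
            RegionPolygon([(160, 120), (320, 120), (320, 240), (160, 240)], "se"),
        ],
        weights=[0.85, 0.8, 1.0, 0.95],
    )


def evaluate_monkey_tracking(
    seed: int,
    duration_s: float = 40.0,
    fps: float = 15.0,
    tol_px: float = 5.0,
) -> Dict[str, object]:
    """Scripted monkey fixture: light-off intervals, pauses, external burst."""
    from zootrack.monkey_behavior import (
        MonkeyTracker,
        OrientationRecord,
        compute_orientation,
    )

    script = make_monkey_script(
        fps=fps, duration_s=duration_s,
        light_off=[(duration_s * 0.25, duration_s * 0.35),
                   (duration_s * 0.62, duration_s * 0.72)],
        pauses=[(duration_s * 0.15, duration_s * 0.2),
                (duration_s * 0.5, duration_s * 0.55)],
        burst=(duration_s * 0.8, duration_s * 0.87),
    )
    scen = Scenario("monkey", fps, duration_s, seed=seed, script=script)
    frames, gt = render_monkey_scene(scen)
    tracker = MonkeyTracker(MONKEY_GEOM["info_polygon"], example_quadrant_regions())
    recovered = n = 0
    gate_violations = 0
    gated_out = 0
    series: List[OrientationRecord] = []
    for f, g in zip(frames, gt.frames):
        loc = tracker.step(f)
        if f.frame_index >= 2:
            n += 1
            if loc is not None and math.dist(loc.position, (g["x"], g["y"])) <= tol_px:
                recovered += 1
        if loc is None:
            continue
        if loc.useful:
            if loc.confidence <= 75.0:
                gate_violations += 1
            series.append(
                OrientationRecord(f.frame_index,
                                  compute_orientation(f.pixels, loc),
                                  loc.confidence)
            )
        else:
            gated_out += 1
    return {
        "n_frames": n,
        "recovery_pct": 100.0 * recovered / max(1, n),
        "gate_violations": gate_violations,
        "gated_out": gated_out,
        "series_len": len(series),
        "series_min_confidence": min((r.confidence for r in series), default=None),
    }


def evaluate_orientation_sweep(
    angles: Sequence[int] = tuple(range(0, 180, 15)),
    sizes: Sequence[Tuple[int, int]] = ((80, 20), (60, 24), (100, 30)),
) -> Dict[str, object]:
    """Angle recovery for rendered rectangles over an angle/size sweep."""
    from zootrack.monkey_behavior import Localization, compute_orientation
    from zootrack.synthetic_scenes import _draw_rot_rect

    max_err = 0.0
    n = 0
    for length, width in sizes:
        for ang in angles:
            img = np.full((220, 220), 160.0)
            _draw_rot_rect(img, 110, 110, length, width, ang, 15.0)
            got = compute_orientation(img, Localization((110, 110), 100.0, 0))
            if got is None:
                return {"max_error_deg": 180.0, "n": n, "failed_at": (length, width, ang)}
            err = min(abs(got - ang), 180.0 - abs(got - ang))
            max_err = max(max_err, err)
            n += 1
    # a sub-minimum contour must be rejected
    img = np.full((220, 220), 160.0)
    _draw_rot_rect(img, 110, 110, 30, 15, 30, 15.0)  # 450 px < 500
    small = compute_orientation(img, Localization((110, 110), 100.0, 0))
    return {"max_error_deg": max_err, "n": n, "small_contour_rejected": small is None}


# ---------------------------------------------------------------------------
# Panda: the scripted four-camera scenario
# ---------------------------------------------------------------------------

EXPECTED_EPISODES = ["walking2", "walking1", "running", "walking3", "stationary"]


def evaluate_panda_scenario(
    seed: int,
    fps: float = 10.0,
    duration_s: float = 120.0,
) -> Dict[str, object]:
    """Full four-camera run scored against the scripted stress timeline."""
    from zootrack.panda_analysis import run_panda_pipeline

    script = make_panda_script(fps=fps, duration_s=duration_s)
    scen = Scenario("panda", fps, duration_s, seed=seed, script=script)
    streams, cfgs, gt = render_panda_scene(scen)
    res = run_panda_pipeline(streams, cfgs, fps=fps)
    traj = res["trajectory"]
    agree = sum(e.stress == g["stress"] for e, g in zip(traj, gt.frames))
    tech_leaks = sum(
        traj[i].camera_id is not None
        for i, g in enumerate(gt.frames)
        if g["technician"]
    )
    return {
        "n_frames": len(traj),
        "agreement_pct": 100.0 * agree / len(traj),
        "episode_classes": [ep.stress_class for ep in res["episodes"]],
        "expected_episode_classes": list(EXPECTED_EPISODES),
        "technician_leak_frames": tech_leaks,
        "fused_length": len(res["fused"]),
        "min_stream_length": min(len(v) for v in streams.values()),
        "episodes": res["episodes"],
    }
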