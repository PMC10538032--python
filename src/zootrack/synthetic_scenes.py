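"""Seeded synthetic scene generators with ground truth.

Each generator renders a scripted video emulating one of the experimental
environments and returns both the frames and per-frame ground truth, so the
pipelines can be validated end to end without proprietary recordings:

* ``rat1`` — top view of the three-chamber box: bright floor, dark wall bands,
  a dark rat ellipse with a tapered head end and a thin tail, scripted walks
  and turn-arounds in the middle room;
* ``rat2`` — side view with two dark cage blocks and two thin door walls, the
  free rat performing scripted compartment visits;
* ``monkey`` — unevenly lit cage, a dark rotated sensor-box rectangle on a
  scripted path with light-off intervals and external motion bursts;
* ``panda`` — four synchronized affine views of one scripted 2-D habitat path
  with gates, refuges, a technician visit, bird blobs and basin ripples.

All generators are bit-deterministic given (script, seed); rendered positions
match the scripted ground truth to the pixel raster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from zootrack.motion_core import GrayFrame, Rect, RegionPolygon

__all__ = [
    "Scenario",
    "GroundTruth",
    "render_rat_scene",
    "render_monkey_scene",
    "render_panda_scene",
    "make_rat1_script",
    "make_rat2_script",
    "make_monkey_script",
    "make_panda_script",
]


@dataclass
class Scenario:
    """A scripted synthetic recording: app id, timing, seed and event script."""

    app: str  # rat1 | rat2 | monkey | panda
    fps: float
    duration_s: float
    seed: int = 0
    script: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass
class GroundTruth:
    """Per-frame true state, aligned 1:1 with the rendered frames."""

    frames: List[dict]

    def column(self, key: str) -> list:
        return [f.get(key) for f in self.frames]


class ScriptError(ValueError):
    """Scripted positions fall outside the scene geometry."""


# ---------------------------------------------------------------------------
# drawing helpers
# ---------------------------------------------------------------------------

def _draw_ellipse(canvas, cx, cy, rx, ry, value, angle_deg=0.0, taper=None):
    """Fill a rotated ellipse; ``taper`` shrinks the half-height linearly from
    the tail end (factor 1) to the head end (factor ``taper``), head at +u."""
    h, w = canvas.shape
    rmax = max(rx, ry) + 2
    x0, x1 = max(0, int(cx - rmax)), min(w, int(cx + rmax) + 1)
    y0, y1 = max(0, int(cy - rmax)), min(h, int(cy + rmax) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    a = math.radians(angle_deg)
    u = (xs - cx) * math.cos(a) + (ys - cy) * math.sin(a)
    v = -(xs - cx) * math.sin(a) + (ys - cy) * math.cos(a)
    ry_eff = np.full_like(u, float(ry))
    if taper is not None:
        # linear taper along the major axis: 1 at u=-rx (tail) to taper at u=+rx
        t = np.clip((u + rx) / (2 * rx), 0, 1)
        ry_eff = ry * (1.0 - (1.0 - taper) * t)
    inside = (u / rx) ** 2 + (v / np.maximum(ry_eff, 1e-6)) ** 2 <= 1.0
    region = canvas[y0:y1, x0:x1]
    region[inside] = value


def _draw_rect(canvas, x, y, w, h, value):
    hh, ww = canvas.shape
    x0, y0 = max(0, int(round(x))), max(0, int(round(y)))
    x1, y1 = min(ww, int(round(x + w))), min(hh, int(round(y + h)))
    if x0 < x1 and y0 < y1:
        canvas[y0:y1, x0:x1] = value


def _draw_rot_rect(canvas, cx, cy, length, width, angle_deg, value):
    """Filled rectangle of ``length × width`` centered at (cx, cy), long side at
    ``angle_deg`` counter-clockwise from +x (y up convention)."""
    h, w = canvas.shape
    r = math.hypot(length, width) / 2 + 2
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 1)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    a = math.radians(angle_deg)
    # y axis points down in image coords: flip the sign of the rotation in y
    u = (xs - cx) * math.cos(a) - (ys - cy) * math.sin(a)
    v = (xs - cx) * math.sin(a) + (ys - cy) * math.cos(a)
    inside = (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
    region = canvas[y0:y1, x0:x1]
    region[inside] = value


def _noisy(canvas, rng, sigma):
    if sigma <= 0:
        return np.clip(canvas, 0, 255)
    return np.clip(canvas + rng.normal(0, sigma, canvas.shape), 0, 255)


# ---------------------------------------------------------------------------
# rat stage 1: top view, head pose
# ---------------------------------------------------------------------------

RAT1_GEOM = {
    "size": (240, 320),  # (h, w)
    "floor": 200.0,
    "wall_value": 30.0,
    "bands": [(4, 10), (100, 108), (210, 218), (309, 315)],
    "b1": 104,
    "b2": 214,
}


def make_rat1_script(
    fps: float = 15.0,
    duration_s: float = 60.0,
    n_turns: int = 5,
    speed: float = 3.0,
    turn_frames: int = 4,
) -> dict:
    """Back-and-forth walk in the middle room with ``n_turns`` turn-arounds.

    Produces per-frame (x, y, heading, square) records; during a turn the body
    is rendered near-circular (square aspect) while the heading flips.
    """
    n = int(round(fps * duration_s))
    x_lo, x_hi = 135.0, 185.0
    y = 120.0
    frames = []
    x = x_lo + 5.0
    heading = "right"
    turn_left = 0
    turns_done = 0
    for _ in range(n):
        if turn_left > 0:
            turn_left -= 1
            square = True
            if turn_left == 0:
                heading = "left" if heading == "right" else "right"
        else:
            square = False
            x += speed if heading == "right" else -speed
            if (x >= x_hi or x <= x_lo) and turns_done < n_turns:
                turn_left = turn_frames
                turns_done += 1
            elif x >= x_hi:
                x = x_hi
            elif x <= x_lo:
                x = x_lo
        frames.append({"x": x, "y": y, "heading": heading, "square": square})
    return {"frames": frames, "n_turns": n_turns}


def _render_rat1(s: Scenario, rng) -> Tuple[List[GrayFrame], GroundTruth]:
    h, w = RAT1_GEOM["size"]
    sigma = s.script.get("noise_sigma", 3.0)
    rx, ry = s.script.get("body_rx", 18), s.script.get("body_ry", 9)
    frames: List[GrayFrame] = []
    gt: List[dict] = []
    for i, rec in enumerate(s.script["frames"]):
        canvas = np.full((h, w), RAT1_GEOM["floor"])
        for (bs, be) in RAT1_GEOM["bands"]:
            _draw_rect(canvas, bs, 0, be - bs + 1, h, RAT1_GEOM["wall_value"])
        x, y, heading, square = rec["x"], rec["y"], rec["heading"], rec["square"]
        if not (RAT1_GEOM["b1"] < x < RAT1_GEOM["b2"]):
            raise ScriptError(f"rat x={x} outside middle room")
        if square:
            _draw_ellipse(canvas, x, y, ry + 2, ry + 2, 45.0)
            head_pt = (x, y)
        else:
            angle = 0.0 if heading == "right" else 180.0
            _draw_ellipse(canvas, x, y, rx, ry, 45.0, angle_deg=angle, taper=0.55)
            dx = rx * 0.8 if heading == "right" else -rx * 0.8
            head_pt = (x + dx, y)
            # thin tail on the side opposite the head
            tail_dir = -1 if heading == "right" else 1
            tx = x + tail_dir * rx
            _draw_rect(canvas, min(tx, tx + tail_dir * 18), y - 1, 18, 2, 45.0)
        frames.append(GrayFrame(_noisy(canvas, rng, sigma), frame_index=i, fps=s.fps))
        gt.append(
            {
                "x": x,
                "y": y,
                "heading": heading,
                "square": square,
                "head_side": heading,
                "head_x": head_pt[0],
                "head_y": head_pt[1],
            }
        )
    return frames, GroundTruth(gt)


# ---------------------------------------------------------------------------
# rat stage 2: side view, compartment visits
# ---------------------------------------------------------------------------

RAT2_GEOM = {
    "size": (240, 320),
    "floor": 190.0,
    "structure_value": 25.0,
    "rat_value": 60.0,
    "left_cage": (10, 60),
    "right_cage": (260, 310),
    "walls": [(110, 112), (210, 212)],
    "b1": 111,
    "b2": 211,
    "anchors": {"left_cage": 85.0, "middle": 160.0, "right_cage": 237.0},
}


def make_rat2_script(
    visits: Sequence[Tuple[str, float]],
    fps: float = 15.0,
    speed: float = 5.0,
    bob_amp: float = 2.0,
) -> dict:
    """Script compartment visits as (compartment, dwell_seconds) segments.

    The rat walks at ``speed`` px/frame between compartment anchor positions
    and bobs slightly while dwelling so that motion tracking never starves.
    """
    anchors = RAT2_GEOM["anchors"]
    frames = []
    x = anchors[visits[0][0]]
    y0 = 170.0
    t = 0
    for comp, dwell in visits:
        target = anchors[comp]
        while abs(x - target) > speed:
            x += speed if target > x else -speed
            frames.append({"x": x, "y": y0 + bob_amp * math.sin(0.9 * t)})
            t += 1
        x = target
        for _ in range(int(round(dwell * fps))):
            frames.append(
                {"x": x + 3.0 * math.sin(0.7 * t), "y": y0 + bob_amp * math.sin(0.9 * t)}
            )
            t += 1
    return {"frames": frames, "visits": list(visits)}


def _render_rat2(s: Scenario, rng) -> Tuple[List[GrayFrame], GroundTruth]:
    h, w = RAT2_GEOM["size"]
    sigma = s.script.get("noise_sigma", 3.0)
    frames: List[GrayFrame] = []
    gt: List[dict] = []
    b1, b2 = RAT2_GEOM["b1"], RAT2_GEOM["b2"]
    for i, rec in enumerate(s.script["frames"]):
        canvas = np.full((h, w), RAT2_GEOM["floor"])
        for (cs, ce) in (RAT2_GEOM["left_cage"], RAT2_GEOM["right_cage"]):
            _draw_rect(canvas, cs, 0, ce - cs + 1, h, RAT2_GEOM["structure_value"])
        for (ws, we) in RAT2_GEOM["walls"]:
            _draw_rect(canvas, ws, 0, we - ws + 1, h, RAT2_GEOM["structure_value"])
        x, y = rec["x"], rec["y"]
        if not (RAT2_GEOM["left_cage"][1] < x < RAT2_GEOM["right_cage"][0]):
            raise ScriptError(f"rat x={x} outside the box")
        _draw_ellipse(canvas, x, y, 15, 8, RAT2_GEOM["rat_value"])
        frames.append(GrayFrame(_noisy(canvas, rng, sigma), frame_index=i, fps=s.fps))
        comp = "left_cage" if x < b1 else ("right_cage" if x > b2 else "middle")
        gt.append({"x": x, "y": y, "compartment": comp})
    return frames, GroundTruth(gt)


# ---------------------------------------------------------------------------
# monkey: unevenly lit cage with a dark sensor box
# ---------------------------------------------------------------------------

MONKEY_GEOM = {
    "size": (240, 320),
    "info_polygon": RegionPolygon(
        [(5, 5), (268, 5), (268, 235), (5, 235)], "info"
    ),
    "box_len": 60,
    "box_wid": 24,
    "box_value": 15.0,
    "dim_factor": 0.2,
}


def make_monkey_script(
    fps: float = 15.0,
    duration_s: float = 40.0,
    light_off: Sequence[Tuple[float, float]] = (),
    pauses: Sequence[Tuple[float, float]] = (),
    burst: Optional[Tuple[float, float]] = None,
    shadow: bool = True,
) -> dict:
    """Smooth sensor-box path with scripted light-off intervals and pauses.

    ``light_off``/``pauses`` are (start_s, end_s) intervals; ``burst`` is an
    external-motion interval rendered outside the information polygon.
    """
    n = int(round(fps * duration_s))
    frames = []
    path_t = 0.0  # path clock advances only while the monkey is not pausing
    for i in range(n):
        t = i / fps
        paused = any(a <= t < b for a, b in pauses)
        if not paused:
            path_t += 1.0 / fps
        x = 140.0 + 80.0 * math.sin(2 * math.pi * path_t / 6.0)
        y = 120.0 + 55.0 * math.sin(2 * math.pi * path_t / 9.5 + 1.0)
        angle = (30.0 + 2.0 * t) % 180.0
        off = any(a <= t < b for a, b in light_off)
        burst_on = burst is not None and burst[0] <= t < burst[1]
        frames.append(
            {
                "x": x,
                "y": y,
                "angle": angle,
                "light": "off" if off else "on",
                "burst": burst_on,
            }
        )
    return {"frames": frames, "shadow": shadow}


def render_monkey_scene(s: Scenario) -> Tuple[List[GrayFrame], GroundTruth]:
    """Render a monkey scenario; deterministic in (script, seed)."""
    if s.app != "monkey":
        raise ScriptError(f"render_monkey_scene cannot render app={s.app!r}")
    rng = np.random.default_rng(s.seed)
    h, w = MONKEY_GEOM["size"]
    sigma = s.script.get("noise_sigma", 3.0)
    shadow = s.script.get("shadow", True)
    xs = np.linspace(100.0, 190.0, w)[np.newaxis, :]
    gradient = np.repeat(xs, h, axis=0)
    frames: List[GrayFrame] = []
    gt: List[dict] = []
    for i, rec in enumerate(s.script["frames"]):
        canvas = gradient.copy()
        x, y, angle = rec["x"], rec["y"], rec["angle"]
        if not (0 <= x < w and 0 <= y < h):
            raise ScriptError(f"sensor box at ({x},{y}) outside the frame")
        _draw_rot_rect(
            canvas, x, y, MONKEY_GEOM["box_len"], MONKEY_GEOM["box_wid"],
            angle, MONKEY_GEOM["box_value"],
        )
        if rec["light"] == "off":
            canvas *= MONKEY_GEOM["dim_factor"]
            if shadow:
                sx = min(w - 12.0, x + 90.0)
                _draw_ellipse(canvas, sx, y, 14, 10, 5.0)
        if rec["burst"]:
            by = 60.0 + 40.0 * math.sin(0.8 * i)
            _draw_ellipse(canvas, 295.0, by, 12, 12, 40.0)
        frames.append(GrayFrame(_noisy(canvas, rng, sigma), frame_index=i, fps=s.fps))
        gt.append(dict(rec))
    return frames, GroundTruth(gt)


# ---------------------------------------------------------------------------
# panda: four synchronized habitat views
# ---------------------------------------------------------------------------

PANDA_WORLD = {
    "size": (270, 480),  # (h, w) world units == camera-6 pixels
    "bg": 150.0,
    "bear_value": 40.0,
    "bear_rx": 14,
    "bear_ry": 9,
    "meadow": [(40, 40), (440, 40), (440, 250), (40, 250)],
    "housing": [(60, 60), (140, 60), (140, 140), (60, 140)],
    "door": (0, 130, 30, 50),  # x, y, w, h
    "tech_gate": (0, 40, 40, 70),
    "basin": (410, 160, 60, 60),
    "stones": [(425, 170, 18, 35), (444, 170, 16, 35)],
    "rocks": [(200, 80, 12), (320, 210, 10)],
}

# per-camera affine projections: (scale, x_offset, y_offset)
PANDA_CAMERAS = {
    5: {"scale": 1.5, "off": (0.0, 30.0), "general": False},
    6: {"scale": 1.0, "off": (0.0, 0.0), "general": True},
    7: {"scale": 0.95, "off": (-8.0, -6.0), "general": True},
    8: {"scale": 1.5, "off": (160.0, 30.0), "general": False},
}
PANDA_RESOLUTION = (480, 270)  # (w, h)


def _project(cam: int, p: Tuple[float, float]) -> Tuple[float, float]:
    c = PANDA_CAMERAS[cam]
    return (
        c["scale"] * (p[0] - c["off"][0]),
        c["scale"] * (p[1] - c["off"][1]),
    )


def _project_rect(cam: int, r: Tuple[float, float, float, float]) -> Rect:
    x0, y0 = _project(cam, (r[0], r[1]))
    x1, y1 = _project(cam, (r[0] + r[2], r[1] + r[3]))
    return Rect(int(round(x0)), int(round(y0)),
                int(round(x1 - x0)), int(round(y1 - y0)))


def _visible_on(cam: int, poly_pts) -> bool:
    w, h = PANDA_RESOLUTION
    pts = [_project(cam, p) for p in poly_pts]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return max(xs) > 0 and min(xs) < w and max(ys) > 0 and min(ys) < h


def make_panda_camera_configs():
    """Build the four CameraConfigs consistent with the world projections."""
    from zootrack.panda_tracking import CameraConfig, Zone

    w, h = PANDA_RESOLUTION
    world_zones = [
        ("door", [(0, 130), (30, 130), (30, 180), (0, 180)], "door", 2),
        ("housing", PANDA_WORLD["housing"], "housing", 1),
        ("basin", [(410, 160), (470, 160), (470, 220), (410, 220)], "basin", 0),
        ("meadow", PANDA_WORLD["meadow"], "full", 0),
    ]
    cfgs = {}
    for cam in PANDA_CAMERAS:
        zones = []
        for name, pts, kind, rank in world_zones:
            if name == "basin" and cam != 8:
                continue  # the basin dwell is only observable by camera 8
            if not _visible_on(cam, pts):
                continue
            zones.append(
                Zone(RegionPolygon([_project(cam, p) for p in pts], name),
                     name, kind, rank)
            )
        corr = {}
        for z in zones:
            partners = []
            for other in PANDA_CAMERAS:
                if other == cam:
                    continue
                if z.name == "basin" and other != 8:
                    continue
                world_pts = next(p for n, p, _, _ in world_zones if n == z.name)
                if _visible_on(other, world_pts):
                    partners.append((other, z.name))
            corr[z.name] = partners
        tech_gate = _project_rect(cam, PANDA_WORLD["tech_gate"])
        tech_gate = tech_gate.intersect(Rect(0, 0, w, h))
        cfgs[cam] = CameraConfig(
            camera_id=cam,
            resolution=PANDA_RESOLUTION,
            info_polygon=RegionPolygon(
                [(2, 2), (w - 3, 2), (w - 3, h - 3), (2, h - 3)], "info"
            ),
            panda_gates=[
                r for r in [_project_rect(cam, PANDA_WORLD["door"]).intersect(
                    Rect(0, 0, w, h))] if r.area > 0
            ],
            technician_gate=tech_gate if tech_gate.area > 0 else None,
            visible_zones=zones,
            zone_correspondence=corr,
            general_view=PANDA_CAMERAS[cam]["general"],
            basin_zone=(
                _project_rect(8, PANDA_WORLD["basin"]).intersect(Rect(0, 0, w, h))
                if cam == 8 else None
            ),
            velocity_weight=1.0 / PANDA_CAMERAS[cam]["scale"],
        )
    return cfgs


def _segment_frames(waypoints, n_frames):
    """Constant-speed positions along a polyline, n_frames samples."""
    pts = [np.asarray(p, float) for p in waypoints]
    seg_len = [np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])]
    total = sum(seg_len)
    out = []
    for k in range(n_frames):
        d = total * k / max(1, n_frames - 1)
        for a, b, L in zip(pts, pts[1:], seg_len):
            if d <= L or (a is pts[-2] and b is pts[-1]):
                t = 0.0 if L == 0 else min(1.0, d / L)
                out.append(tuple(a + t * (b - a)))
                break
            d -= L
    return out


def make_panda_script(fps: float = 10.0, duration_s: float = 120.0) -> dict:
    """Scripted 2-minute habitat scenario with all five stress contexts.

    Timeline: entry walk, slow wander, housing still, mid-speed walk
    (walking 2), meadow rest, mid-speed walk (walking 1) with a bird event,
    dash (running), housing still, slow bent walk (walking 3), exit, caretaker
    visit, re-entry, walk to the basin, hidden bath (stationary), final rest.
    """
    n = int(round(fps * duration_s))
    frames = [dict(pos=None, stress=None, technician=False, bath=False,
                   bird=False, still=False) for _ in range(n)]

    def fill(t0, t1, waypoints=None, pos=None, stress=None, still=False):
        i0, i1 = int(round(t0 * fps)), min(n, int(round(t1 * fps)))
        if waypoints is not None:
            path = _segment_frames(waypoints, i1 - i0)
        for k, i in enumerate(range(i0, i1)):
            if waypoints is not None:
                frames[i]["pos"] = path[k]
            elif pos is not None:
                jx = 0.4 * math.sin(0.8 * i)
                jy = 0.4 * math.sin(0.6 * i + 1)
                frames[i]["pos"] = (pos[0] + jx, pos[1] + jy)
            frames[i]["stress"] = stress
            frames[i]["still"] = still

    fill(0, 2, waypoints=[(15, 155), (85, 155)])
    fill(2, 18, waypoints=[(85, 155), (120, 185), (170, 195), (150, 140), (120, 110)])
    fill(18, 28, pos=(120, 110), still=True)  # housing still period
    fill(28, 38, waypoints=[(120, 110), (300, 170), (140, 230), (330, 240)],
         stress="walking2")
    fill(38, 46, pos=(330, 240), still=True)  # rest in the full-visibility zone
    fill(46, 54, waypoints=[(330, 240), (150, 180), (300, 120), (380, 180)],
         stress="walking1")
    fill(54, 57, waypoints=[(380, 180), (240, 60), (100, 130)], stress="running")
    fill(57, 67, pos=(100, 130), still=True)  # housing still period
    fill(67, 77, waypoints=[(100, 130), (220, 140), (240, 220)], stress="walking3")
    fill(77, 80, pos=(240, 220), still=True)
    fill(80, 90, waypoints=[(240, 220), (15, 155)])  # exit through the door
    # 91..99: bear in a refuge, caretaker visit (triangular sweep of the cage)
    t0, span = int(91 * fps), int(8 * fps)
    for i in range(t0, min(n, t0 + span)):
        frames[i]["technician"] = True
        k = i - t0
        half = span // 2
        frac = k / half if k <= half else (span - k) / half
        frames[i]["tech_x"] = 5.0 + 195.0 * max(0.0, min(1.0, frac))
    fill(99, 102, waypoints=[(15, 155), (85, 160)])  # re-entry
    fill(102, 107, waypoints=[(85, 160), (430, 185)])  # walk to the basin
    for i in range(int(107 * fps), min(n, int(117 * fps))):  # hidden bath
        frames[i]["bath"] = True
        frames[i]["stress"] = "stationary"
    fill(117, duration_s, pos=(350, 200), still=True)
    # bird event on the general views during the walking-1 segment
    b0 = int(47 * fps)
    for i in range(b0, min(n, int(49 * fps))):
        frames[i]["bird"] = True
        frames[i]["bird_pos"] = (50.0 + 22.0 * (i - b0), 20.0)
    return {"frames": frames}


def render_panda_scene(s: Scenario):
    """Render the four synchronized views plus camera configs and ground truth.

    Returns (frames_by_camera, camera_configs, ground_truth).
    """
    if s.app != "panda":
        raise ScriptError(f"render_panda_scene cannot render app={s.app!r}")
    rng = np.random.default_rng(s.seed)
    sigma = s.script.get("noise_sigma", 3.0)
    w, h = PANDA_RESOLUTION
    cfgs = make_panda_camera_configs()
    streams: Dict[int, List[GrayFrame]] = {cam: [] for cam in PANDA_CAMERAS}
    gt: List[dict] = []
    wh, ww = PANDA_WORLD["size"]
    for i, rec in enumerate(s.script["frames"]):
        pos = rec["pos"]
        if pos is not None and not (0 <= pos[0] < ww and 0 <= pos[1] < wh):
            raise ScriptError(f"bear at {pos} outside the habitat")
        # world-level dynamic content shared by all views
        ripples = []
        if rec["bath"]:
            bx, by, bw, bh = PANDA_WORLD["basin"]
            for _ in range(25):
                ripples.append(
                    (bx + rng.uniform(0, bw), by + rng.uniform(0, bh),
                     rng.uniform(2.5, 5.0))
                )
        tech_x = rec.get("tech_x")
        bird_pos = rec.get("bird_pos")
        for cam in PANDA_CAMERAS:
            scale = PANDA_CAMERAS[cam]["scale"]
            canvas = np.full((h, w), PANDA_WORLD["bg"] + 2.0 * cam)
            for rx, ry_, rr in PANDA_WORLD["rocks"]:
                px, py = _project(cam, (rx, ry_))
                _draw_ellipse(canvas, px, py, rr * scale, rr * scale, 120.0)
            bx, by, bw, bh_ = PANDA_WORLD["basin"]
            r = _project_rect(cam, (bx, by, bw, bh_))
            _draw_rect(canvas, r.x, r.y, r.w, r.h, 135.0)
            for (rx, ry_, rr) in ripples:
                px, py = _project(cam, (rx, ry_))
                _draw_ellipse(canvas, px, py, rr * scale, rr * scale * 0.7, 100.0)
            if pos is not None:
                px, py = _project(cam, pos)
                _draw_ellipse(
                    canvas, px, py,
                    PANDA_WORLD["bear_rx"] * scale, PANDA_WORLD["bear_ry"] * scale,
                    PANDA_WORLD["bear_value"],
                )
            for sx, sy, sw, sh in PANDA_WORLD["stones"]:
                r = _project_rect(cam, (sx, sy, sw, sh))
                _draw_rect(canvas, r.x, r.y, r.w, r.h, 70.0)
            if tech_x is not None:
                r = _project_rect(cam, (tech_x - 15, 50, 30, 170))
                _draw_rect(canvas, r.x, r.y, r.w, r.h, 50.0)
            if bird_pos is not None and PANDA_CAMERAS[cam]["general"]:
                px, py = _project(cam, bird_pos)
                _draw_ellipse(canvas, px, py, 10 * scale, 6 * scale, 60.0)
            streams[cam].append(
                GrayFrame(_noisy(canvas, rng, sigma), frame_index=i, fps=s.fps)
            )
        g = dict(rec)
        g["x"] = None if pos is None else pos[0]
        g["y"] = None if pos is None else pos[1]
        gt.append(g)
    return streams, cfgs, GroundTruth(gt)


def render_rat_scene(s: Scenario) -> Tuple[List[GrayFrame], GroundTruth]:
    """Render a rat scenario (``app`` rat1 or rat2); deterministic in seed."""
    rng = np.random.default_rng(s.seed)
    if s.app == "rat1":
        return _render_rat1(s, rng)
    if s.app == "rat2":
        return _render_rat2(s, rng)
    raise ScriptError(f"render_rat_scene cannot render app={s.app!r}")
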