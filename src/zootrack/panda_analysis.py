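"""Multi-view trajectory synthesis and stress-episode analysis.

Per synchronized frame index the best per-camera observation is selected into
one fused :class:`TrackEntry` (technician and out-of-zone candidates dropped,
zone-hierarchy ranking, ties favoring the previously selected camera). The
fused list is then post-processed:

1. compaction filtering — short runs of a complementary camera interleaved
   between two large runs of the same camera are substituted by that camera's
   own positions;
2. gap interpolation — coordinate gaps of 2..100 frames bounded by the same
   camera are filled linearly, the attribute following the moving/freezing
   rule of the bounding pair;
3. attribute smoothing — centered-window majority vote;
4. velocities — Euclidean displacement between same-camera neighbors, scaled
   by the per-camera weight and resolution normalization, then window-averaged
   over valid entries;
5. stress labeling — five classes from the velocity bands ``thr_v1 > thr_v2 >
   thr_v3`` and the habitat context (full-visibility zone vs. garden housing
   still periods, path heights, the camera-8 basin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from zootrack.motion_core import ConfigurationError, compute_motion_image
from zootrack.panda_tracking import (
    FREEZING,
    MOVEMENT,
    NO_INFORMATION,
    CameraConfig,
    FrameObservation,
    MotionThresholds,
    PandaCameraTracker,
    TrackerParams,
)

__all__ = [
    "TrackEntry",
    "VelocityThresholds",
    "StressEpisode",
    "StressParams",
    "select_view",
    "fuse_views",
    "run_panda_pipeline",
    "filter_pass_compaction",
    "fill_gaps",
    "smooth_attributes",
    "compute_velocities",
    "classify_stress",
]

FREEZING_OR_MISSING = "freezing_or_missing"

RUNNING = "running"
WALKING1 = "walking1"
WALKING2 = "walking2"
WALKING3 = "walking3"
STATIONARY = "stationary"

STRESS_CLASSES = (RUNNING, WALKING1, WALKING2, WALKING3, STATIONARY)


@dataclass
class TrackEntry:
    frame_index: int
    camera_id: Optional[int] = None
    x: Optional[float] = None
    y: Optional[float] = None
    attribute: str = FREEZING_OR_MISSING
    zone_name: Optional[str] = None
    velocity: Optional[float] = None
    stress: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.camera_id is None) != (self.x is None or self.y is None):
            raise ConfigurationError("camera and coordinates must be null together")

    @property
    def position(self) -> Optional[Tuple[float, float]]:
        if self.x is None:
            return None
        return (self.x, self.y)


@dataclass
class VelocityThresholds:
    thr_v1: float = 9.0
    thr_v2: float = 4.0
    thr_v3: float = 1.5

    def __post_init__(self) -> None:
        if not (self.thr_v1 > self.thr_v2 > self.thr_v3):
            raise ConfigurationError("thresholds must satisfy thr_v1>thr_v2>thr_v3")


@dataclass
class StressEpisode:
    stress_class: str
    start_frame: int
    end_frame: int
    duration_s: float
    camera_id: Optional[int] = None


@dataclass
class StressParams:
    height_dist: float = 20.0  # px: "significant distance" of a path height
    context_window_s: float = 10.0  # look-back for the preceding-period zone
    context_still_frames: int = 40  # nearest still entries that vote on the zone
    min_episode_s: float = 1.0  # shortest reportable episode
    stationary_min_s: float = 5.0
    basin_margin: float = 10.0  # "close to the basin" distance
    velocity_window: int = 9
    attribute_window: int = 5


# ---------------------------------------------------------------------------
# View selection / fusion
# ---------------------------------------------------------------------------

def _zone_rank(cfg: CameraConfig, zone) -> int:
    # lower is better; ground cameras beat general views at equal zone rank
    return zone.rank * 10 + (1 if cfg.general_view else 0)


def select_view(
    candidates: Dict[int, FrameObservation],
    prev_selected: Optional[TrackEntry],
    cfgs: Dict[int, CameraConfig],
    frame_index: int,
) -> TrackEntry:
    """Pick the per-frame observation with the most observable bear.

    Technician frames and positions outside every visible zone are dropped;
    remaining candidates are ranked by the zone hierarchy; ties keep the
    previously selected camera. Returns a null entry when nothing qualifies.
    """
    ranked = []
    for cam, obs in candidates.items():
        if obs is None or obs.zoo_technician:
            continue
        if obs.attribute not in (MOVEMENT, FREEZING) or obs.position is None:
            continue
        cfg = cfgs[cam]
        zone = cfg.zone_of(obs.position)
        if zone is None:
            continue  # exterior of the observable zones
        area = obs.rect.area if obs.rect is not None else 0
        ranked.append((_zone_rank(cfg, zone), area, cam, obs, zone))
    if not ranked:
        return TrackEntry(frame_index)
    best_rank = min(r[0] for r in ranked)
    top = [r for r in ranked if r[0] == best_rank]
    # "most observable bear": largest movement rectangle wins; the previously
    # selected camera is kept when it offers almost the same information
    top.sort(key=lambda r: -r[1])
    chosen = top[0]
    if prev_selected is not None and prev_selected.camera_id is not None:
        for r in top:
            if r[2] == prev_selected.camera_id and r[1] >= 0.67 * top[0][1]:
                chosen = r
                break
    _, _, cam, obs, zone = chosen
    x, y = obs.position
    return TrackEntry(
        frame_index, cam, float(x), float(y), obs.attribute, zone.name
    )


def fuse_views(
    per_camera: Dict[int, Sequence[Optional[FrameObservation]]],
    cfgs: Dict[int, CameraConfig],
) -> List[TrackEntry]:
    """Frame-by-frame fusion; result length = min per-camera length."""
    n = min(len(v) for v in per_camera.values())
    fused: List[TrackEntry] = []
    prev: Optional[TrackEntry] = None
    for i in range(n):
        cands = {cam: seq[i] for cam, seq in per_camera.items()}
        entry = select_view(cands, prev, cfgs, i)
        fused.append(entry)
        if entry.camera_id is not None:
            prev = entry
    return fused


def run_panda_pipeline(
    frames_by_cam: Dict[int, Sequence],
    cfgs: Dict[int, CameraConfig],
    thr: Optional[MotionThresholds] = None,
    vthr: Optional[VelocityThresholds] = None,
    fps: float = 10.0,
    stress_params: Optional[StressParams] = None,
    tracker_params: Optional[TrackerParams] = None,
    motion_threshold: float = 15.0,
    erosion_size: int = 2,
    dilation_size: int = 5,
) -> Dict[str, object]:
    """Full panda analysis: per-camera tracking, fusion, filtering, stress.

    Per synchronized frame index each camera tracker is stepped (fed the
    previously fused entry for the cross-view validation rules), the best view
    is fused, and the fused list is run through the filtering passes, gap
    interpolation, attribute smoothing, velocity computation and stress
    labeling. The fused list length equals the minimum video length.
    """
    thr = thr or MotionThresholds()
    vthr = vthr or VelocityThresholds()
    stress_params = stress_params or StressParams()
    trackers = {
        cam: PandaCameraTracker(cfgs[cam], thr, tracker_params)
        for cam in frames_by_cam
    }
    n = min(len(v) for v in frames_by_cam.values())
    per_cam_obs: Dict[int, List[FrameObservation]] = {cam: [] for cam in frames_by_cam}
    fused: List[TrackEntry] = []
    prev_entry: Optional[TrackEntry] = None
    prev_zone: Optional[Tuple[int, str]] = None
    for i in range(n):
        cands: Dict[int, FrameObservation] = {}
        for cam, frames in frames_by_cam.items():
            if i < 2:  # warm-up: the frame triple is incomplete
                obs = FrameObservation(i, cam, None, NO_INFORMATION, 0, False)
            else:
                m = compute_motion_image(
                    frames[i], frames[i - 1], frames[i - 2],
                    threshold=motion_threshold,
                    erosion_size=erosion_size, dilation_size=dilation_size,
                )
                obs = trackers[cam].step(m, i, prev_entry, prev_zone)
            per_cam_obs[cam].append(obs)
            cands[cam] = obs
        entry = select_view(cands, prev_entry, cfgs, i)
        fused.append(entry)
        if entry.camera_id is not None:
            prev_entry = entry
            prev_zone = (entry.camera_id, entry.zone_name)
    compacted = filter_pass_compaction(fused, per_cam_obs, cfgs)
    filled = fill_gaps(compacted)
    smoothed = smooth_attributes(filled, stress_params.attribute_window)
    with_v = compute_velocities(smoothed, cfgs, stress_params.velocity_window)
    labeled, episodes = classify_stress(with_v, vthr, cfgs, fps, stress_params)
    return {
        "per_camera": per_cam_obs,
        "fused": fused,
        "trajectory": labeled,
        "episodes": episodes,
    }


# ---------------------------------------------------------------------------
# Filtering passes
# ---------------------------------------------------------------------------

def _camera_runs(entries: Sequence[TrackEntry]) -> List[Tuple[Optional[int], int, int]]:
    """Maximal runs of equal camera id: list of (camera, start, end_inclusive)."""
    runs = []
    start = 0
    for i in range(1, len(entries) + 1):
        if i == len(entries) or entries[i].camera_id != entries[start].camera_id:
            runs.append((entries[start].camera_id, start, i - 1))
            start = i
    return runs


def filter_pass_compaction(
    entries: Sequence[TrackEntry],
    per_camera_tracks: Optional[Dict[int, Sequence[Optional[FrameObservation]]]] = None,
    cfgs: Optional[Dict[int, CameraConfig]] = None,
    large_min: int = 50,
    short_max: int = 10,
) -> List[TrackEntry]:
    """Compaction pass: substitute short interleaved other-camera runs.

    Between two large runs of the same camera A, every interleaved run of
    length ≤ ``short_max`` belonging to another camera is replaced by camera
    A's own positions for those frames (taken from its per-camera trajectory
    when available, otherwise by linear interpolation along camera A's
    bounding positions).
    """
    out = [TrackEntry(**vars(e)) for e in entries]
    runs = _camera_runs(out)
    large = [
        (idx, cam, s, e)
        for idx, (cam, s, e) in enumerate(runs)
        if cam is not None and e - s + 1 >= large_min
    ]
    for (ia, cam_a, sa, ea), (ib, cam_b, sb, eb) in zip(large, large[1:]):
        if cam_a != cam_b:
            continue
        inner = runs[ia + 1 : ib]
        if not inner:
            continue
        if any(
            cam is not None and cam != cam_a and e - s + 1 > short_max
            for cam, s, e in inner
        ):
            continue
        for cam, s, e in inner:
            if cam is None or cam == cam_a:
                continue
            for i in range(s, e + 1):
                repl = None
                if per_camera_tracks is not None and cam_a in per_camera_tracks:
                    obs = per_camera_tracks[cam_a][i]
                    if obs is not None and obs.position is not None:
                        repl = obs.position
                if repl is None:
                    # interpolate along camera A's bounding entries
                    p0 = out[ea].position
                    p1 = out[sb].position
                    t = (i - ea) / (sb - ea)
                    repl = (
                        p0[0] + t * (p1[0] - p0[0]),
                        p0[1] + t * (p1[1] - p0[1]),
                    )
                out[i] = TrackEntry(
                    out[i].frame_index, cam_a, float(repl[0]), float(repl[1]),
                    out[i].attribute, out[i].zone_name,
                )
    return out


def fill_gaps(entries: Sequence[TrackEntry]) -> List[TrackEntry]:
    """Fill coordinate gaps of length 2..100 bounded by the same camera.

    Intermediate frame k of a gap between filled entries at i and i+j gets
    ``x(F_{i+k}) = x(F_i) + k·(x(F_{i+j}) − x(F_i))/(F_{i+j} − F_i)`` (same in
    y); the attribute is moving when at least one bounding entry is moving,
    freezing otherwise. Longer gaps or different-camera bounds stay untouched.
    """
    out = [TrackEntry(**vars(e)) for e in entries]
    filled_idx = [i for i, e in enumerate(out) if e.camera_id is not None]
    for a, b in zip(filled_idx, filled_idx[1:]):
        j = b - a
        if not (2 <= j <= 100):
            continue
        ea, eb = out[a], out[b]
        if ea.camera_id != eb.camera_id:
            continue
        attr = MOVEMENT if MOVEMENT in (ea.attribute, eb.attribute) else FREEZING
        for k in range(1, j):
            t = k / j
            out[a + k] = TrackEntry(
                out[a + k].frame_index,
                ea.camera_id,
                ea.x + t * (eb.x - ea.x),
                ea.y + t * (eb.y - ea.y),
                attr,
                ea.zone_name,
            )
    return out


def smooth_attributes(
    entries: Sequence[TrackEntry], window: int = 5
) -> List[TrackEntry]:
    """Centered-window majority vote over the attribute field.

    Ties keep the current attribute (deterministic, change-averse).
    """
    if window % 2 == 0:
        raise ConfigurationError("attribute window must be odd")
    half = window // 2
    n = len(entries)
    out = [TrackEntry(**vars(e)) for e in entries]
    attrs = [e.attribute for e in entries]
    for i in range(n):
        votes: Dict[str, int] = {}
        for j in range(max(0, i - half), min(n, i + half + 1)):
            votes[attrs[j]] = votes.get(attrs[j], 0) + 1
        best = max(votes.values())
        winners = sorted(k for k, v in votes.items() if v == best)
        if attrs[i] in winners:
            out[i].attribute = attrs[i]
        else:
            out[i].attribute = winners[0]
    return out


def compute_velocities(
    entries: Sequence[TrackEntry],
    cfgs: Dict[int, CameraConfig],
    window: int = 9,
    ref_width: Optional[int] = None,
) -> List[TrackEntry]:
    """Per-entry weighted velocity, then centered-window averaging.

    ``v_{i+1}`` is the Euclidean displacement between consecutive entries of
    the same camera, multiplied by the camera's velocity weight and by the
    resolution normalization ``ref_width / camera_width``; cross-camera pairs
    yield a missing velocity.
    """
    if window % 2 == 0:
        raise ConfigurationError("velocity window must be odd")
    out = [TrackEntry(**vars(e)) for e in entries]
    n = len(out)
    raw: List[Optional[float]] = [None] * n
    if ref_width is None and cfgs:
        ref_width = max(c.resolution[0] for c in cfgs.values())
    for i in range(n - 1):
        a, b = out[i], out[i + 1]
        if a.camera_id is None or a.camera_id != b.camera_id:
            continue
        cfg = cfgs[a.camera_id]
        scale = cfg.velocity_weight * (ref_width / cfg.resolution[0])
        raw[i + 1] = math.dist((a.x, a.y), (b.x, b.y)) * scale
    half = window // 2
    for i in range(n):
        if out[i].camera_id is None:
            out[i].velocity = None  # null entries never carry a velocity
            continue
        vals = [
            raw[j]
            for j in range(max(0, i - half), min(n, i + half + 1))
            if raw[j] is not None
        ]
        out[i].velocity = float(np.mean(vals)) if vals else None
    return out


# ---------------------------------------------------------------------------
# Stress classification
# ---------------------------------------------------------------------------

def _path_has_height(points: Sequence[Tuple[float, float]], height_dist: float) -> bool:
    """True when some point lies far from the least-squares line of the path."""
    if len(points) < 3:
        return False
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    # principal direction via SVD: residual = distance to the fitted line
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    residuals = np.abs(centered @ vt[1])
    return bool(residuals.max() > height_dist)


def _preceding_context(
    entries: Sequence[TrackEntry],
    run_start: int,
    cfgs: Dict[int, CameraConfig],
    fps: float,
    params: StressParams,
    min_still_frames: int = 15,
) -> Optional[str]:
    """Zone kind of the still period preceding a moving run.

    Looks back over the context window for a sustained block of non-moving
    present entries (a genuine still / recording period, not a transient) and
    votes over the zone kinds of the block. Returns 'housing', 'full' or None.
    """
    look = int(params.context_window_s * fps)
    kinds: List[str] = []
    i = run_start - 1
    lo = max(-1, run_start - 1 - look)
    while i > lo and len(kinds) < params.context_still_frames:
        e = entries[i]
        if e.camera_id is None:
            i -= 1
            continue  # allow missing stretches inside the still period
        if e.attribute == MOVEMENT:
            break
        zone = cfgs[e.camera_id].zone_of(e.position)
        if zone is not None:
            kinds.append(zone.kind)
        i -= 1
    if len(kinds) < min_still_frames:
        return None
    housing = kinds.count("housing")
    full = kinds.count("full")
    if housing >= full and housing > 0:
        return "housing"
    if full > 0:
        return "full"
    return None


def classify_stress(
    entries: Sequence[TrackEntry],
    thr: VelocityThresholds,
    cfgs: Dict[int, CameraConfig],
    fps: float,
    params: Optional[StressParams] = None,
) -> Tuple[List[TrackEntry], List[StressEpisode]]:
    """Label each entry with one of the five stress classes (or none).

    * v > thr_v1 → running;
    * thr_v2 < v < thr_v1 in a moving series following a recording period in a
      complete-visibility zone → walking 1, following a still period in a
      garden housing → walking 2;
    * thr_v3 < v < thr_v2 after a housing still period, when the path section
      shows at least one height → walking 3;
    * camera-8 basin dwells longer than the stationary minimum → stationary.
    """
    params = params or StressParams()
    out = [TrackEntry(**vars(e)) for e in entries]
    n = len(out)

    # --- stationary: camera-8 basin dwells ---------------------------------
    basin_cam = next(
        (cam for cam, c in cfgs.items() if c.basin_zone is not None), None
    )
    if basin_cam is not None:
        bz = cfgs[basin_cam].basin_zone
        i = 0
        while i < n:
            e = out[i]
            def _bathing(entry: TrackEntry) -> bool:
                # bathing floods the basin with motion traits: attribute stays
                # movement while the mass center hugs the basin
                return (
                    entry.camera_id == basin_cam
                    and entry.attribute == MOVEMENT
                    and entry.position is not None
                    and math.dist(entry.position, bz.center)
                    < bz.diagonal / 2 + params.basin_margin
                )

            if not _bathing(e):
                i += 1
                continue
            j = i
            while j < n and _bathing(out[j]):
                j += 1
            if (j - i) / fps > params.stationary_min_s:
                for k in range(i, j):
                    out[k].stress = STATIONARY
            i = j

    # --- running: pure velocity rule ---------------------------------------
    for e in out:
        if e.stress is None and e.velocity is not None and e.velocity > thr.thr_v1:
            e.stress = RUNNING

    # --- walking 1/2/3: moving runs with context ---------------------------
    run_start = None
    runs: List[Tuple[int, int]] = []
    for i in range(n + 1):
        moving = i < n and out[i].attribute == MOVEMENT and out[i].camera_id is not None
        if moving and run_start is None:
            run_start = i
        elif not moving and run_start is not None:
            runs.append((run_start, i - 1))
            run_start = None
    for s, e_ in runs:
        context = _preceding_context(out, s, cfgs, fps, params)
        pts = [out[i].position for i in range(s, e_ + 1) if out[i].position]
        has_height = _path_has_height(pts, params.height_dist)
        for i in range(s, e_ + 1):
            entry = out[i]
            if entry.stress is not None or entry.velocity is None:
                continue
            v = entry.velocity
            if thr.thr_v2 < v < thr.thr_v1:
                if context == "full":
                    entry.stress = WALKING1
                elif context == "housing":
                    entry.stress = WALKING2
            elif thr.thr_v3 < v < thr.thr_v2:
                if context == "housing" and has_height:
                    entry.stress = WALKING3

    episodes = _group_episodes(out, fps, params)
    return out, episodes


def _group_episodes(
    entries: Sequence[TrackEntry], fps: float, params: StressParams
) -> List[StressEpisode]:
    """Group consecutive same-label entries; bridge sub-minimum gaps; drop
    fragments shorter than the minimum episode duration."""
    min_frames = max(1, int(round(params.min_episode_s * fps)))
    labeled: List[Tuple[str, int, int]] = []
    cur = None
    start = 0
    for i in range(len(entries) + 1):
        lab = entries[i].stress if i < len(entries) else None
        if lab != cur:
            if cur is not None:
                labeled.append((cur, start, i - 1))
            cur = lab
            start = i
    # bridge short unlabeled gaps between same-class segments
    merged: List[Tuple[str, int, int]] = []
    for seg in labeled:
        if (
            merged
            and merged[-1][0] == seg[0]
            and seg[1] - merged[-1][2] - 1 < min_frames
        ):
            merged[-1] = (seg[0], merged[-1][1], seg[2])
        else:
            merged.append(seg)
    episodes = []
    for lab, s, e in merged:
        dur = (e - s + 1) / fps
        if lab == STATIONARY and dur <= params.stationary_min_s:
            continue
        if e - s + 1 < min_frames:
            continue
        cams = [x.camera_id for x in entries[s : e + 1] if x.camera_id is not None]
        cam = max(set(cams), key=cams.count) if cams else None
        episodes.append(StressEpisode(lab, s, e, dur, cam))
    return episodes
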