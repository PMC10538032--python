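"""Per-camera panda tracking state machine.

Each of the four habitat cameras runs an independent tracking session driven
by the strength of the motion signal (``features_nmb`` of the masked motion
image) against three thresholds ``low < mid < high``:

* above ``high`` — session (re)start; when the movement rectangle is tall
  (caretaker profile) and sits in the technician gate, the whole session is
  flagged ``zoo_technician`` and its frames are excluded from fusion;
* between ``mid`` and ``high`` — a normal movement frame, subject to the
  validation rules (area bursts, far jumps, direction disagreement, bird
  suppression on the general-view cameras);
* between ``low`` and ``mid`` — door-area watching after an exit, or freezing
  when the rectangle is nearly static in a visible non-door zone;
* below ``low`` — freezing when the animal was previously seen in an
  observable zone (keeps the session alive through relaxation pauses),
  otherwise ``no_information``.

A special search restriction handles bathing behind the camera-8 foreground
stones, where pond ripples flood the basin with motion traits while the bear
itself is invisible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from zootrack.motion_core import (
    ConfigurationError,
    MotionImage,
    MovementCluster,
    Rect,
    RegionPolygon,
    counting_box_cluster,
    mask_outside_region,
    point_in_polygon,
)

__all__ = [
    "Zone",
    "CameraConfig",
    "MotionThresholds",
    "FrameObservation",
    "PandaCameraTracker",
    "session_gate",
    "classify_frame",
    "validate_movement_frame",
]

Point = Tuple[float, float]

MOVEMENT = "movement"
FREEZING = "freezing"
NO_INFORMATION = "no_information"


@dataclass(frozen=True)
class Zone:
    """A visible (observable) zone with its habitat role and fusion rank."""

    polygon: RegionPolygon
    name: str
    kind: str = "full"  # full | door | housing | partial | basin
    rank: int = 0  # lower ranks win at fusion


@dataclass
class CameraConfig:
    camera_id: int
    resolution: Tuple[int, int]  # (w, h)
    info_polygon: RegionPolygon
    panda_gates: List[Rect] = field(default_factory=list)
    technician_gate: Optional[Rect] = None
    visible_zones: List[Zone] = field(default_factory=list)
    zone_correspondence: Dict[str, List[Tuple[int, str]]] = field(default_factory=dict)
    general_view: bool = False
    basin_zone: Optional[Rect] = None
    velocity_weight: float = 1.0

    def zone_of(self, p: Optional[Point]) -> Optional[Zone]:
        if p is None:
            return None
        for z in self.visible_zones:
            if point_in_polygon(p, z.polygon):
                return z
        return None


@dataclass
class MotionThresholds:
    low_features_nmb_thr: int = 20
    features_nmb_thr: int = 60
    high_features_nmb_thr: int = 1500

    def __post_init__(self) -> None:
        if not (
            self.low_features_nmb_thr
            < self.features_nmb_thr
            < self.high_features_nmb_thr
        ):
            raise ConfigurationError("thresholds must satisfy low < mid < high")


@dataclass
class FrameObservation:
    frame_index: int
    camera_id: int
    rect: Optional[Rect]
    attribute: str = NO_INFORMATION
    zoo_technician: int = 0
    session_active: bool = False

    def __post_init__(self) -> None:
        if self.attribute == MOVEMENT and self.rect is None:
            raise ConfigurationError("movement observation requires a rectangle")

    @property
    def position(self) -> Optional[Point]:
        return None if self.rect is None else self.rect.center


@dataclass
class TrackerParams:
    """Behavioral knobs of the per-camera state machine (pixel units)."""

    box_w: int = 40
    box_h: int = 40
    area_burst_ratio: float = 3.0
    far_factor: float = 2.0  # × rect diagonal per frame = "far away"
    static_series_end: int = 900  # session ends after this many static frames
    technician_height_frac: float = 0.55
    near_static_dist: float = 6.0
    confine_radius: int = 60  # search confinement around the last position
    basin_restrain_radius: int = 50
    direction_max_angle_deg: float = 90.0
    freeze_max: int = 50  # frames: freezing decays to no_information after this


def _movement_rect(m: MotionImage, cluster: MovementCluster) -> Rect:
    """Bounding box of the connected feature mass overlapping the winning box.

    The counting box itself has fixed size; the movement rectangle must follow
    the real extent of the mover (the caretaker profile is a *tall* rectangle).
    """
    labels, n = ndimage.label(m.features)
    if n == 0:
        return cluster.box
    b = cluster.box.intersect(Rect(0, 0, m.features.shape[1], m.features.shape[0]))
    window = labels[b.y : b.y + b.h, b.x : b.x + b.w]
    ids = np.unique(window[window > 0])
    if len(ids) == 0:
        return cluster.box
    sel = np.isin(labels, ids)
    ys, xs = np.nonzero(sel)
    return Rect(
        int(xs.min()), int(ys.min()),
        int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1),
    )


def session_gate(
    m: MotionImage,
    cluster: Optional[MovementCluster],
    cfg: CameraConfig,
    thr: MotionThresholds,
    prev: Optional[FrameObservation],
    params: Optional[TrackerParams] = None,
    fused_prev_zone: Optional[Tuple[int, str]] = None,
) -> Tuple[Optional[str], int]:
    """Decide whether a tracking session starts on this frame.

    Returns (start reason or None, zoo_technician flag). Reasons: 'high'
    (strong burst, possibly the caretaker), 'gate' (movement in a gate area),
    'previous' (movement at the previous valid position), 'handoff' (movement
    in the zone corresponding to the previously fused view of another camera).
    """
    params = params or TrackerParams()
    if cluster is None:
        return None, 0
    f = m.features_nmb
    pos = cluster.mass_center
    if f > thr.high_features_nmb_thr:
        rect = _movement_rect(m, cluster)
        tall = rect.h > params.technician_height_frac * cfg.resolution[1]
        in_tech_gate = (
            cfg.technician_gate is not None
            and cfg.technician_gate.intersect(rect).area > 0
        )
        return "high", int(tall and in_tech_gate)
    if f > thr.features_nmb_thr:
        if any(g.contains(pos) for g in cfg.panda_gates):
            return "gate", 0
        if (
            prev is not None
            and prev.session_active
            and prev.rect is not None
            and math.dist(pos, prev.rect.center) < params.confine_radius
        ):
            return "previous", 0
        if fused_prev_zone is not None:
            for zone_name, partners in cfg.zone_correspondence.items():
                if fused_prev_zone in partners or (
                    fused_prev_zone[0] == cfg.camera_id
                    and fused_prev_zone[1] == zone_name
                ):
                    z = next(
                        (z for z in cfg.visible_zones if z.name == zone_name), None
                    )
                    if z is not None and point_in_polygon(pos, z.polygon):
                        return "handoff", 0
    return None, 0


def classify_frame(
    features_nmb: int,
    cluster: Optional[MovementCluster],
    prev: Optional[FrameObservation],
    cfg: CameraConfig,
    thr: MotionThresholds,
    params: Optional[TrackerParams] = None,
    door_watch: bool = False,
) -> str:
    """Three-band frame attribute decision for an active session.

    Returns one of movement / freezing / no_information (movement still
    subject to validation by the caller).
    """
    params = params or TrackerParams()
    prev_attr = prev.attribute if prev is not None else NO_INFORMATION
    prev_pos = prev.position if prev is not None else None
    if features_nmb > thr.features_nmb_thr:
        return MOVEMENT
    if features_nmb < thr.low_features_nmb_thr:
        if prev_attr == MOVEMENT and cfg.zone_of(prev_pos) is not None:
            return FREEZING
        if prev_attr == FREEZING:
            return FREEZING
        return NO_INFORMATION
    # mid band
    if door_watch:
        return NO_INFORMATION  # restricted door watching continues
    if cluster is not None and prev_pos is not None:
        zone = cfg.zone_of(cluster.mass_center)
        if (
            zone is not None
            and zone.kind != "door"
            and math.dist(cluster.mass_center, prev_pos) <= params.near_static_dist
        ):
            return FREEZING
    return NO_INFORMATION


def validate_movement_frame(
    rect: Rect,
    history: Sequence[FrameObservation],
    fused_prev: Optional["object"],
    cfg: CameraConfig,
    body_check: Optional[Point] = None,
    params: Optional[TrackerParams] = None,
) -> bool:
    """Accept or reject a pre-classified movement rectangle.

    Rejections: (a) area burst over the previous movement area; (b) far jump
    from the previous position in a visible area; (c) disagreement with the
    previous motion direction; branch-play (body found near the previous
    position while the rectangle jumped); bird suppression on general-view
    cameras via the zone-correspondence of the previously fused view.
    """
    params = params or TrackerParams()
    prev_rects = [h.rect for h in history if h.rect is not None]
    if prev_rects:
        prev_rect = prev_rects[-1]
        if rect.area > params.area_burst_ratio * prev_rect.area:
            return False  # (a) bursting, huge movement (flare)
        dist = math.dist(rect.center, prev_rect.center)
        far = dist > params.far_factor * prev_rect.diagonal
        if far and cfg.zone_of(rect.center) is not None:
            if body_check is not None:
                # branch play: the panda corpus is still near the old position
                if math.dist(body_check, prev_rect.center) < params.near_static_dist * 2:
                    return False
            else:
                return False  # (b) far away in a visible area
        if len(prev_rects) >= 2:
            p0, p1 = prev_rects[-2].center, prev_rects[-1].center
            v_prev = (p1[0] - p0[0], p1[1] - p0[1])
            v_cur = (rect.center[0] - p1[0], rect.center[1] - p1[1])
            n_prev = math.hypot(*v_prev)
            n_cur = math.hypot(*v_cur)
            # only meaningful for brisk motion; slow drift directions are noise
            if n_prev > 8.0 and n_cur > 8.0:
                cosang = (v_prev[0] * v_cur[0] + v_prev[1] * v_cur[1]) / (
                    n_prev * n_cur
                )
                if cosang < math.cos(math.radians(params.direction_max_angle_deg)):
                    return False  # (c) direction disagreement
    if cfg.general_view and fused_prev is not None:
        # bird suppression: require the rectangle in a zone corresponding to
        # the previously fused (camera, zone) pair
        fused_cam = getattr(fused_prev, "camera_id", None)
        fused_zone = getattr(fused_prev, "zone_name", None)
        if fused_cam is not None and fused_zone is not None:
            ok = False
            for zone_name, partners in cfg.zone_correspondence.items():
                same = fused_cam == cfg.camera_id and fused_zone == zone_name
                if same or (fused_cam, fused_zone) in partners:
                    z = next(
                        (z for z in cfg.visible_zones if z.name == zone_name), None
                    )
                    if z is not None and point_in_polygon(rect.center, z.polygon):
                        ok = True
                        break
            if not ok:
                return False
    return True


class PandaCameraTracker:
    """Stateful per-camera loop producing one FrameObservation per frame."""

    def __init__(
        self,
        cfg: CameraConfig,
        thr: Optional[MotionThresholds] = None,
        params: Optional[TrackerParams] = None,
    ) -> None:
        self.cfg = cfg
        self.thr = thr or MotionThresholds()
        self.params = params or TrackerParams()
        self.session_active = False
        self.zoo_technician = 0
        self.door_watch = False
        self.static_run = 0
        self.freeze_run = 0
        self.history: List[FrameObservation] = []
        self.last_rect: Optional[Rect] = None

    # -- search-region policy ------------------------------------------------
    def _search_rect(self) -> Optional[Rect]:
        p = self.params
        w, h = self.cfg.resolution
        if not self.session_active or self.last_rect is None:
            return None  # whole masked motion zone
        cx, cy = self.last_rect.center
        if self.door_watch:
            for g in self.cfg.panda_gates:
                if g.contains((cx, cy)) or math.dist((cx, cy), g.center) < p.confine_radius:
                    return g
        if (
            self.cfg.basin_zone is not None
            and math.dist((cx, cy), self.cfg.basin_zone.center)
            < self.cfg.basin_zone.diagonal
        ):
            # bath behind the foreground stones: restrain beside last position
            r = p.basin_restrain_radius
            return Rect(int(cx) - r, int(cy) - r, 2 * r, 2 * r)
        if self.history and self.history[-1].attribute == MOVEMENT:
            r = p.confine_radius
            return Rect(int(cx) - r, int(cy) - r, 2 * r, 2 * r)
        return None

    def step(
        self,
        m: MotionImage,
        frame_index: int,
        fused_prev=None,
        fused_prev_zone: Optional[Tuple[int, str]] = None,
    ) -> FrameObservation:
        cfg, thr, params = self.cfg, self.thr, self.params
        m = mask_outside_region(m, cfg.info_polygon)
        search = self._search_rect()
        cluster = counting_box_cluster(
            m, search=search, box_w=params.box_w, box_h=params.box_h,
            relevance_thr=thr.features_nmb_thr,
        )
        if cluster is None and search is not None:
            # widen to the entire ray-cast motion zone
            cluster = counting_box_cluster(
                m, box_w=params.box_w, box_h=params.box_h,
                relevance_thr=thr.features_nmb_thr,
            )
        f = m.features_nmb

        if not self.session_active:
            # a previous valid position allows the restart rule even after the
            # session was canceled ("the precedent tracking session provided
            # valid results")
            prev_for_gate = None
            if self.last_rect is not None:
                prev_for_gate = FrameObservation(
                    frame_index - 1, cfg.camera_id, self.last_rect, FREEZING, 0, True
                )
            reason, tech = session_gate(
                m, cluster, cfg, thr, prev_for_gate, params, fused_prev_zone,
            )
            if reason is None:
                obs = FrameObservation(frame_index, cfg.camera_id, None,
                                       NO_INFORMATION, 0, False)
                self.history.append(obs)
                return obs
            self.session_active = True
            self.zoo_technician = tech
            self.static_run = 0

        attr = classify_frame(
            f, cluster, self.history[-1] if self.history else None, cfg, thr,
            params, self.door_watch,
        )
        rect: Optional[Rect] = None
        if attr == MOVEMENT and cluster is not None:
            rect = _movement_rect(m, cluster)
            if self.zoo_technician == 0 and not validate_movement_frame(
                rect, self.history[-8:], fused_prev, cfg, None, params
            ):
                attr = NO_INFORMATION
                rect = None
        if (
            attr == FREEZING
            and self.last_rect is not None
            and any(g.intersect(self.last_rect).area > 0 for g in cfg.panda_gates)
        ):
            # motion died away inside a gate: the animal exited; end the session
            attr = NO_INFORMATION
            self.session_active = False
            self.zoo_technician = 0
            self.last_rect = None
            self.door_watch = False
        if attr == FREEZING and rect is None:
            rect = self.last_rect  # animal present but motionless
        if attr == FREEZING and rect is not None:
            # a last position hugging the frame border means the animal most
            # likely left this view rather than froze: do not hold it
            margin = 16
            w_res, h_res = cfg.resolution
            cx, cy = rect.center
            if not (margin <= cx <= w_res - margin and margin <= cy <= h_res - margin):
                attr = NO_INFORMATION
                rect = None
        if attr == FREEZING:
            self.freeze_run += 1
            if self.freeze_run > params.freeze_max:
                # long uninterrupted freezing: demote to no_information so a
                # stale position does not dominate fusion indefinitely
                attr = NO_INFORMATION
                rect = None
        else:
            self.freeze_run = 0

        # the caretaker reads as a frame-tall rectangle on any camera; the
        # profile applies to carried (freezing) rectangles as well
        tech_frame = (
            rect is not None
            and rect.h > params.technician_height_frac * cfg.resolution[1]
        )

        # bookkeeping: door watching, static-run session end, exits
        if rect is not None and attr == MOVEMENT:
            self.last_rect = rect
            self.static_run = 0
            self.door_watch = any(g.intersect(rect).area > 0 for g in cfg.panda_gates)
        else:
            self.static_run += 1
        if self.static_run > params.static_series_end:
            self.session_active = False
            self.zoo_technician = 0
        if attr == NO_INFORMATION and not self.door_watch and (
            self.history and self.history[-1].attribute == NO_INFORMATION
        ):
            # two consecutive uninformative frames outside a door watch:
            # cancel the session ("the watching was canceled"); the last valid
            # position is retained for the restart rule
            self.session_active = False
            self.zoo_technician = 0

        obs = FrameObservation(
            frame_index, cfg.camera_id, rect, attr,
            max(self.zoo_technician, int(tech_frame)), self.session_active,
        )
        self.history.append(obs)
        if len(self.history) > 32:
            self.history = self.history[-32:]
        return obs
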