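"""Monkey sensor-box localization and head-orientation estimation.

The monkey carries a dark, rectangular sensor box on its head. The cage is
unevenly illuminated and the animal can switch the light at any moment, so
plain appearance tracking is unreliable; localization couples the shared
motion-feature method with three safeguards:

* a gray-level template ("model") of the box, created only under strict
  conditions (relevant motion cluster, Canny edge count near the cluster
  center within the range typical of the box border, edge-free immediate
  center, dark neighborhood, lit scene) and updated after every accepted
  position;
* normalized cross-correlation of that template to validate positions close
  to the previous one;
* a confidence index combining the per-region reliability weight, the match
  score and an iteration penalty — only localizations with confidence
  strictly above 75% feed the orientation analysis.

Head orientation is the direction of the long side of the minimum-area
bounding rectangle of the best (highest filling-index) dark contour in the
inflated ROI around an accepted localization; the per-frame angle series is
cleaned with a 1-D windowed mean that skips missing and low-confidence
entries and fills gaps.

Angles are degrees in [0, 180), measured counter-clockwise from the +x axis
with y pointing up (i.e. screen-down angles are negative before wrapping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage.feature import canny as sk_canny
from skimage.feature import match_template

from zootrack.motion_core import (
    GrayFrame,
    MovementCluster,
    Rect,
    RegionPolygon,
    compute_motion_image,
    counting_box_cluster,
    mask_outside_region,
    point_in_polygon,
    _as_pixels,
)

__all__ = [
    "MonkeyModel",
    "Localization",
    "OrientationRecord",
    "RegionReliability",
    "MonkeyConfig",
    "MonkeyTracker",
    "detect_light_state",
    "try_init_model",
    "compute_confidence",
    "compute_orientation",
    "filter_angles",
]

Point = Tuple[float, float]


@dataclass
class MonkeyModel:
    template: np.ndarray
    origin: Point
    created_frame: int


@dataclass
class Localization:
    position: Point
    confidence: float
    region_id: int
    iteration: int = 1
    match_score: Optional[float] = None

    @property
    def useful(self) -> bool:
        """Strict gate: only confidence > 75% enters further analysis."""
        return self.confidence > 75.0


@dataclass
class OrientationRecord:
    frame_index: int
    angle_deg: Optional[float]
    confidence: float
    filled: bool = False

    def __post_init__(self) -> None:
        if self.angle_deg is not None:
            self.angle_deg = float(self.angle_deg) % 180.0


@dataclass
class RegionReliability:
    """Four cage areas with experimentally assigned reliability weights."""

    polygons: List[RegionPolygon]
    weights: List[float]
    default_weight: float = 0.5

    def __post_init__(self) -> None:
        if any(not (0 <= w <= 1) for w in self.weights):
            raise ValueError("reliability weights must lie in [0, 1]")

    def lookup(self, p: Point) -> Tuple[int, float]:
        for i, (poly, w) in enumerate(zip(self.polygons, self.weights)):
            if point_in_polygon(p, poly):
                return i, w
        return -1, self.default_weight


@dataclass
class MonkeyConfig:
    light_thr: float = 60.0
    motion_threshold: float = 15.0
    template_size: int = 32
    box_w: int = 40
    box_h: int = 40
    relevance_thr: int = 30
    very_relevant_thr: int = 120
    canny_sigma: float = 2.0
    canny_low: float = 0.1
    canny_high: float = 0.25
    edge_neighborhood: int = 24  # half-size of the edge-count window
    edge_range: Tuple[int, int] = (30, 2000)
    center_free_radius: int = 3
    dark_thr: float = 80.0
    dark_radius: int = 6
    match_accept: float = 0.7
    vicinity_factor: float = 1.5  # × template diagonal = "close vicinity"
    iteration_penalty: float = 0.9
    great_features: int = 400
    uniform_std: float = 4.0
    # orientation
    area_min: int = 500
    orient_threshold_range: Tuple[float, float] = (30.0, 60.0)
    gaussian_sigma: float = 1.5
    filter_window: int = 11
    conf_thr: float = 75.0


def detect_light_state(frame, thr: float = 60.0) -> str:
    """'on' iff the mean frame intensity reaches ``thr``."""
    return "on" if float(_as_pixels(frame).mean()) >= thr else "off"


def _canny_map(pix: np.ndarray, cfg: MonkeyConfig) -> np.ndarray:
    # contrast-normalized so box edges survive the light-off dimming
    lo, hi = float(pix.min()), float(pix.max())
    norm = (pix - lo) / max(hi - lo, 1.0)
    return sk_canny(
        norm, sigma=cfg.canny_sigma, low_threshold=cfg.canny_low,
        high_threshold=cfg.canny_high,
    )


def _edge_conditions(canny_edges: np.ndarray, center: Point, cfg: MonkeyConfig) -> bool:
    h, w = canny_edges.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    k = cfg.edge_neighborhood
    win = canny_edges[max(0, cy - k) : cy + k + 1, max(0, cx - k) : cx + k + 1]
    n_edges = int(win.sum())
    if not (cfg.edge_range[0] <= n_edges <= cfg.edge_range[1]):
        return False
    r = cfg.center_free_radius
    center_win = canny_edges[max(0, cy - r) : cy + r + 1, max(0, cx - r) : cx + r + 1]
    return int(center_win.sum()) == 0


def try_init_model(
    frame,
    cluster: Optional[MovementCluster],
    canny_edges: np.ndarray,
    light: str,
    cfg: Optional[MonkeyConfig] = None,
) -> Optional[MonkeyModel]:
    """Create the gray-level model when the strict (a)–(c) conditions hold.

    (a) the cluster is relevant; (b) the Canny edge count near its mass center
    is in the box-border range and the immediate center is edge-free; (c) the
    center neighborhood is dark. Only possible with the scene illuminated.
    """
    cfg = cfg or MonkeyConfig()
    if light != "on" or cluster is None or not cluster.relevant:
        return None
    pix = _as_pixels(frame)
    cx, cy = cluster.mass_center
    if not _edge_conditions(canny_edges, (cx, cy), cfg):
        return None
    r = cfg.dark_radius
    icx, icy = int(round(cx)), int(round(cy))
    neigh = pix[max(0, icy - r) : icy + r + 1, max(0, icx - r) : icx + r + 1]
    if neigh.size == 0 or float(neigh.mean()) >= cfg.dark_thr:
        return None
    template = _extract_patch(pix, (cx, cy), cfg.template_size)
    if template is None:
        return None
    fi = frame.frame_index if isinstance(frame, GrayFrame) else 0
    return MonkeyModel(template=template, origin=(cx, cy), created_frame=fi)


def _extract_patch(pix: np.ndarray, center: Point, size: int) -> Optional[np.ndarray]:
    h, w = pix.shape
    half = size // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    x0, y0 = cx - half, cy - half
    if x0 < 0 or y0 < 0 or x0 + size > w or y0 + size > h:
        return None
    return pix[y0 : y0 + size, x0 : x0 + size].copy()


def _match_near(pix: np.ndarray, model: MonkeyModel, center: Point, radius: int):
    """NCC of the model template in a window around ``center``.

    Returns (score, matched_center) or (None, None) if the window is too small.
    """
    h, w = pix.shape
    size = model.template.shape[0]
    half = size // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    x0 = max(0, cx - half - radius)
    y0 = max(0, cy - half - radius)
    x1 = min(w, cx + half + radius + 1)
    y1 = min(h, cy + half + radius + 1)
    win = pix[y0:y1, x0:x1]
    if win.shape[0] < size or win.shape[1] < size:
        return None, None
    resp = match_template(win, model.template)
    iy, ix = np.unravel_index(int(np.argmax(resp)), resp.shape)
    score = float(resp[iy, ix])
    return score, (x0 + ix + half, y0 + iy + half)


def _refine_dark_center(pix: np.ndarray, center: Point, cfg: MonkeyConfig) -> Point:
    """Snap a coarse position to the centroid of the dark box mass nearby.

    The sensor box reads as the darkest compact area; a window-relative
    threshold keeps this valid under light-off dimming.
    """
    h, w = pix.shape
    half = cfg.template_size
    pos = center
    for _ in range(2):  # second pass removes window-clipping bias
        cx, cy = int(round(pos[0])), int(round(pos[1]))
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        win = pix[y0:y1, x0:x1]
        if win.size == 0:
            return pos
        lo, hi = float(win.min()), float(win.max())
        if hi - lo < 10.0:
            return pos
        thr = lo + 0.4 * (hi - lo)
        ys, xs = np.nonzero(win < thr)
        if len(xs) == 0:
            return pos
        pos = (x0 + float(xs.mean()), y0 + float(ys.mean()))
    return pos


def compute_confidence(
    region_weight: float,
    match_score: Optional[float],
    iteration: int,
    features: int,
    cfg: Optional[MonkeyConfig] = None,
) -> float:
    """Confidence percent: region weight × match score × iteration penalty.

    The penalty is ``p^(iteration-1)``, with one extra factor of ``p`` when
    the localization was not found at the first iteration and the motion-trait
    count is great (shadow-like bursts); monotone non-increasing in iteration.
    """
    cfg = cfg or MonkeyConfig()
    if not (0.0 <= region_weight <= 1.0):
        raise ValueError("region_weight must lie in [0, 1]")
    conf = 100.0 * region_weight
    if match_score is not None:
        conf *= max(0.0, min(1.0, match_score))
    conf *= cfg.iteration_penalty ** (iteration - 1)
    if iteration > 1 and features > cfg.great_features:
        conf *= cfg.iteration_penalty
    return conf


class MonkeyTracker:
    """Stateful per-frame localization loop for one recording session."""

    def __init__(
        self,
        info_polygon: RegionPolygon,
        regions: RegionReliability,
        cfg: Optional[MonkeyConfig] = None,
    ) -> None:
        self.info_polygon = info_polygon
        self.regions = regions
        self.cfg = cfg or MonkeyConfig()
        self.model: Optional[MonkeyModel] = None
        self.prev: Optional[Localization] = None
        self._buffer: List[np.ndarray] = []
        self.restarted: bool = False

    def _restart(self) -> None:
        self.model = None
        self.prev = None
        self.restarted = True

    def step(self, frame) -> Optional[Localization]:
        """Process one frame; returns the accepted localization or ``None``."""
        cfg = self.cfg
        pix = _as_pixels(frame)
        fi = frame.frame_index if isinstance(frame, GrayFrame) else len(self._buffer)
        self.restarted = False
        light = detect_light_state(pix, cfg.light_thr)
        if float(pix.std()) < cfg.uniform_std:  # uniform frame: full restart
            self._restart()
            self._buffer = []
            return None
        if len(self._buffer) < 2:
            self._buffer.append(pix)
            return None
        ib, ic = self._buffer[-1], self._buffer[-2]
        self._buffer = [ib, pix]
        m = compute_motion_image(pix, ib, ic, threshold=cfg.motion_threshold)
        m = mask_outside_region(m, self.info_polygon)
        diag = cfg.template_size * math.sqrt(2.0)
        vicinity = cfg.vicinity_factor * diag

        loc = self._iteration_near_prev(pix, m, light, fi, vicinity)
        iteration = 1
        if loc is None:
            loc = self._iteration_global(pix, m, light, fi, vicinity)
            iteration = 2
        if loc is None:
            return None
        loc.position = _refine_dark_center(pix, loc.position, cfg)
        loc.region_id = self.regions.lookup(loc.position)[0]
        loc.iteration = iteration
        loc.confidence = compute_confidence(
            self.regions.lookup(loc.position)[1],
            loc.match_score,
            iteration,
            m.features_nmb,
            cfg,
        )
        # model update after every accepted position
        patch = _extract_patch(pix, loc.position, cfg.template_size)
        if patch is not None:
            if self.model is None:
                self.model = MonkeyModel(patch, loc.position, fi)
            else:
                self.model = MonkeyModel(patch, loc.position, self.model.created_frame)
        self.prev = loc
        return loc

    # -- iteration 1: restricted search near the previous position ---------
    def _iteration_near_prev(self, pix, m, light, fi, vicinity):
        cfg = self.cfg
        if self.prev is None:
            return None
        px, py = self.prev.position
        r = int(vicinity)
        search = Rect(int(px) - r, int(py) - r, 2 * r, 2 * r)
        cluster = counting_box_cluster(
            m, search=search, box_w=cfg.box_w, box_h=cfg.box_h,
            relevance_thr=cfg.relevance_thr,
        )
        canny_edges = _canny_map(pix, cfg)
        anchors = []
        if cluster is not None and cluster.relevant:
            anchors.append((cluster.mass_center, 16))
        anchors.append(((px, py), 8))
        if self.model is not None:
            for anchor, radius in anchors:
                score, pos = _match_near(pix, self.model, anchor, radius=radius)
                if (
                    score is not None
                    and score >= cfg.match_accept
                    and _edge_conditions(canny_edges, pos, cfg)
                ):
                    rid, _ = self.regions.lookup(pos)
                    return Localization(pos, 0.0, rid, match_score=score)
        if cluster is not None and cluster.relevant and _edge_conditions(
            canny_edges, cluster.mass_center, cfg
        ):
            rid, _ = self.regions.lookup(cluster.mass_center)
            return Localization(cluster.mass_center, 0.0, rid)
        return None

    # -- iteration 2: global search, possible restart and model synthesis --
    def _iteration_global(self, pix, m, light, fi, vicinity):
        cfg = self.cfg
        cluster = counting_box_cluster(
            m, box_w=cfg.box_w, box_h=cfg.box_h, relevance_thr=cfg.relevance_thr
        )
        if cluster is None or not cluster.relevant:
            return None
        far = (
            self.prev is not None
            and math.dist(cluster.mass_center, self.prev.position) > vicinity
        )
        if far and cluster.feature_count < cfg.very_relevant_thr:
            return None  # far but not convincing: ignore
        if light == "off" and far:
            return None  # shadow features must not restart tracking in the dark
        canny_edges = _canny_map(pix, cfg)
        frame_like = GrayFrame(pix, frame_index=fi)
        model = try_init_model(frame_like, cluster, canny_edges, light, cfg)
        if model is None:
            return None
        if far or self.prev is None:
            self.restarted = True
        self.model = model
        rid, _ = self.regions.lookup(cluster.mass_center)
        return Localization(cluster.mass_center, 0.0, rid)


# ---------------------------------------------------------------------------
# Head orientation
# ---------------------------------------------------------------------------

def _value_channel(frame) -> np.ndarray:
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    # HSV value channel is the per-pixel max over RGB
    return arr[..., :3].max(axis=2)


def _min_area_rect_angle(coords: np.ndarray) -> Tuple[float, float]:
    """Minimum-area bounding rectangle of pixel coordinates (row, col).

    Returns (rect_area, angle of the long side in [0, 180), y-up convention).
    """
    pts = MultiPoint([(float(c), float(r)) for r, c in coords])
    rect = pts.convex_hull.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate (collinear) region
        return 0.0, 0.0
    xs, ys = rect.exterior.coords.xy
    corners = list(zip(xs, ys))[:4]
    e1 = math.dist(corners[0], corners[1])
    e2 = math.dist(corners[1], corners[2])
    if e1 >= e2:
        dx = corners[1][0] - corners[0][0]
        dy = corners[1][1] - corners[0][1]
    else:
        dx = corners[2][0] - corners[1][0]
        dy = corners[2][1] - corners[1][1]
    angle = math.degrees(math.atan2(-dy, dx)) % 180.0
    return float(rect.area), angle


def compute_orientation(
    frame,
    loc: Localization,
    area_min: int = 500,
    cfg: Optional[MonkeyConfig] = None,
) -> Optional[float]:
    """Orientation of the sensor box around an accepted localization.

    The ROI (model-sized window at the localization) is inflated by half its
    dimensions in every direction; the HSV value channel is Gaussian-smoothed
    and binarized with a brightness-dependent threshold in [30, 60]; among the
    dark contours with area above ``area_min`` the one with the highest
    filling index (contour area / min-area-rectangle area) gives the angle of
    its long rectangle side. Returns ``None`` when no contour qualifies.
    """
    cfg = cfg or MonkeyConfig()
    value = _value_channel(frame)
    h, w = value.shape
    size = cfg.template_size
    # primary ROI inflated by half of its measures in every direction
    half = size  # size/2 primary half-extent + size/2 inflation on each side
    cx, cy = int(round(loc.position[0])), int(round(loc.position[1]))
    x0, x1 = max(0, cx - half), min(w, cx + half + 1)
    y0, y1 = max(0, cy - half), min(h, cy + half + 1)
    roi = value[y0:y1, x0:x1]
    if roi.size == 0:
        return None
    roi = ndimage.gaussian_filter(roi, cfg.gaussian_sigma)
    lo, hi = cfg.orient_threshold_range
    thr = lo + (hi - lo) * min(1.0, float(roi.mean()) / 255.0)
    binary = roi < thr
    labels, n = ndimage.label(binary)
    best_angle = None
    best_fill = -1.0
    for region in range(1, n + 1):
        coords = np.argwhere(labels == region)
        area = len(coords)
        if area <= area_min or area > 0.8 * roi.size:
            continue
        rect_area, angle = _min_area_rect_angle(coords)
        if rect_area <= 0:
            continue
        fill = area / rect_area
        if fill > best_fill:
            best_fill = fill
            best_angle = angle
    return best_angle


def filter_angles(
    series: Sequence[OrientationRecord],
    t: int = 11,
    conf_thr: float = 75.0,
) -> List[OrientationRecord]:
    """1-D windowed average of the angle series.

    Each angle is replaced by the mean over the valid entries (angle computed,
    confidence ≥ ``conf_thr``) of the size-``t`` window centered on it; missing
    angles are estimated the same way and flagged ``filled``. Angles are
    unwrapped modulo 180° about the window median before averaging to handle
    the 0/180 wrap. Windows without any valid entry leave the angle missing.
    """
    if t % 2 == 0:
        raise ValueError("window size t must be odd")
    half = t // 2
    n = len(series)
    out: List[OrientationRecord] = []
    for i, rec in enumerate(series):
        vals = [
            r.angle_deg
            for r in series[max(0, i - half) : min(n, i + half + 1)]
            if r.angle_deg is not None and r.confidence >= conf_thr and not r.filled
        ]
        if not vals:
            out.append(OrientationRecord(rec.frame_index, rec.angle_deg,
                                         rec.confidence, rec.filled))
            continue
        med = float(np.median(vals))
        unwrapped = [((v - med + 90.0) % 180.0) - 90.0 + med for v in vals]
        mean = float(np.mean(unwrapped)) % 180.0
        out.append(
            OrientationRecord(rec.frame_index, mean, rec.confidence,
                              filled=rec.angle_deg is None)
        )
    return out
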