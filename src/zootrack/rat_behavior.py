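"""Rat behavior analysis: head pose (stage 1) and compartment visits (stage 2).

Stage 1 (top view): the three-chamber box is analyzed per frame. An adaptive
binarization threshold is searched until the column projection of the binary
(dark-pixel) image shows exactly five clusters: outer-left wall, interior-left
wall, the rat itself, interior-right wall, outer-right wall. The middle-room
walls ``b1``/``b2`` are the midpoints of clusters 2 and 4. The rat body is the
largest eroded blob between the interior walls; its head is located by a
two-vote scheme (flank pixel-count asymmetry vs. tail detection in thin strips
outside the body box) with ambiguous cases deferred and resolved offline.

Stage 2 (side view): cage limits ``c11 < c12 < b1 < b2 < c21 < c22`` are
recomputed per frame from the tall-column projection (the experimenter may nudge
the camera); the free rat is tracked with the shared motion-feature method and
its compartment (left cage / middle / right cage) is decided from the mass-center
x against ``b1``/``b2``. Entries and visit durations are reported with a
debounce guard against boundary flicker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from zootrack.motion_core import (
    ConfigurationError,
    GrayFrame,
    Rect,
    compute_motion_image,
    counting_box_cluster,
    _as_pixels,
)

__all__ = [
    "SceneWallsStage1",
    "CageParams",
    "BodyBox",
    "HeadDecision",
    "VisitRecord",
    "Stage1Config",
    "Stage2Config",
    "compute_scene_walls",
    "detect_rat_blob",
    "locate_head",
    "resolve_trajectory",
    "compute_cage_params",
    "track_stage2",
    "analyze_visits",
]

Point = Tuple[float, float]

LEFT_CAGE = "left_cage"
MIDDLE = "middle"
RIGHT_CAGE = "right_cage"


class UnresolvedSessionError(RuntimeError):
    """No certain head decision exists anywhere in the session."""


@dataclass
class SceneWallsStage1:
    """Five projection clusters and the derived middle-room wall columns."""

    cluster_bounds: List[Tuple[int, int]]
    b1: int
    b2: int
    bin_thr: float

    def __post_init__(self) -> None:
        if len(self.cluster_bounds) != 5:
            raise ConfigurationError("exactly five clusters required")
        flat = [v for se in self.cluster_bounds for v in se]
        if any(a > b for a, b in zip(flat, flat[1:])):
            raise ConfigurationError("cluster bounds must be ordered")
        if not self.b1 < self.b2:
            raise ConfigurationError("b1 must be left of b2")


@dataclass
class CageParams:
    """Stage-2 scene columns; the ordering invariant is checked on creation."""

    c11: int
    c12: int
    c21: int
    c22: int
    b1: int
    b2: int

    def __post_init__(self) -> None:
        if not (0 < self.c11 < self.c12 < self.b1 < self.b2 < self.c21 < self.c22):
            raise ConfigurationError(
                "cage parameters must satisfy 0<c11<c12<b1<b2<c21<c22"
            )


@dataclass
class BodyBox:
    box: Rect
    aspect: str  # horizontal | vertical | square
    mass_center: Point


@dataclass
class HeadDecision:
    frame_index: int
    candidates: List[Point]
    status: str  # certain | ambiguous | deferred

    def __post_init__(self) -> None:
        if self.status == "certain" and len(self.candidates) != 1:
            raise ConfigurationError("certain decision needs exactly one candidate")
        if self.status == "ambiguous" and len(self.candidates) != 2:
            raise ConfigurationError("ambiguous decision needs exactly two candidates")


@dataclass
class VisitRecord:
    compartment: str
    start_frame: int
    end_frame: int
    duration_s: float


@dataclass
class Stage1Config:
    """Tunables for the top-view pipeline (all pixel/ratio units)."""

    min_cluster_width: int = 2
    max_cluster_width: int = 80
    min_cluster_gap: int = 5
    min_column_count: int = 3
    threshold_range: Tuple[float, float] = (40.0, 200.0)
    threshold_step: float = 10.0
    blob_min_area: int = 60
    erosion_size: int = 3
    square_ratio: Tuple[float, float] = (0.8, 1.25)
    flank_fraction: float = 1.0 / 3.0
    weak_ratio: float = 0.8
    tail_strip_fraction: float = 0.25
    tail_min_pixels: int = 6


@dataclass
class Stage2Config:
    tall_column_fraction: float = 0.5
    threshold_range: Tuple[float, float] = (40.0, 200.0)
    threshold_step: float = 10.0
    cage_min_width: int = 10
    wall_max_width: int = 8
    motion_threshold: float = 15.0
    box_w: int = 40
    box_h: int = 40
    relevance_thr: int = 20


# ---------------------------------------------------------------------------
# Stage 1: scene walls, rat blob, head voting, offline resolution
# ---------------------------------------------------------------------------

def _projection_clusters(binary: np.ndarray, min_count: int) -> List[Tuple[int, int]]:
    """Maximal runs of columns whose dark-pixel count exceeds ``min_count``."""
    cols = binary.sum(axis=0) >= min_count
    clusters: List[Tuple[int, int]] = []
    start = None
    for x, on in enumerate(cols):
        if on and start is None:
            start = x
        elif not on and start is not None:
            clusters.append((start, x - 1))
            start = None
    if start is not None:
        clusters.append((start, len(cols) - 1))
    return clusters


def _clusters_valid(
    clusters: Sequence[Tuple[int, int]], cfg: Stage1Config
) -> bool:
    if len(clusters) != 5:
        return False
    for s, e in clusters:
        if not (cfg.min_cluster_width <= e - s + 1 <= cfg.max_cluster_width):
            return False
    for (s0, e0), (s1, e1) in zip(clusters, clusters[1:]):
        if s1 - e0 - 1 < cfg.min_cluster_gap:
            return False
    return True


def compute_scene_walls(
    frame, cfg: Optional[Stage1Config] = None
) -> Optional[SceneWallsStage1]:
    """Search a binarization threshold whose projection yields five clusters.

    Returns ``None`` when no threshold in the configured range produces a valid
    five-cluster projection (occluder present, uniform frame...); the caller
    then moves on to the next frame.
    """
    cfg = cfg or Stage1Config()
    pix = _as_pixels(frame)
    lo, hi = cfg.threshold_range
    passing = []
    for thr in np.arange(lo, hi + 1e-9, cfg.threshold_step):
        binary = pix < thr
        clusters = _projection_clusters(binary, cfg.min_column_count)
        if _clusters_valid(clusters, cfg):
            passing.append((float(thr), list(clusters)))
    if not passing:
        return None
    # middle of the passing range: maximal noise margin on both sides
    thr, clusters = passing[len(passing) // 2]
    b1 = (clusters[1][0] + clusters[1][1]) // 2
    b2 = (clusters[3][0] + clusters[3][1]) // 2
    return SceneWallsStage1(
        cluster_bounds=list(clusters), b1=b1, b2=b2, bin_thr=thr
    )


def _aspect_of(w: int, h: int, square_ratio: Tuple[float, float]) -> str:
    r = w / max(h, 1)
    if square_ratio[0] <= r <= square_ratio[1]:
        return "square"
    return "horizontal" if r > 1 else "vertical"


def detect_rat_blob(
    frame, walls: SceneWallsStage1, cfg: Optional[Stage1Config] = None
) -> Optional[BodyBox]:
    """Largest eroded dark blob strictly between the interior walls."""
    cfg = cfg or Stage1Config()
    pix = _as_pixels(frame)
    x0 = walls.cluster_bounds[1][1] + 1  # inner edge of interior-left wall
    x1 = walls.cluster_bounds[3][0]  # inner edge of interior-right wall
    if x1 - x0 < 4:
        return None
    sub = pix[:, x0:x1] < walls.bin_thr
    sub = ndimage.binary_erosion(
        sub, structure=np.ones((cfg.erosion_size, cfg.erosion_size), bool)
    )
    labels, n = ndimage.label(sub)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < cfg.blob_min_area:
        return None
    ys, xs = np.nonzero(labels == best)
    bx, by = int(xs.min()) + x0, int(ys.min())
    bw, bh = int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1)
    return BodyBox(
        box=Rect(bx, by, bw, bh),
        aspect=_aspect_of(bw, bh, cfg.square_ratio),
        mass_center=(float(xs.mean()) + x0, float(ys.mean())),
    )


def _body_mask(pix: np.ndarray, body: BodyBox, thr: float) -> np.ndarray:
    b = body.box
    return pix[b.y : b.y + b.h, b.x : b.x + b.w] < thr


def _flank_vote(mask: np.ndarray, horizontal: bool, cfg: Stage1Config):
    """Vote 1: the flank with significantly fewer body pixels holds the head.

    Returns (side, strong) where side is 'neg' (left/top) or 'pos'
    (right/bottom) or None.
    """
    if not horizontal:
        mask = mask.T
    w = mask.shape[1]
    k = max(1, int(round(w * cfg.flank_fraction)))
    c_neg = int(mask[:, :k].sum())
    c_pos = int(mask[:, -k:].sum())
    if c_neg == c_pos == 0:
        return None, False
    lo, hi = min(c_neg, c_pos), max(c_neg, c_pos)
    if hi == 0 or lo / hi >= cfg.weak_ratio:
        return None, False
    return ("neg" if c_neg < c_pos else "pos"), True


def _tail_vote(pix: np.ndarray, body: BodyBox, thr: float, horizontal: bool, cfg: Stage1Config):
    """Vote 2: scan thin strips outside the body box for the tail.

    The tail container is the strip with a large middle-located body-pixel
    count; the head is on the opposite side.
    """
    b = body.box
    h_img, w_img = pix.shape
    strip = max(2, int(round((b.w if horizontal else b.h) * cfg.tail_strip_fraction)))
    gap = 2  # skip the blob boundary ring left by the erosion step
    if horizontal:
        mid0, mid1 = b.y + b.h // 4, b.y + (3 * b.h) // 4 + 1
        neg = pix[mid0:mid1, max(0, b.x - gap - strip) : max(0, b.x - gap)] < thr
        pos = pix[mid0:mid1, b.x + b.w + gap : min(w_img, b.x + b.w + gap + strip)] < thr
    else:
        mid0, mid1 = b.x + b.w // 4, b.x + (3 * b.w) // 4 + 1
        neg = pix[max(0, b.y - gap - strip) : max(0, b.y - gap), mid0:mid1] < thr
        pos = pix[b.y + b.h + gap : min(h_img, b.y + b.h + gap + strip), mid0:mid1] < thr
    c_neg, c_pos = int(neg.sum()), int(pos.sum())
    if max(c_neg, c_pos) < cfg.tail_min_pixels:
        return None, False
    if min(c_neg, c_pos) * 2 > max(c_neg, c_pos):
        return None, False  # no clear tail side
    tail = "neg" if c_neg > c_pos else "pos"
    head = "pos" if tail == "neg" else "neg"
    return head, True


def _flank_centroid(mask: np.ndarray, body: BodyBox, side: str, horizontal: bool, cfg: Stage1Config) -> Point:
    b = body.box
    work = mask if horizontal else mask.T
    w = work.shape[1]
    k = max(1, int(round(w * cfg.flank_fraction)))
    sel = work[:, :k] if side == "neg" else work[:, -k:]
    ys, xs = np.nonzero(sel)
    if len(xs) == 0:  # fall back to the flank geometric center
        cx = k / 2 if side == "neg" else w - k / 2
        cy = work.shape[0] / 2
    else:
        cx = xs.mean() + (0 if side == "neg" else w - k)
        cy = ys.mean()
    if horizontal:
        return (b.x + cx, b.y + cy)
    return (b.x + cy, b.y + cx)


def _side_of(decision: HeadDecision, body: BodyBox, horizontal: bool) -> Optional[str]:
    if decision.status != "certain":
        return None
    hx, hy = decision.candidates[0]
    cx, cy = body.mass_center
    if horizontal:
        return "neg" if hx < cx else "pos"
    return "neg" if hy < cy else "pos"


def _mask_extremes(mask: np.ndarray, body: BodyBox) -> List[Point]:
    """Leftmost / rightmost / topmost / bottommost body pixels (frame coords)."""
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        c = body.box.center
        return [c, c, c, c]
    b = body.box
    pts = []
    for idx in (np.argmin(xs), np.argmax(xs), np.argmin(ys), np.argmax(ys)):
        pts.append((b.x + float(xs[idx]), b.y + float(ys[idx])))
    return pts


def locate_head(
    frame,
    body: BodyBox,
    prev: Optional[Sequence[HeadDecision]] = None,
    bin_thr: float = 100.0,
    cfg: Optional[Stage1Config] = None,
) -> HeadDecision:
    """Locate the head of the detected body for one frame.

    With two preceding certain decisions agreeing on a side, that side directs
    the decision. Otherwise horizontal/vertical bodies use the two-method vote:
    (a) agreement → certain; (b) one weak → the strong one; (c) both strong but
    contradictory → the tail method wins; (d) neither → deferred. Square bodies
    (turn-arounds, wall contact) are decided from previous head locations and
    movement direction, emitting the two most plausible extremes when ambiguous.
    """
    cfg = cfg or Stage1Config()
    pix = _as_pixels(frame)
    fi = frame.frame_index if isinstance(frame, GrayFrame) else 0
    mask = _body_mask(pix, body, bin_thr)
    prev = [d for d in (prev or []) if d is not None]

    if body.aspect in ("horizontal", "vertical"):
        horizontal = body.aspect == "horizontal"
        s1, strong1 = _flank_vote(mask, horizontal, cfg)
        s2, strong2 = _tail_vote(pix, body, bin_thr, horizontal, cfg)
        prev_sides = [_side_of(d, body, horizontal) for d in prev[-2:]]
        prev_agree = (
            len(prev_sides) == 2
            and prev_sides[0] is not None
            and prev_sides[0] == prev_sides[1]
        )
        # the two previous localizations direct the decision unless both votes
        # strongly agree against them (turn-around just completed)
        if prev_agree and not (strong1 and strong2 and s1 == s2 != prev_sides[0]):
            c = _flank_centroid(mask, body, prev_sides[0], horizontal, cfg)
            return HeadDecision(fi, [c], "certain")
        if strong1 and strong2:
            side = s2 if s1 != s2 else s1  # contradiction: tail method validated
        elif strong1 or strong2:
            side = s1 if strong1 else s2
        else:
            return HeadDecision(fi, [], "deferred")
        c = _flank_centroid(mask, body, side, horizontal, cfg)
        return HeadDecision(fi, [c], "certain")

    # square aspect: rely on movement direction / previous head locations
    certain_prev = [d for d in prev if d.status == "certain"]
    extremes = _mask_extremes(mask, body)
    if len(certain_prev) >= 2:
        (x0, y0), (x1, y1) = certain_prev[-2].candidates[0], certain_prev[-1].candidates[0]
        dx, dy = x1 - x0, y1 - y0
        if np.hypot(dx, dy) > 1.5:  # clear motion direction
            # extreme pixel furthest along the motion direction
            scores = [ex[0] * dx + ex[1] * dy for ex in extremes]
            best = extremes[int(np.argmax(scores))]
            return HeadDecision(fi, [best], "certain")
    if certain_prev:
        ref = certain_prev[-1].candidates[0]
        order = np.argsort([np.hypot(ex[0] - ref[0], ex[1] - ref[1]) for ex in extremes])
        two = [extremes[int(order[0])], extremes[int(order[1])]]
        return HeadDecision(fi, two, "ambiguous")
    return HeadDecision(fi, [], "deferred")


def resolve_trajectory(
    decisions: Sequence[HeadDecision],
) -> List[Tuple[int, Point]]:
    """Offline pass: resolve ambiguous and deferred head decisions.

    Ambiguous frames take the candidate closest to the next certain frame's
    position (the previous certain one when no later exists); deferred frames
    are linearly interpolated between neighboring certain frames.
    """
    certain_idx = [i for i, d in enumerate(decisions) if d.status == "certain"]
    if not certain_idx:
        raise UnresolvedSessionError("no certain head decision in the session")
    n = len(decisions)
    next_certain: List[Optional[int]] = [None] * n
    prev_certain: List[Optional[int]] = [None] * n
    last = None
    for i in range(n):
        if decisions[i].status == "certain":
            last = i
        prev_certain[i] = last
    nxt = None
    for i in range(n - 1, -1, -1):
        if decisions[i].status == "certain":
            nxt = i
        next_certain[i] = nxt

    out: List[Tuple[int, Point]] = []
    for i, d in enumerate(decisions):
        if d.status == "certain":
            out.append((d.frame_index, d.candidates[0]))
            continue
        ref_i = next_certain[i] if next_certain[i] is not None else prev_certain[i]
        ref = decisions[ref_i].candidates[0]
        if d.status == "ambiguous":
            dists = [np.hypot(c[0] - ref[0], c[1] - ref[1]) for c in d.candidates]
            out.append((d.frame_index, d.candidates[int(np.argmin(dists))]))
        else:  # deferred: interpolate between flanking certain frames
            pi, ni = prev_certain[i], next_certain[i]
            if pi is None or ni is None:
                out.append((d.frame_index, ref))
            else:
                p, q = decisions[pi].candidates[0], decisions[ni].candidates[0]
                t = (i - pi) / (ni - pi)
                out.append(
                    (d.frame_index, (p[0] + t * (q[0] - p[0]), p[1] + t * (q[1] - p[1])))
                )
    return out


def run_stage1(
    frames: Sequence[GrayFrame], cfg: Optional[Stage1Config] = None
) -> Tuple[List[HeadDecision], List[Optional[BodyBox]]]:
    """Per-frame stage-1 loop: scene walls, rat blob, head decision.

    Frames whose scene check or blob detection fails contribute a deferred
    decision (resolved offline like any other uncertain case).
    """
    cfg = cfg or Stage1Config()
    decisions: List[HeadDecision] = []
    bodies: List[Optional[BodyBox]] = []
    recent: List[HeadDecision] = []
    for fr in frames:
        walls = compute_scene_walls(fr, cfg)
        body = detect_rat_blob(fr, walls, cfg) if walls is not None else None
        if body is None:
            d = HeadDecision(fr.frame_index, [], "deferred")
        else:
            d = locate_head(fr, body, recent, bin_thr=walls.bin_thr, cfg=cfg)
        decisions.append(d)
        bodies.append(body)
        recent = (recent + [d])[-2:]
    return decisions, bodies


# ---------------------------------------------------------------------------
# Stage 2: cage parameters, tracking, visit analysis
# ---------------------------------------------------------------------------

def compute_cage_params(
    frame, cfg: Optional[Stage2Config] = None
) -> Optional[CageParams]:
    """Recover ``c11..c22`` and ``b1,b2`` from the tall-column projection.

    Cage blocks are wide tall-column runs at the frame extremes; the two door
    walls are thin tall runs strictly between the cages. Returns ``None`` when
    the structure or the ordering invariant is not met (frame skipped).
    """
    cfg = cfg or Stage2Config()
    pix = _as_pixels(frame)
    h = pix.shape[0]
    lo, hi = cfg.threshold_range
    for thr in np.arange(lo, hi + 1e-9, cfg.threshold_step):
        binary = pix < thr
        tall = binary.sum(axis=0) >= cfg.tall_column_fraction * h
        runs = []
        start = None
        for x, on in enumerate(tall):
            if on and start is None:
                start = x
            elif not on and start is not None:
                runs.append((start, x - 1))
                start = None
        if start is not None:
            runs.append((start, len(tall) - 1))
        wide = [(s, e) for s, e in runs if e - s + 1 >= cfg.cage_min_width]
        if len(wide) < 2:
            continue
        c11, c12 = wide[0]
        c21, c22 = wide[-1]
        if not (0 < c11 < c12 < c21 < c22):
            continue
        inner = [
            (s, e)
            for s, e in runs
            if s > c12 and e < c21 and e - s + 1 <= cfg.wall_max_width
        ]
        if len(inner) != 2:
            continue
        b1 = (inner[0][0] + inner[0][1]) // 2
        b2 = (inner[1][0] + inner[1][1]) // 2
        try:
            return CageParams(c11=c11, c12=c12, c21=c21, c22=c22, b1=b1, b2=b2)
        except ConfigurationError:
            continue
    return None


def track_stage2(
    frames: Sequence[GrayFrame], cfg: Optional[Stage2Config] = None
) -> Tuple[List[Tuple[int, Point]], Optional[CageParams]]:
    """Track the free rat over a stage-2 frame sequence.

    Per frame the cage parameters are recomputed; the motion image of the
    frame triple, restricted to the columns between the cages, is searched with
    the counting box. Freezing frames (no relevant cluster) keep the last
    position. Returns the track and the last accepted cage parameters.
    """
    cfg = cfg or Stage2Config()
    track: List[Tuple[int, Point]] = []
    params: Optional[CageParams] = None
    last_pos: Optional[Point] = None
    for i, fr in enumerate(frames):
        p = compute_cage_params(fr, cfg)
        if p is not None:
            params = p
        if params is None or i < 2:
            continue
        m = compute_motion_image(
            frames[i], frames[i - 1], frames[i - 2], threshold=cfg.motion_threshold
        )
        search = Rect(params.c12 + 1, 0, params.c21 - params.c12 - 1, fr.height)
        cluster = counting_box_cluster(
            m, search=search, box_w=cfg.box_w, box_h=cfg.box_h,
            relevance_thr=cfg.relevance_thr,
        )
        if cluster is not None and cluster.relevant:
            last_pos = cluster.mass_center
        if last_pos is not None:
            track.append((fr.frame_index, last_pos))
    return track, params


def compartment_of(x: float, params: CageParams) -> str:
    if x < params.b1:
        return LEFT_CAGE
    if x > params.b2:
        return RIGHT_CAGE
    return MIDDLE


def analyze_visits(
    track: Sequence[Tuple[int, Point]],
    params: CageParams,
    fps: float,
    debounce: int = 3,
) -> Tuple[List[VisitRecord], Dict[str, int]]:
    """Turn a position track into visit records and per-compartment entries.

    A compartment change counts only when sustained for at least ``debounce``
    consecutive frames; the visit boundary is placed at the first frame of the
    sustained run. The initial compartment is a visit but not an entry.
    """
    entries = {LEFT_CAGE: 0, MIDDLE: 0, RIGHT_CAGE: 0}
    if not track:
        return [], entries
    visits: List[VisitRecord] = []
    cur = compartment_of(track[0][1][0], params)
    cur_start = track[0][0]
    cand: Optional[str] = None
    cand_start = 0
    cand_len = 0
    last_frame = track[0][0]
    for fi, (x, _y) in track:
        comp = compartment_of(x, params)
        last_frame = fi
        if comp == cur:
            cand = None
            cand_len = 0
            continue
        if comp != cand:
            cand = comp
            cand_start = fi
            cand_len = 1
        else:
            cand_len += 1
        if cand_len >= debounce:
            visits.append(
                VisitRecord(cur, cur_start, cand_start - 1,
                            (cand_start - cur_start) / fps)
            )
            entries[cand] += 1
            cur = cand
            cur_start = cand_start
            cand = None
            cand_len = 0
    visits.append(
        VisitRecord(cur, cur_start, last_frame, (last_frame - cur_start + 1) / fps)
    )
    return visits, entries
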