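"""Shared motion-feature extraction and cluster localization.

The localization primitive used by all three application pipelines works on a
triple of consecutive grayscale frames ``ia`` (current), ``ib``, ``ic`` (the
two anterior frames):

1. double difference ``|ia - ib| - |ib - ic|``, clipped at zero;
2. binarization with an intensity threshold;
3. morphological erosion then dilation (square structuring elements) to
   suppress isolated noise pixels and consolidate the moving-target blob;
4. masking of all feature pixels outside the per-view useful-information
   polygon (ray-casting membership);
5. a "counting box" scan: the axis-aligned box placement containing the most
   feature pixels; its feature centroid is the raw target localization.

Conventions: coordinates are 0-based, x rightward, y downward; rectangles are
half-open ``[x, x+w) × [y, y+h)``; points exactly on a polygon edge count as
inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "GrayFrame",
    "MotionImage",
    "MovementCluster",
    "RegionPolygon",
    "Rect",
    "to_gray",
    "compute_motion_image",
    "point_in_polygon",
    "polygon_mask",
    "mask_outside_region",
    "counting_box_cluster",
]


class ConfigurationError(ValueError):
    """Raised when scene geometry or parameters violate a stated invariant."""


class WarmUpError(RuntimeError):
    """Raised when fewer than three frames are available for differencing."""


Point = Tuple[float, float]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, half-open: ``[x, x+w) × [y, y+h)``."""

    x: int
    y: int
    w: int
    h: int

    @property
    def center(self) -> Point:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.w, self.h))

    def contains(self, p: Point) -> bool:
        return self.x <= p[0] < self.x + self.w and self.y <= p[1] < self.y + self.h

    def intersect(self, other: "Rect") -> "Rect":
        x0 = max(self.x, other.x)
        y0 = max(self.y, other.y)
        x1 = min(self.x + self.w, other.x + other.w)
        y1 = min(self.y + self.h, other.y + other.h)
        return Rect(x0, y0, max(0, x1 - x0), max(0, y1 - y0))


@dataclass
class GrayFrame:
    """A single grayscale frame with timing metadata.

    ``pixels`` is a 2-D array of intensities in [0, 255]; color input should be
    converted first with :func:`to_gray`.
    """

    pixels: np.ndarray
    frame_index: int = 0
    fps: float = 25.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ConfigurationError("GrayFrame requires a 2-D intensity array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ConfigurationError("frame dimensions must be positive")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def timestamp_s(self) -> float:
        return self.frame_index / self.fps


@dataclass
class MotionImage:
    """Binary motion-feature map plus its nonzero-pixel count."""

    features: np.ndarray
    features_nmb: int = field(default=-1)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=bool)
        if self.features_nmb < 0:
            self.features_nmb = int(np.count_nonzero(self.features))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.features.shape  # type: ignore[return-value]


@dataclass
class MovementCluster:
    """Counting-box result: winning box, feature centroid and count."""

    box: Rect
    mass_center: Point
    feature_count: int
    relevant: bool


@dataclass(frozen=True)
class RegionPolygon:
    """Simple polygon given as an ordered vertex list, with a label."""

    vertices: Tuple[Point, ...]
    name: str = ""

    def __init__(self, vertices: Sequence[Point], name: str = "") -> None:
        verts = tuple((float(x), float(y)) for x, y in vertices)
        if len(verts) < 3:
            raise ConfigurationError("polygon needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "name", name)

    @property
    def bounds(self) -> Tuple[float, float, float, float]:
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return (min(xs), min(ys), max(xs), max(ys))


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) color frame to grayscale by Rec.601 luma weighting.

    2-D input is passed through as float64.
    """
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    raise ConfigurationError(f"unsupported frame shape {arr.shape}")


def _as_pixels(frame) -> np.ndarray:
    if isinstance(frame, GrayFrame):
        return np.asarray(frame.pixels, dtype=np.float64)
    return to_gray(frame)


def compute_motion_image(
    ia,
    ib,
    ic,
    erosion_size: int = 3,
    dilation_size: int = 5,
    threshold: float = 15.0,
) -> MotionImage:
    """Compute the binary motion image from a frame triple (``ia`` newest).

    The double difference ``|ia-ib| - |ib-ic|`` (negatives clipped to 0) is
    binarized at ``threshold`` and cleaned by erosion with a
    ``erosion_size``-square element followed by dilation with a
    ``dilation_size``-square element. Out-of-frame pixels act as background
    (zero) for both morphological operators.
    """
    if ia is None or ib is None or ic is None:
        raise WarmUpError("three frames are required for the double difference")
    a, b, c = _as_pixels(ia), _as_pixels(ib), _as_pixels(ic)
    if not (a.shape == b.shape == c.shape):
        raise ConfigurationError(
            f"frame dimension mismatch: {a.shape}, {b.shape}, {c.shape}"
        )
    dif_dif = np.abs(a - b) - np.abs(b - c)
    np.clip(dif_dif, 0.0, None, out=dif_dif)
    binary = dif_dif >= threshold
    if erosion_size > 1:
        binary = ndimage.binary_erosion(
            binary, structure=np.ones((erosion_size, erosion_size), bool),
            border_value=0,
        )
    if dilation_size > 1:
        binary = ndimage.binary_dilation(
            binary, structure=np.ones((dilation_size, dilation_size), bool),
            border_value=0,
        )
    return MotionImage(features=binary)


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------

def _on_segment(px, py, x0, y0, x1, y1, eps: float = 1e-9) -> bool:
    cross = (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)
    if abs(cross) > eps * max(1.0, abs(x1 - x0) + abs(y1 - y0)):
        return False
    return (
        min(x0, x1) - eps <= px <= max(x0, x1) + eps
        and min(y0, y1) - eps <= py <= max(y0, y1) + eps
    )


def point_in_polygon(p: Point, poly: RegionPolygon) -> bool:
    """Ray-casting membership test; points exactly on an edge count as inside."""
    px, py = float(p[0]), float(p[1])
    verts = poly.vertices
    n = len(verts)
    inside = False
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        if _on_segment(px, py, x0, y0, x1, y1):
            return True
        # crossing test, half-open in y to avoid double-counting vertices
        if (y0 > py) != (y1 > py):
            x_int = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
            if px < x_int:
                inside = not inside
    return inside


@lru_cache(maxsize=64)
def _polygon_mask_cached(
    vertices: Tuple[Point, ...], shape: Tuple[int, int]
) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    xs = xs.astype(np.float64)
    ys = ys.astype(np.float64)
    inside = np.zeros(shape, dtype=bool)
    on_edge = np.zeros(shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        cross = (x1 - x0) * (ys - y0) - (y1 - y0) * (xs - x0)
        seg_scale = 1e-9 * max(1.0, abs(x1 - x0) + abs(y1 - y0))
        on = (
            (np.abs(cross) <= seg_scale)
            & (xs >= min(x0, x1) - 1e-9)
            & (xs <= max(x0, x1) + 1e-9)
            & (ys >= min(y0, y1) - 1e-9)
            & (ys <= max(y0, y1) + 1e-9)
        )
        on_edge |= on
        if y0 != y1:
            crossing = ((y0 > ys) != (y1 > ys)) & (
                xs < x0 + (ys - y0) * (x1 - x0) / (y1 - y0)
            )
            inside ^= crossing
    mask = inside | on_edge
    mask.flags.writeable = False
    return mask


def polygon_mask(poly: RegionPolygon, shape: Tuple[int, int]) -> np.ndarray:
    """Boolean raster of the polygon interior (edge pixels included), cached."""
    return _polygon_mask_cached(poly.vertices, (int(shape[0]), int(shape[1])))


def mask_outside_region(m: MotionImage, poly: RegionPolygon) -> MotionImage:
    """Zero all motion features outside the useful-information polygon."""
    mask = polygon_mask(poly, m.shape)
    return MotionImage(features=m.features & mask)


# ---------------------------------------------------------------------------
# Counting box
# ---------------------------------------------------------------------------

def counting_box_cluster(
    m: MotionImage,
    search: Optional[Rect] = None,
    box_w: int = 40,
    box_h: int = 40,
    relevance_thr: int = 30,
) -> Optional[MovementCluster]:
    """Find the most relevant movement cluster with a sliding counting box.

    Every placement of a ``box_w × box_h`` box inside ``search`` (stride 1) is
    scored by the number of feature pixels it contains; the placement with the
    maximal count wins, ties broken by smallest (y, then x) of the box origin.
    Returns ``None`` when the search region contains no features or is empty.
    """
    h, w = m.shape
    if search is None:
        search = Rect(0, 0, w, h)
    search = search.intersect(Rect(0, 0, w, h))
    if search.w <= 0 or search.h <= 0:
        return None
    box_w = min(box_w, search.w)
    box_h = min(box_h, search.h)
    sub = m.features[search.y : search.y + search.h, search.x : search.x + search.w]
    if not sub.any():
        return None
    # box sums for every placement via 2-D cumulative sums (exact, stride 1)
    ii = np.zeros((sub.shape[0] + 1, sub.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(sub, axis=0), axis=1, out=ii[1:, 1:])
    counts = (
        ii[box_h:, box_w:]
        - ii[:-box_h, box_w:]
        - ii[box_h:, :-box_w]
        + ii[:-box_h, :-box_w]
    )
    flat = int(np.argmax(counts))  # argmax is first occurrence: smallest (y, x)
    by, bx = divmod(flat, counts.shape[1])
    count = int(counts[by, bx])
    box = Rect(search.x + bx, search.y + by, box_w, box_h)
    win = sub[by : by + box_h, bx : bx + box_w]
    ys, xs = np.nonzero(win)
    cx = float(xs.mean()) + box.x
    cy = float(ys.mean()) + box.y
    return MovementCluster(
        box=box,
        mass_center=(cx, cy),
        feature_count=count,
        relevant=count >= relevance_thr,
    )
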