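# Methods

## The shared motion primitive

All three applications localize a low-contrast animal by the strength and
placement of frame-to-frame change rather than by appearance. For a frame
triple — current frame `Ia` and the two anterior frames `Ib`, `Ic` — the
motion image is

```
Imov = D( E( clip(|Ia − Ib| − |Ib − Ic|, 0) ≥ θ ) )
```

where `E` and `D` are binary erosion and dilation with square structuring
elements. The double difference suppresses the ghost the animal leaves at its
previous position (a single difference highlights both endpoints of the
displacement); clipping at zero makes the subtraction well defined for
unsigned intensities. Erosion removes isolated super-threshold noise pixels,
dilation re-consolidates the surviving blob. Feature pixels outside the
per-view useful-information polygon are deleted by a ray-casting membership
test, and a *counting box* — an exhaustive stride-1 scan for the box placement
containing the most feature pixels, implemented with an integral image so the
scan is exact, not approximate — yields the raw localization (the feature
centroid inside the winning box).

Assumptions and consequences:

* the animal is the dominant mover inside the information polygon; static
  scene structure contributes nothing to the motion image;
* inter-frame displacement must exceed roughly the erosion size. With the
  default 3×3 erosion, movement below ~3 px/frame is invisible; the pipelines
  treat such frames as *freezing* and hold the last position. The panda
  pipeline uses a 2×2 erosion by default because a slow-pacing bear at
  480×270 moves 2–3 px/frame in the ground views — still well above the
  spatial scale of intensity noise, which a 2×2 erosion removes;
* optical-flow and Kalman approaches are deliberately not used: the targets
  show abrupt speed and direction changes and the scenes show abrupt
  brightness changes, violating both methods' core assumptions.

Numerical conventions: 0-based pixel coordinates, x rightward, y downward;
rectangles half-open `[x, x+w) × [y, y+h)`; points exactly on a polygon edge
count as inside; counting-box ties break toward the smallest (y, x) origin.
Binarization threshold defaults to 15 intensity levels (≈3.5σ of the
generator's σ=3 sensor noise); erosion 3×3 then dilation 5×5 unless an
application overrides them.

## Rat: head pose and compartment visits

**Stage 1 (top view).** The scene check binarizes the frame with a threshold
searched over a configurable range; a frame is *normal* when the column
projection of the dark pixels shows exactly five clusters (outer wall,
interior wall, the rat itself, interior wall, outer wall). When several
thresholds pass, the median passing threshold is used — it maximizes the noise
margin on both sides, which keeps the rat blob solid under sensor noise. The
interior-wall columns `b1`, `b2` are the midpoints of clusters 2 and 4. The
rat body is the largest eroded dark blob strictly between the interior walls;
its box aspect (width/height against a square band of [0.8, 1.25]) selects
the head-finding strategy.

The head votes for elongated bodies: (1) the flank third with significantly
fewer body pixels (count ratio < 0.8) holds the head; (2) thin strips scanned
just outside the body box (width = box/4, offset 2 px past the erosion ring)
locate the tail as the side with a clear majority (≥2:1) of middle-row body
pixels — the head is opposite. Agreement → certain; one strong vote → that
vote; both strong but contradictory → the tail vote wins (the tail is the
more specific landmark); neither → deferred. Two preceding concordant certain
decisions direct the decision *unless* both votes strongly agree against them
— the exception is what lets the tracker recover within one frame after a
turn-around instead of locking in the stale direction. Near-square bodies
(turns, wall contact) use the motion direction of recent certain positions
when it is clear (>1.5 px), otherwise emit the two body extremes closest to
the previous head as an ambiguous pair. The offline pass resolves ambiguous
frames to the candidate nearest the next certain position and interpolates
deferred frames; on the synthetic fixtures it never increases the error
count.

**Stage 2 (side view).** Cage parameters are recomputed every frame (the
operator may nudge the camera): tall columns (dark over ≥50% of the height)
form the projection; the two wide runs at the extremes are the cages
`c11..c12`, `c21..c22`, the two thin runs between them are the door walls
`b1`, `b2`; any violation of `0 < c11 < c12 < b1 < b2 < c21 < c22` skips the
frame. Tracking is the shared primitive restricted to the columns between
the cages; freezing holds the last position. The compartment of a position is
decided by its x against `b1`/`b2` alone (side view; y carries no compartment
information). An entry requires the new compartment to persist for a
debounce window (default 3 frames) so boundary flicker is not counted; the
visit boundary is placed at the first frame of the sustained run, and
durations are `(end − start + 1)/fps`.

## Monkey: localization, confidence, orientation

The sensor box on the monkey's head is a dark, rigid rectangle — the only
reliable landmark in an unevenly lit cage where the animal can kill the
light at any moment. Localization layers three safeguards over the motion
primitive:

* **model**: a gray-level template (default 32×32) stored at the accepted
  position and refreshed after every acceptance. It is created only when the
  scene is lit and the strict conditions hold — relevant cluster, Canny edge
  count near the center inside the configured band with an edge-free
  immediate center (the box interior is featureless while its border is not),
  and a dark center neighborhood;
* **matching**: normalized cross-correlation (`skimage.feature.match_template`)
  of the model near the previous position (and near the current cluster);
  acceptance at score ≥ 0.7. Matching is attempted at both anchors because
  during freezing there is no cluster, and during fast motion the cluster
  centroid lags the box;
* **refinement**: the accepted position snaps to the centroid of the dark
  mass in a window around it, using a window-relative threshold
  (`min + 0.4·range`) so the step survives light-off dimming; the refinement
  runs twice so window clipping cannot bias the centroid. Without this step
  the template inherits the motion centroid's systematic lag and the error
  never decays.

Canny input is contrast-normalized per frame, otherwise the dimmed scene
produces no edges. During light-off the global search is disabled (shadows
may generate large spurious clusters) and only the near-previous search
runs. A uniform frame (std below 4 intensity levels) restarts the session
entirely. A very relevant far cluster (≥120 features) restarts tracking with
fresh model synthesis.

Confidence is `100 · region_weight · match_score · p^(it−1)` with
`p = 0.9` and one extra factor of `p` when the localization needed a second
iteration while the motion-trait count was large; the product form is the
package's construction — the factors themselves (area reliability, match
score, iteration) are the method's. Only confidences strictly above 75%
enter the orientation analysis.

Orientation inflates the ROI by half its size in every direction, smooths
the HSV value channel (Gaussian, σ=1.5), binarizes with a brightness-mapped
threshold in [30, 60], and among dark contours larger than 500 px picks the
one with the highest filling index (contour area over min-area-rectangle
area, the rectangle from `shapely.minimum_rotated_rectangle`); the angle is
the long side's direction in [0, 180), counter-clockwise from +x with y up.
A contour covering more than 80% of the ROI is rejected as degenerate
binarization (an unlit ROI thresholds to a single mass). The 1-D angle
filter replaces each angle by the mean of the valid window entries (present,
confidence ≥ threshold, window default 11), after unwrapping the window
modulo 180° about its median so that 175° and 5° average to 0°, not 90°;
missing angles estimated this way are flagged `filled`.

## Panda: per-camera sessions, fusion, stress classes

Each camera classifies every frame by `features_nmb` against
`low < mid < high` (defaults 20/60/1500 at 480×270): above `high` a session
(re)starts — and a frame-height movement rectangle (>0.55 of the frame
height) marks the zoo technician, whose frames never enter fusion; above
`mid`, a movement frame subject to validation (area burst > 3×, far jump
> 2 diagonals in a visible area, direction reversal at speed, and on the
general-view cameras membership of a zone corresponding to the previously
fused view — the bird filter); the mid band continues door watching after an
exit or freezes a near-static rectangle in a visible non-door zone; below
`low`, freezing while the animal was last seen in an observable zone,
otherwise `no_information` and (after two such frames) session
cancellation. Two guards added by this implementation, both documented as
such: freezing decays to `no_information` after 5 s so a stale held position
cannot dominate fusion when the animal has actually left the view, and a
held rectangle hugging the frame border is released immediately (an
edge-touching "freeze" is almost always an exit, not a pause). A session can
restart from the last valid position, from a gate, or — an addition
consistent with the fusion correlation the method requires — from a zone
corresponding to the currently fused view of another camera (cross-camera
hand-off). Bathing behind the camera-8 foreground stones restrains the
search to a window beside the last observable position, so the pond ripples
keep the track anchored there.

Fusion picks, per synchronized frame, the candidate with the best zone rank
(full-visibility zones over doors over partials, ground cameras over the
general views), then the largest movement rectangle ("the most observable
bear"), keeping the previously selected camera when it offers at least 2/3
of the best rectangle. Technician and out-of-zone candidates are dropped
first. The fused list length is the minimum stream length.

Post-processing: (1) compaction — short (≤10-frame) interleaved runs of a
complementary camera between two large (≥50-frame) runs of the same camera
are substituted by that camera's own positions (the further filter passes of
the same substitution mechanism in other contexts are parameterized but off
by default, as reconstructions); (2) linear gap interpolation for 2–100
frame gaps bounded by the same camera, attribute moving if either bound
moves; (3) attribute majority vote in a centered window (default 5), ties
keeping the current attribute; (4) velocity as the Euclidean displacement of
same-camera neighbors × per-camera weight × resolution normalization,
averaged over a centered window (default 9) of valid entries — cross-camera
pairs have no velocity.

Stress labels against `thr_v1 > thr_v2 > thr_v3` (defaults 9/4/1.5 weighted
px/frame): running above `thr_v1` unconditionally; the two walking bands
depend on the zone of the *preceding still period*, found as the nearest
sustained (≥1.5 s) block of non-moving present entries within a 10-s
look-back, its kind decided by majority — a full-visibility rest yields
walking 1 (mid band), a garden-housing still period yields walking 2 (mid
band) or walking 3 (low band, additionally requiring a path *height*: a
point at >20 px residual from the total-least-squares line of the section);
stationary marks camera-8 basin dwells (movement attribute, mass center
within the basin plus a 10 px margin) longer than 5 s. Episodes are maximal
same-label runs; fragments shorter than 1 s are dropped and sub-1-s gaps
between same-class segments are bridged — the shortest episode the method is
expected to report is 1.5 s, so the floor cannot clip a genuine episode.

## Synthetic scenes

The generators render deterministic (script, seed) scenarios with additive
Gaussian sensor noise (σ=3) and per-frame ground truth:

* **rat1** (320×240, 15 fps): bright floor, four dark wall bands (the rat is
  the fifth projection cluster), a tapered dark ellipse with a thin middle
  tail, scripted back-and-forth walks with near-circular turn-around frames;
* **rat2** (320×240, 15 fps): full-height cage blocks and thin door walls at
  known columns; the rat gray level sits above the structure threshold so
  the parameter projection is clean; scripted visits move between
  compartment anchors at 5 px/frame with small dwell sway;
* **monkey** (320×240, 15 fps): horizontal illumination gradient, a rotated
  dark 60×24 sensor-box rectangle on a smooth two-frequency path (typical
  speed 3–6 px/frame), scripted pauses (the path clock stops), light-off
  intervals (×0.2 dimming plus a moving shadow blob 90 px from the box) and
  a feeding-like motion burst outside the information polygon;
* **panda** (4×480×270, 10 fps): one 2-D world (480×270 units) projected
  per camera by fixed affine maps — two full-arena general views and two
  1.5× ground views — with a door zone, a housing zone, a full-visibility
  meadow and a camera-8 basin with two foreground stones; world zones
  project to per-camera visible zones and the correspondence map follows
  the projections. The scripted two-minute timeline exercises every stress
  context, a technician sweep (frame-tall rectangle), a bird transient on
  the general views only, and a hidden bath rendered as seeded ripple blobs
  in the basin.

What the generators do *not* emulate: articulated body shape, perspective
distortion, shadows cast by the animal in lit scenes, compression
artifacts, reflections and occlusions other than the scripted stones. The
passing tests therefore demonstrate the correctness and internal
consistency of the algorithms under controlled conditions — thresholds
transfer to real footage only after per-scene configuration, which is why
every scene constant is exposed in the project configuration.

Problem sizes in the shipped evaluations: five 2-minute rat-2 fixtures, two
1-minute rat-1 fixtures with five turn-arounds each, one 40-s monkey fixture
(600 frames, two light-off intervals, two pauses, one burst), one 2-minute
four-camera panda scenario (4×1200 frames). These sizes exercise every
scripted event class while keeping a full evaluation run in the minutes
range on one core.

## Known limitations

* The stage-1 head voter assumes a visible taper or tail; a rat seen
  perfectly end-on defers until geometry returns.
* The monkey tracker's dark-centroid refinement assumes the sensor box is
  the darkest compact mass near the localization; a second dark object
  inside the refinement window would bias it.
* Panda walking-1/2/3 depend on a correct preceding-context decision; a
  still period split across a camera switch with inconsistent zone kinds
  votes by majority, which can misattribute a band when the views disagree.
* The six filtering passes are represented by pass 1 plus a parameterized
  substitution mechanism; the remaining contexts are reconstructions and are
  disabled by default.
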