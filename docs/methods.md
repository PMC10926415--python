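# Methods

## The problem

Wildlife cameras pointed at the night sky photograph low-flying insects
as bright motion-blur streaks: during a long exposure (order 0.1 s) a
moth crosses many pixels, and its wings modulate the brightness of the
trace once per wingbeat.  `streaktrack` turns such frames into
quantitative observations: per-image annotations of each blur's path,
per-individual trajectories across video frames, displacement
directions, and crude wingbeat frequencies.

## Annotation model

A blur is annotated as one of three shapes:

* **polyline** — an ordered vertex chain along the blur path, used
  whenever the blur is fully inside the frame and long enough to trace;
* **circle** — the minimum enclosing circle, used when the blur is
  clipped by the frame edge (its path cannot be traced reliably);
* **point** — a single mark for blurs too short to carry path
  information (default threshold: fitted path shorter than 10 px).

Coordinates are VIA pixel coordinates: x = column, y = row, origin at
the top-left pixel centre, sub-pixel floats.  Annotations are exchanged
as VIA version-2 project JSON, so they can be loaded into the VIA editor
and corrected by hand; detection scores travel in `region_attributes`
under `"score"`, trajectory membership under `"trajectory_id"`, and
per-image exposure under `file_attributes["exposure_time"]`.

## Detection

The detector is a deterministic classical pipeline exposing the same
contract as a learned instance-segmentation backend (masks in, scored
annotations out), so either can sit under the tracker:

1. binarise at `background median + k·MAD` (defaults k = 8; median and
   MAD are per-frame and robust to the sparse bright streak pixels);
2. morphological closing (disc radius 1) and 8-connected labelling;
   components below 20 px are dropped; components within 2 px of the
   frame edge are flagged as border-touching;
3. polyline inference by polynomial regression: mask pixel coordinates
   are rotated into the principal-axis frame (largest coordinate
   variance; isotropic ties break toward the x-axis), a least-squares
   polynomial `v = Σ c_k u^k` is fitted and evaluated at 10 equally
   spaced abscissae, then rotated back.  Degree 2 by default — insect
   flight within a single exposure is well modelled by low-order
   curves — configurable for more tortuous fliers.  Masks with too few
   distinct abscissae fall back to a line; masks with sub-pixel extent
   become points.
4. the detection score is `(mean_on − background_median) /
   (255 − background_median)`, clipped to [0, 1], where `mean_on` is the
   *median* intensity of the component's above-threshold pixels.  The
   median (rather than the mean) makes the score a statistic of the
   streak core: the anti-aliased fringe of a rasterised streak, whose
   share of the mask varies with path angle, would otherwise dilute the
   contrast systematically.  Gap pixels added by closing are likewise
   excluded from the statistic.

RGB input collapses to grayscale by channel maximum (streaks are
near-white under an infra-red flash); Rec.601 luminance is available as
an option.

## Matching distance and tracking

For two polylines `P_a`, `P_b` with endpoint vertices `a_0, a_{n−1}`,
`b_0, b_{m−1}`, the matching distance is

    d_M(P_a, P_b) = second-smallest of
        { d(a_0, P_b), d(a_{n−1}, P_b), d(b_0, P_a), d(b_{m−1}, P_a) }

with `d(x, P)` the exact Euclidean point-to-polyline distance.  Two
blurs that continue one another — overlapping, or abutting end to
end — have at least two near-zero endpoint distances, so d_M ≈ 0; two
blurs crossing by chance have all four distances of order the
half-lengths.  d_M is symmetric but deliberately *not* a metric
(abutting distinct segments score 0).

Tracking needs no motion model because each detection carries its own
path.  A batch of N frames yields N−1 pairwise maximum images
(pixelwise max of consecutive frames — approximating a doubled
exposure); one insect's blurs in consecutive maximum images share the
middle frame's blur and therefore overlap.  Detection runs on each
maximum image; detections in successive maximum images are linked by
minimum-total-d_M one-to-one assignment (the linear sum assignment
problem, solved by scipy's modified Jonker-Volgenant implementation);
links with d_M above a threshold (default 40 px at 1080p; retention is
inclusive) are removed, rectangular instances being padded to square at
the threshold cost so starting a new trajectory competes fairly with
extending one.  Chains are then filtered: fewer than 3 detections
removed, then mean detection score below 0.8 removed, then (optionally)
any trajectory with a polyline vertex outside a circular region of
interest removed — the ROI eliminates the directional bias a
rectangular frame imposes on displacement statistics.  Circle and point
detections carry no path for d_M, so they form singleton trajectories
that the length filter removes.

Displacement direction orients each polyline in the chain so successive
ends flow consistently, then reports `atan2(Δy, Δx)` of (last oriented
end − first oriented start) in degrees, (−180, 180], image coordinates
(+y is down-image); conversion to compass bearings needs the camera
orientation and is the caller's concern.  Trajectories do not bridge
across batch boundaries.

## Wingbeat frequency

Intensity is sampled along the polyline at 1 px arc steps, averaged
over a 3 px band along the local normal (bilinear interpolation).  The
profile is detrended by subtracting a moving average (window =
arc/4, clamped ≥ 8 px) and a zero-padded Hann periodogram is taken; the
number of cycles along the blur is `arc_length × f_peak` (cycles/px),
searched above 1.5 cycles per blur so the trend cannot masquerade as a
wingbeat.  Confidence is the fraction of DC-free power inside the
peak's main lobe; below 0.2 the profile is flagged non-periodic rather
than producing a number.  Finally

    wingbeat_hz = n_cycles / exposure_seconds

with exposure resolved from EXIF ExposureTime, a VIA file attribute, or
a configured default, in that order.  Only polyline annotations are
measured — circles and points carry no blur path — and the method is
inherently restricted to long (night-time) exposures.  This estimator
is a minimal, documented stand-in for a fuller measurement procedure
(e.g. with body-glint or blur-end corrections) and is isolated behind
`count_cycles` so such a variant can replace it without interface
changes.

## Evaluation

Predictions are matched to ground truth greedily, one-to-one, in
descending score order on bounding-box IoU (threshold 0.5, the standard
detection-evaluation convention; configurable).  Matched pairs report
IoU and, for polyline-polyline pairs, the polyline Hausdorff distance
(computed by resampling both chains at ≤ 0.5 px arc steps and taking
exact sample-to-polyline distances, accurate to ±0.5 px) and the signed
arc-length difference (prediction − truth).  Sweeping the score
threshold over the observed scores yields the precision-recall curve;
precision is defined as 1 when nothing is predicted and recall as 0
when there is no ground truth.  One caveat: an exactly axis-aligned
two-vertex polyline has a zero-area bounding box, and IoU between
degenerate boxes is defined as 0, so such a pair cannot match — real
fitted polylines are never exactly axis-aligned, but synthetic fixtures
should use sloped paths.

## Synthetic scenes

The generator emulates what the pipeline actually consumes: a dark sky
(Gaussian background, default level 10, σ 2 on an 8-bit scale — a
deliberate simplification of Poisson sensor statistics), crossed by
streaks rendered by max-compositing soft-edged discs (diameter 3 px,
pixel-coverage anti-aliasing) along a per-axis quadratic path
`p(t) = c0 + c1·t + c2·t²`.  Blur intensity is a raised sinusoid
`baseline + amplitude·(0.5 + 0.5·sin(2π·f·t))` at the wingbeat
frequency f, so the blur never goes fully dark between beats; the
rendered cycle count equals `f × exposure` analytically.  Defaults
follow typical capture settings: 1080p, 30 frames/s, 1/9 s still
exposure.  Sequences render frame i over [i/fps, i/fps + exposure], so
at exposure = 1/fps consecutive blurs of one insect abut end to end —
the property the tracker's maximum images rely on; shorter exposures
leave kinematic gaps of `speed × (1/fps − exposure)`.  Ground truth is
exact: a polyline per fully-visible blur, an enclosing circle per
clipped blur, plus identity, arc length and cycle count.

`random_scene` draws reproducible scenes.  The **clean** preset models a
coherent passage of bright insects, the regime in which each individual
should be counted exactly once: speeds uniform in the requested range
(default 100–1500 px/s), wingbeats 20–80 Hz, near-saturated intensity
(baseline 210–235, amplitude to 255) as under an infra-red flash at
close range, a shared scene heading with ~3° per-track jitter, and
placement in evenly spaced lanes across the heading normal with
rejection sampling enforcing pairwise path separation of at least 80 px
(2× the linking threshold) and a minimum visible span.  Lanes and
coherent headings are not cosmetic: independent random headings almost
surely cross inside the frame, which would violate the separation the
preset guarantees.  The **hard** preset (dim, independently headed,
crossing tracks) exists for stress testing and makes no such
guarantees.

What passing tests on these scenes does *not* show: robustness to
cloud/vegetation clutter, rain, sensor vignetting, defocus, compression
artefacts, overlapping blurs of crossing insects, or detector score
distributions of a learned model on real imagery.  The clean-scene
results are a correctness check of the geometry, linking, filtering and
spectral machinery under the structural assumptions stated above, not a
field-performance claim.

## Numerical and design choices

* Point-to-segment distances are exact (clamped projection); only the
  Hausdorff distance resamples, at 0.5 px.
* The assignment solver's retained links satisfy cost ≤ threshold
  (inclusive); optimality is cross-checked against exhaustive
  permutation minima in tests.
* Filter order is pinned (length, then score, then ROI) for
  reproducible stage counts, though the surviving set is
  order-independent.
* ROI membership tests every polyline vertex (inclusive boundary); the
  circle's convexity makes the vertex test sufficient for whole
  segments.
* Uniform (zero-MAD) frames yield zero detections, not errors; a
  saturated background (median 255) defines score 0.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; every render, detection and benchmark is
  bit-reproducible.

## Benchmark problem sizes

The standard self-checks (`streaktrack.benchmarks`, also run by
`scripts/acceptance.py`) use: 100 stills at 1080p with 1–5 streaks of
30–300 px chord (exposure 0.2 s, speeds 150–1500 px/s); twenty 5 s
clips at 854×480, 30 fps, five insects each; 200 single streaks with
3–10 cycles over 120–400 px arcs; 1000 random polyline pairs for the
d_M oracle; 500 random cost matrices up to 7×7 for assignment
optimality.  These sizes keep a full run to a few minutes on one CPU
while leaving each estimate well-determined.
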