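# Methods

## Pipeline model

The package treats an axial CT stack as a video in which each rib's
cross-section is a slowly moving object. Slices are stored superior →
inferior, so frame index `k` maps to the volume-local coordinate
`z = k·dz` (mm, increasing toward the feet); in-plane pixel `(cx, cy)`
maps to `(cx·dx, cy·dy)`. All geometry downstream works in these
volume-local millimetres.

**Detection.** The reference detector thresholds raw HU at a bone level
(default 350 HU), labels 4-connected components, filters them by area and
an optional midline exclusion band, and emits one detection per component
with the component centroid as the box centre and the tight extents as
width/height. Operating on HU rather than on windowed 8-bit frames avoids
quantisation sensitivity; the windowing module still provides the six
standard presets (lung 1500/−500, fat 200/−100, liver 120/60,
bone 2000/300, soft tissue 400/40, vessel 700/300 WW/WL) for display,
export and six-fold dataset expansion. Detection confidence is an
area-based proxy, `score = min(1, area / score_ref_area)` with
`score_ref_area = 100 px²`: a separate normalisation constant rather than
the area *filter* bound, because cross-section areas vary by an order of
magnitude along a rib and the two-threshold tracker only needs a useful
score ordering (well-formed bands score near 1, tube-tip fragments score
low). External detectors plug in through the CSV/JSON detection schema
and bypass the reference detector entirely.

**Tracking.** A constant-velocity Kalman filter on `(cx, cy, w, h)` plus
velocities predicts each track's box on the next slice; association is
optimal one-to-one assignment on cost `1 − IoU`, gated at IoU ≥ 0.2, in
two stages: high-score detections (≥ 0.5) first, then unmatched tracks
against low-score detections (≥ 0.1). New tracks start only from
unmatched high-score detections; tracks unmatched for more than 5 frames
finish; finished tracks shorter than 10 frames are discarded. A 10⁻⁹-scale
index epsilon on the assignment costs makes tie-breaks (lower track id,
then lower detection index) deterministic, so runs are bit-reproducible.

**Rib labeling.** Track point clouds become rib trajectories either by
class label (when ground-truth or detector classes exist) or by geometric
endpoint merging (default gap 8 mm, deliberately below the phantom's rib
stacking pitch). Side is the sign of the mean x against the volume
midline; within a side, trajectories are ranked by their most superior
point and numbered 1–12. A side without exactly 12 candidates is flagged
as failed rather than guessed.

**Plane fitting and the 0.99 gate.** Each trajectory is fitted with
ordinary least squares `z = a·x + b·y + c` — the slice axis is the
dependent variable, which is what makes a near-horizontal rib the
degenerate case. `R² = 1 − SS_res/SS_tot` and `r` is the Pearson
correlation between observed and fitted z (identically `√R²` for OLS with
an intercept; the identity is asserted to 10⁻¹² in tests as an internal
consistency check). The fit is accepted iff it is non-degenerate and both
`r ≥ 0.99` and `R² ≥ 0.99`; otherwise the two-fit split runs: exhaustive
search over contiguous splits with each segment ≥ max(3, 20 % of points),
choosing the split that maximises `min(R²₁, R²₂)`, ties to the smallest
index.

Two numerical choices here are deliberate. First, a fit is flagged
*degenerate* not only when the z variance is below tolerance but also when
the in-plane support is nearly collinear (second singular value of the
centred (x, y) matrix below 1 mm·√n): a horizontal rib contributes one
band centroid per slice at almost the same (x, y), so its z variance is
healthy while the plane orientation is completely unconstrained — only
the collinearity criterion catches it. Exactly collinear input still
raises, as does n < 3. Second, the split search excludes one guard point
on each side of a candidate split from the segment fits (the returned
ranges still partition the trajectory): detection centroids on slices
within a tube radius of a crease average image content from both planes,
and without the guard they drag the estimated split systematically late by
2–4 points.

**MPR resampling.** The sampling grid lies in the fitted plane: u is the
unit projection of the trajectory's principal direction onto the plane,
v = n × u, spacing defaults to the smaller in-plane voxel spacing, and a
10 mm margin surrounds the projected trajectory. Interpolation is
trilinear (`scipy.ndimage.map_coordinates`, order 1), which reproduces
linear HU fields to machine precision — the property the resampling tests
pin down. Out-of-volume samples are set to −1000 HU and masked, and the
exporter refuses NaNs, writes 8-bit PNG/TIFF through a window, and stores
plane and grid geometry in a JSON sidecar.

**Completeness.** The completeness measure is geometric, *not* the reader
judgment used in clinical evaluation: the arc-length fraction of
trajectory points within 2 mm perpendicular distance of their own
segment's plane, with "complete" meaning ≥ 95 %. Degenerate planes cover
nothing, so a rib whose fits all failed reports fraction 0. Both numbers
are configurable; no claim is made that they match reader-assessed
completeness rates.

## Synthetic phantom

The phantom provides study-like inputs with exact ground truth. A
240 × 240 × 148-voxel volume at (1.0, 1.0, 1.5) mm spacing holds a
soft-tissue body ellipse (40 HU) in air (−1000 HU) and 24 bone tubes
(700 HU), rasterized as unions of spheres along dense centerline
polylines. Slice thickness 1.5 mm sits at the top of the usual rib-CT
protocol range.

Centerlines are elliptical arcs in plan view with z given by one plane —
or two planes joined at a crease for the bent ribs — so true plane
parameters exist in closed form and plane recovery can be tested exactly:

* ribs 2–8: shared 85/65 mm ring, 30° tilt, 4 mm tube radius, stacked
  14 mm apart;
* ribs 9–12: smaller 66/49 mm ring, 30° proximal tilt with a 20°
  tilt-change crease at 30 % of the arc (the two-fit case), stacked 20 mm
  apart — the separate ring keeps their long, shallow distal bands from
  ever touching the steeper ribs above on any slice (verified by an
  analytic band-collision analysis; minimum inter-rib band gap ≈ 4 mm);
* first ribs: small 55/40 mm ring, broad 8 mm tube, tilt exactly 0 — the
  degenerate-fit case.

Per-slice ground truth (band centre, tight box, area) is computed from the
same polyline with the same union-of-spheres model, so ground truth and
rasterization agree by construction; band centres are the chord-weighted
centroids of the analytic band and sit within half an in-plane voxel of
the tube axis for ordinary crossings. Fracture-like defects modify the
rasterization: displaced (distal fragment offset, default 5 mm, with the
centerline and crossings updated), non-displaced (1.5 mm soft-tissue gap
slab), buckle (local radius bulge ×1.6), old (1100 HU callus sphere).
`default_study_spec` draws per-rib fracture indicators i.i.d.
Bernoulli(0.193) — the study-scale prevalence — with uniformly random
type and position and a small per-patient size jitter; no within-patient
correlation is imposed because the per-rib analysis is the primary unit.

What the phantom does *not* emulate: spine, sternum, scapula or lungs;
cortical/trabecular structure; scanner physics, beam hardening or
realistic noise texture (the default additive Gaussian noise is 1 HU
against a 660 HU bone/soft-tissue contrast); respiratory motion. Passing
phantom tests therefore demonstrates the correctness of the geometry,
tracking and statistics machinery under known truth — not clinical
detection performance, which in the real system is carried by a trained
detector outside this package's scope.

A known measurement artifact is worth stating: a detection centre is the
centroid of a band (the oblique tube-slice intersection), not a point on
the rib axis. For steep crossings the difference is sub-voxel, but near
tube ends, along shallow segments, and across the crease the centroid is
pulled millimetres off the axis. This is why planar-rib normal recovery is
verified to 1° rather than arbitrarily tighter, why the crease location is
recoverable only to about ±2 trajectory points, and why the first rib's
whole-arc bands produce the near-vertical point stacks that the degeneracy
flag exists for.

## Diagnostic statistics

Rib-level records (patient, side, rib 1–12, reference label, predicted
label; labels are `negative` or one of displaced / non-displaced / buckle
/ old) feed stratified confusion counts: overall, side, rib index,
fracture type, sex, age group (<30, 30–50, 50–70, >70 years; bins are
half-open [lo, hi)), and per patient (any positive rib makes the patient
positive). Fracture-type rows are one-vs-rest on the typed labels — for
type t, TP requires reference *and* prediction t — because per-type
specificity needs a typed prediction denominator; the reading is
configurable in code since other conventions exist. Sensitivity and
specificity come with Wilson score 95 % intervals (statsmodels); zero
denominators yield NaN rather than errors. Paired comparisons use the
exact binomial McNemar test `p = min(1, 2·P(X ≤ min(b,c)))`; sex uses
Fisher's exact test; age trend uses Cochran–Armitage (implemented
directly, two-sided normal p, scores 1..k); rib-level homogeneity uses
Pearson χ² without continuity correction. All of these are checked against
enumeration or closed-form oracles in the test suite.

Per-patient error accounting is on *error counts*, not net fracture
counts: exact match means zero missed and zero false-positive ribs, the
single-error categories are exactly one missed or one false positive, and
a patient with one of each is a two-error patient even though the net
count matches. Pooling the published per-side counts through this module
reproduces the published overall sensitivity 85.4 % (910/1,065),
specificity 98.9 % (4,406/4,455), prevalence 19.3 %, Wilson lower bound
83.2 % and specificity interval 98.5–99.2 %. One discrepancy: the Wilson
upper bound for 910/1,065 computes to 87.4 %, one last-digit step below
the published 87.5 %; it is reported as computed.

## Problem sizes

The default phantom (24 ribs, 148 slices, 8.5 M voxels) generates in
about one second and runs through the full pipeline in another; the test
suite and the acceptance script each complete in well under a minute.
These sizes were chosen so that every geometric claim can be verified
across many seeds during development while keeping the phantom large
enough that each rib spans tens of slices, as in clinical thin-slice CT.

## Known limitations

* Trajectory merging in geometric mode is single-linkage on endpoint
  distance; pathological fragment layouts could chain wrongly. Class-aware
  merging is preferred when labels exist.
* The completeness measure is a geometric proxy with no calibrated
  relationship to reader-judged diagnosability.
* The tracker assumes one crossing per rib per slice for track-count
  guarantees; arcs spanning more than ±90° produce double crossings and
  rely on the merging stage.
* Slab/thick-slab MPR, maximum-intensity projection and curved surface
  reformats are out of scope.
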