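# ribmpr — automatic rib multiplanar reconstruction from chest CT

Reading rib fractures on axial CT means scrolling through hundreds of
slices while each rib drifts obliquely through the stack. `ribmpr`
automates the alternative radiologists prefer but rarely have time for:
a per-rib oblique multiplanar reconstruction (MPR) that shows each rib
flat in a single image. It is aimed at medical-image-analysis researchers
and engineers who want a fully inspectable, phantom-verifiable
implementation of the detection-and-tracking approach to rib MPR,
together with the diagnostic-accuracy statistics used to evaluate such a
system.

## Method

The axial slice stack is treated as a video. For each frame, a detector
marks rib cross-sections as boxes with centre points (a pluggable slot: a
classical HU-threshold/connected-component reference detector is included,
and externally produced detections, e.g. from a trained object detector,
can be ingested from CSV/JSON). A two-stage (BYTE-style) tracker with a
constant-velocity Kalman filter on the box state `(cx, cy, w, h)` links
detections across slices by IoU using optimal (Hungarian) assignment:
high-confidence detections associate first, unmatched tracks are then
rescued by low-confidence detections, and new tracks start only from
high-confidence detections.

Each track becomes a 3-D point sequence `(cx·dx, cy·dy, k·dz)`; points are
pooled per rib, and ribs are labeled by order (side from the volume
midline, index 1–12 from the most superior point). A least-squares plane

    z = a·x + b·y + c

is fitted to each rib cloud and evaluated with the plane linear
correlation coefficient `r` (Pearson correlation of observed vs fitted
`z`) and the goodness of fit `R²`; the fit is accepted only when both
reach **0.99**. Otherwise the trajectory is split into two contiguous
segments with one plane each (the *two-fit* method), the split chosen by
exhaustive search maximising `min(R²₁, R²₂)`. The volume is then resampled
on each plane with trilinear interpolation to produce the per-rib MPR
image(s), plus a geometric completeness measure (arc-length fraction of
the trajectory within tolerance of its plane).

Because no public CT data accompany the approach, the package ships a
seeded synthetic thorax phantom: 24 rib-like tubes on elliptical arcs in
exactly known planes (horizontal first ribs to exercise the degenerate
fit, creased lower ribs to exercise the two-fit path, optional
displaced / non-displaced / buckle / old fracture-like defects), with
per-slice ground-truth boxes and centres. A statistics module computes the
stratified confusion counts, sensitivity/specificity with Wilson score
intervals, exact McNemar, Fisher exact, Cochran–Armitage trend, and
χ² homogeneity tests.

## Worked example

```python
from ribmpr import generate_phantom, run_reconstruction, PipelineConfig

volume, truth = generate_phantom(noise_sd=1.0, seed=7)
result = run_reconstruction(volume, PipelineConfig(render_mpr=False))
print(len(result.tracks), result.labeling.all_labeled)
for rib in result.ribs[:3] + result.ribs[8:10]:
    ps = rib.plane_set
    print(rib.label, rib.method or "failed",
          "" if ps is None else f"r2={ps.planes[0].r2:.4f}",
          f"complete={rib.completeness.complete}")
```

prints

```
24 True
L1 failed  complete=False
L2 one_fit r2=0.9988 complete=True
L3 one_fit r2=0.9992 complete=True
L9 two_fit r2=0.9958 complete=True
L10 two_fit r2=0.9948 complete=True
```

All 24 tracks survive, labeling is complete, the planar ribs pass the
0.99 gate with a single plane, the creased lower ribs fall back to the
two-fit split, and the horizontal first rib — whose per-slice centres
stack almost vertically, so no plane orientation is determined — is
reported as not reconstructable, mirroring the known first-rib weakness of
plane-based rib MPR.

The same pipeline is exposed on the command line:

```sh
ribmpr simulate    --out out/phantom --seed 7
ribmpr reconstruct --volume out/phantom/patient_000.nii.gz --out out/recon
ribmpr evaluate    --records records.csv --out out/stats
ribmpr full-run    --out out --seed 7
```

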