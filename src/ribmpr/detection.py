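"""Per-frame rib cross-section detection.

The production slot for a learned detector is the external-detections path
(:mod:`ribmpr.io_formats`).  For phantom volumes a classical reference
detector is provided: threshold the HU slice at a bone level, take 2-D
connected components, filter by area and by a configurable midline
exclusion band (to suppress spine/sternum on real volumes), and emit one
detection per surviving component with the component centroid as centre
and the tight bounding box extents as width/height.

The detector operates on raw HU rather than on windowed 8-bit frames,
which removes quantization sensitivity; external detectors that need
frames can use :mod:`ribmpr.windowing`.

Scores are an area-based proxy (no learned confidence exists):
``score = min(1, area / score_ref_area)``.  The tracker's two-threshold
logic needs a score ordering, not calibrated probabilities; the reference
area is chosen so that well-formed rib cross-sections score high while
small tube-tip fragments score low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = ["Detection", "DetectorConfig", "detect_reference", "attach_class_labels"]


@dataclass
class Detection:
    """A rib cross-section candidate on one slice.

    The box is ``(cx, cy, w, h)`` in pixels with the component centroid as
    its centre; ``w`` and ``h`` are the tight extents of the component.
    """

    frame_index: int
    cx: float
    cy: float
    w: float
    h: float
    score: float
    class_label: str | None = None

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.cx, self.cy, self.w, self.h)

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)


@dataclass
class DetectorConfig:
    """Reference-detector parameters.

    ``hu_threshold`` separates bone from soft tissue (default 350 HU, well
    above soft tissue and below cortical bone).  Components with area
    outside ``[min_area_px, max_area_px]`` are dropped, as are components
    whose centroid falls within ``midline_half_width_px`` of the image
    vertical midline (spine/sternum exclusion; 0 disables the band).
    ``score_ref_area_px`` normalises the area-based score.
    """

    hu_threshold: float = 350.0
    min_area_px: int = 8
    max_area_px: int = 5000
    midline_half_width_px: float = 0.0
    score_ref_area_px: float = 100.0
    score_mode: str = "area_ratio"

    def __post_init__(self) -> None:
        if not 0 < self.min_area_px < self.max_area_px:
            raise ValueError("need 0 < min_area_px < max_area_px")
        if self.score_ref_area_px <= 0:
            raise ValueError("score_ref_area_px must be > 0")


def detect_reference(hu_slice: np.ndarray, config: DetectorConfig | None = None,
                     frame_index: int = 0) -> list[Detection]:
    """Detect rib cross-sections on one HU slice.

    Deterministic: detections are ordered by (cy, cx).  Returns an empty
    list when nothing exceeds the threshold.
    """
    if config is None:
        config = DetectorConfig()
    hu_slice = np.asarray(hu_slice)
    mask = hu_slice >= config.hu_threshold
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=1)
    midline = (hu_slice.shape[1] - 1) / 2.0
    out: list[Detection] = []
    for region in measure.regionprops(labels):
        area = region.area
        if area < config.min_area_px or area > config.max_area_px:
            continue
        cy, cx = region.centroid
        if config.midline_half_width_px > 0 and abs(cx - midline) <= config.midline_half_width_px:
            continue
        minr, minc, maxr, maxc = region.bbox
        out.append(
            Detection(
                frame_index=frame_index,
                cx=float(cx),
                cy=float(cy),
                w=float(maxc - minc),
                h=float(maxr - minr),
                score=float(min(1.0, area / config.score_ref_area_px)),
            )
        )
    out.sort(key=lambda d: (d.cy, d.cx))
    return out


def attach_class_labels(detections: list[Detection], ground_truth,
                        max_dist_px: float = 5.0):
    """Label detections with the nearest ground-truth rib crossing.

    Supervised/phantom mode only.  Each detection receives the rib label of
    the nearest ground-truth crossing on its frame within ``max_dist_px``,
    otherwise ``"unknown"``.  Returns ``(labeled, report)`` where ``report``
    lists crossings claimed by more than one detection (duplicates are
    labeled, not dropped).
    """
    labeled: list[Detection] = []
    claims: dict[tuple[int, str], int] = {}
    for det in detections:
        entries = ground_truth.crossings_on_frame(det.frame_index)
        best = None
        best_d = None
        for e in entries:
            d = float(np.hypot(det.cx - e.center_px[0], det.cy - e.center_px[1]))
            if best_d is None or d < best_d:
                best, best_d = e, d
        if best is not None and best_d is not None and best_d <= max_dist_px:
            label = best.rib_id
            claims[(det.frame_index, label)] = claims.get((det.frame_index, label), 0) + 1
        else:
            label = "unknown"
        labeled.append(Detection(det.frame_index, det.cx, det.cy, det.w, det.h,
                                 det.score, label))
    report = {
        "duplicates": sorted(key for key, n in claims.items() if n > 1),
    }
    return labeled, report
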