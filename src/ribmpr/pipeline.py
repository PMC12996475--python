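"""End-to-end reconstruction runner: detection -> tracking -> geometry -> MPR.

This is the library-level pipeline behind the command line: given a CT
volume (and optionally pre-computed detections), it produces labeled rib
trajectories, fitted plane sets, per-rib MPR images, and a completeness
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import detection as det_mod
from . import geometry as geo
from . import mpr as mpr_mod
from . import tracking as trk
from .detection import Detection, DetectorConfig
from .geometry import EvalConfig, LabelingReport, PlaneSet, RibTrajectory
from .io_formats import CTVolume
from .mpr import CompletenessEntry, MPRImage
from .tracking import Track, TrackerConfig

__all__ = ["PipelineConfig", "RibResult", "ReconstructionResult",
           "run_detection", "run_reconstruction"]


@dataclass
class PipelineConfig:
    """All stage parameters of the reconstruction pipeline."""

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    trajectory_mode: str = "geometric"
    merge_dist_mm: float = 8.0
    completeness_tolerance_mm: float = 2.0
    completeness_threshold: float = 0.95
    mpr_margin_mm: float = 10.0
    render_mpr: bool = True


@dataclass
class RibResult:
    """Everything the pipeline produced for one labeled rib."""

    trajectory: RibTrajectory
    plane_set: PlaneSet | None
    completeness: CompletenessEntry | None
    images: list[MPRImage] = field(default_factory=list)
    error: str | None = None

    @property
    def label(self) -> str | None:
        return self.trajectory.label

    @property
    def method(self) -> str | None:
        return self.plane_set.method if self.plane_set else None


@dataclass
class ReconstructionResult:
    tracks: list[Track]
    trajectories: list[RibTrajectory]
    labeling: LabelingReport
    ribs: list[RibResult]

    @property
    def n_labeled(self) -> int:
        return len(self.ribs)

    def rib(self, label: str) -> RibResult:
        for r in self.ribs:
            if r.label == label:
                return r
        raise KeyError(f"no rib labeled {label!r}")


def run_detection(volume: CTVolume, config: DetectorConfig | None = None
                  ) -> list[tuple[int, list[Detection]]]:
    """Reference detector over every slice, as (frame, detections) pairs."""
    if config is None:
        config = DetectorConfig()
    return [(k, det_mod.detect_reference(volume.slice_hu(k), config, frame_index=k))
            for k in range(volume.n_slices)]


def run_reconstruction(volume: CTVolume,
                       config: PipelineConfig | None = None,
                       detections: list[tuple[int, list[Detection]]] | None = None,
                       ) -> ReconstructionResult:
    """Run the full reconstruction pipeline on one volume.

    ``detections`` may be supplied externally (e.g. from a learned
    detector, read through :mod:`ribmpr.io_formats`); otherwise the
    reference detector is run on every slice.
    """
    if config is None:
        config = PipelineConfig()
    if detections is None:
        detections = run_detection(volume, config.detector)

    tracks = trk.byte_track(detections, config.tracker)
    trajectories = geo.tracks_to_trajectories(
        tracks, volume.spacing, mode=config.trajectory_mode,
        merge_dist_mm=config.merge_dist_mm)
    labeled, report = geo.label_ribs(trajectories, volume.shape, volume.spacing)

    ribs: list[RibResult] = []
    for traj in labeled:
        plane_set = None
        comp = None
        images: list[MPRImage] = []
        error = None
        try:
            plane_set = geo.plane_set_for_rib(traj, config.evaluation)
        except ValueError as exc:
            error = str(exc)
        if plane_set is not None:
            comp = mpr_mod.completeness(
                traj, plane_set,
                tolerance_mm=config.completeness_tolerance_mm,
                threshold=config.completeness_threshold)
            if config.render_mpr:
                for pid, plane in enumerate(plane_set.planes, start=1):
                    if plane.degenerate:
                        continue
                    grid = mpr_mod.build_grid(plane, traj, volume.spacing,
                                              margin_mm=config.mpr_margin_mm)
                    images.append(mpr_mod.resample_plane(volume, grid,
                                                         rib_label=traj.label,
                                                         plane_id=pid))
        else:
            comp = CompletenessEntry(rib_label=traj.label, fraction=0.0,
                                     complete=False, method="failed")
        ribs.append(RibResult(trajectory=traj, plane_set=plane_set,
                              completeness=comp, images=images, error=error))
    return ReconstructionResult(tracks=tracks, trajectories=labeled,
                                labeling=report, ribs=ribs)
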