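"""Two-stage (BYTE-style) association of per-frame detections into tracks.

Slices play as video frames; each rib cross-section drifts smoothly from
frame to frame, so a constant-velocity Kalman filter on the box state
``(cx, cy, w, h)`` plus per-frame velocities predicts where each track's
box should appear next.  Association is optimal one-to-one assignment
(Hungarian method) on the cost ``1 - IoU`` between predicted and detected
boxes, gated at a minimum IoU.

The two-stage rule: high-score detections are matched first; tracks left
unmatched then get a second chance against low-score detections (the
"rescue" stage that keeps a track alive across a frame where the detector
was unsure).  New tracks start only from unmatched high-score detections.
Tracks unmatched for more than ``max_age`` frames are finished, and tracks
shorter than ``min_track_length`` are discarded at the end.

Defaults (score_high 0.5, score_low 0.1, iou_gate 0.2, max_age 5,
min_track_length 10) follow published two-stage-tracking conventions and
are all exposed in :class:`TrackerConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection

__all__ = ["TrackerConfig", "Track", "KalmanBoxState", "iou", "byte_track"]

_INFEASIBLE = 1e6


@dataclass
class TrackerConfig:
    score_high: float = 0.5
    score_low: float = 0.1
    iou_gate: float = 0.2
    max_age: int = 5
    min_track_length: int = 10
    process_noise: float = 1.0
    measurement_noise: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.score_low < self.score_high <= 1:
            raise ValueError("need 0 <= score_low < score_high <= 1")
        if not 0 < self.iou_gate < 1:
            raise ValueError("iou_gate must lie in (0, 1)")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")


def iou(box_a, box_b) -> float:
    """Intersection over union of two (cx, cy, w, h) boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("box width/height must be > 0")
    ax1, ay1, ax2, ay2 = ax - aw / 2, ay - ah / 2, ax + aw / 2, ay + ah / 2
    bx1, by1, bx2, by2 = bx - bw / 2, by - bh / 2, bx + bw / 2, by + bh / 2
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = aw * ah + bw * bh - inter
    return float(inter / union)


class KalmanBoxState:
    """Constant-velocity linear-Gaussian filter on (cx, cy, w, h).

    State is 8-dimensional: the box plus its per-frame velocities.
    ``predict`` advances one frame and inflates the covariance; ``update``
    is the standard Kalman correction.  The covariance remains symmetric
    positive semi-definite by construction (Joseph-free form with
    re-symmetrisation).
    """

    def __init__(self, box, process_noise: float = 1.0, measurement_noise: float = 1.0):
        self.x = np.array([box[0], box[1], box[2], box[3], 0, 0, 0, 0], dtype=np.float64)
        self.P = np.diag([1.0, 1.0, 1.0, 1.0, 100.0, 100.0, 100.0, 100.0])
        self.F = np.eye(8)
        self.F[:4, 4:] = np.eye(4)
        self.H = np.zeros((4, 8))
        self.H[:4, :4] = np.eye(4)
        self.Q = process_noise * np.diag([0.25, 0.25, 0.25, 0.25, 1.0, 1.0, 1.0, 1.0])
        self.R = measurement_noise * np.eye(4)

    def predict(self) -> np.ndarray:
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite Kalman state")
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        self.P = (self.P + self.P.T) / 2.0
        return self.box

    def update(self, box) -> None:
        z = np.asarray(box, dtype=np.float64)
        y = z - self.H @ self.x
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(8) - K @ self.H) @ self.P
        self.P = (self.P + self.P.T) / 2.0

    @property
    def box(self) -> np.ndarray:
        return self.x[:4].copy()


@dataclass
class Track:
    """A chain of detections across slices with its Kalman state."""

    track_id: int
    kalman: KalmanBoxState
    history: list[tuple[int, Detection]] = field(default_factory=list)
    status: str = "active"  # active | lost | finished
    time_since_update: int = 0

    def __len__(self) -> int:
        return len(self.history)

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.history]

    @property
    def detections(self) -> list[Detection]:
        return [d for _, d in self.history]


def _match(track_boxes, det_boxes, gate: float):
    """Gated optimal assignment; cost = 1 - IoU with an index tie-break.

    Returns (matches, unmatched_track_idx, unmatched_det_idx).  The
    epsilon tie-break makes equal-cost optima resolve toward lower track
    then lower detection index, so results are bit-reproducible.
    """
    nt, nd = len(track_boxes), len(det_boxes)
    if nt == 0 or nd == 0:
        return [], list(range(nt)), list(range(nd))
    cost = np.full((nt, nd), _INFEASIBLE)
    for i, tb in enumerate(track_boxes):
        if tb[2] <= 0 or tb[3] <= 0:
            # A degenerate Kalman prediction cannot be matched this frame.
            continue
        for j, db in enumerate(det_boxes):
            ov = iou(tb, db)
            if ov >= gate:
                cost[i, j] = 1.0 - ov + 1e-9 * (i * nd + j)
    rows, cols = linear_sum_assignment(cost)
    matches, um_t, um_d = [], set(range(nt)), set(range(nd))
    for i, j in zip(rows, cols):
        if cost[i, j] < _INFEASIBLE / 2:
            matches.append((i, j))
            um_t.discard(i)
            um_d.discard(j)
    return matches, sorted(um_t), sorted(um_d)


def byte_track(frames, config: TrackerConfig | None = None) -> list[Track]:
    """Associate per-frame detections into tracks.

    Parameters
    ----------
    frames:
        Iterable of ``(frame_index, [Detection, ...])`` with strictly
        increasing frame indices (frames with no detections may be present
        as empty lists or simply absent).
    config:
        Tracker thresholds; defaults to :class:`TrackerConfig`.

    Returns the finished tracks of length >= ``min_track_length``,
    deterministically ordered by track id.
    """
    if config is None:
        config = TrackerConfig()
    frames = list(frames)
    idxs = [f for f, _ in frames]
    if any(b <= a for a, b in zip(idxs, idxs[1:])):
        raise ValueError("frames must be ordered by strictly increasing frame index")

    active: list[Track] = []
    done: list[Track] = []
    next_id = 0

    for frame_index, dets in frames:
        preds = [t.kalman.predict() for t in active]
        high = [d for d in dets if d.score >= config.score_high]
        low = [d for d in dets if config.score_low <= d.score < config.score_high]

        matches, um_t, um_d_high = _match(preds, [d.box for d in high], config.iou_gate)
        matched_tracks = set()
        for ti, dj in matches:
            tr = active[ti]
            tr.kalman.update(high[dj].box)
            tr.history.append((frame_index, high[dj]))
            tr.time_since_update = 0
            matched_tracks.add(ti)

        # Rescue stage: remaining tracks vs low-score detections.
        rem = [ti for ti in um_t]
        matches2, um_t2, _ = _match([preds[ti] for ti in rem],
                                    [d.box for d in low], config.iou_gate)
        for ri, dj in matches2:
            tr = active[rem[ri]]
            tr.kalman.update(low[dj].box)
            tr.history.append((frame_index, low[dj]))
            tr.time_since_update = 0
            matched_tracks.add(rem[ri])

        # New tracks from unmatched high-score detections only.
        for dj in um_d_high:
            det = high[dj]
            tr = Track(
                track_id=next_id,
                kalman=KalmanBoxState(det.box, config.process_noise,
                                      config.measurement_noise),
            )
            tr.history.append((frame_index, det))
            active.append(tr)
            next_id += 1

        survivors = []
        for tr in active:
            if tr.history and tr.history[-1][0] == frame_index:
                tr.status = "active"
                survivors.append(tr)
                continue
            tr.time_since_update += 1
            if tr.time_since_update > config.max_age:
                tr.status = "finished"
                done.append(tr)
            else:
                tr.status = "lost"
                survivors.append(tr)
        active = survivors

    for tr in active:
        tr.status = "finished"
        done.append(tr)

    kept = [t for t in done if len(t) >= config.min_track_length]
    kept.sort(key=lambda t: t.track_id)
    return kept
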