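"""Rib trajectories, rib-order labeling, and least-squares plane fitting.

Each finished track becomes a cloud of 3-D points by mapping its detection
centres through the voxel spacing: ``(cx * dx, cy * dy, frame * dz)``.
Labeled trajectories are fitted with an ordinary least-squares plane
``z = a x + b y + c`` — the slice axis is the dependent variable, which is
what makes the near-horizontal first rib (almost no tilt, hence almost no
z variation relative to its in-plane extent) the characteristic degenerate
case.

The fit is accepted when both the correlation coefficient ``r`` (Pearson
correlation between observed and fitted z, which equals the square root of
``R^2`` for OLS with intercept) and the goodness of fit ``R^2`` reach the
threshold 0.99.  A rejected single-plane fit falls back to a two-plane
split: an exhaustive search over contiguous split indices that maximises
the smaller of the two segment ``R^2`` values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import Track

__all__ = [
    "RibTrajectory",
    "FittedPlane",
    "PlaneSet",
    "EvalConfig",
    "LabelingReport",
    "tracks_to_trajectories",
    "label_ribs",
    "fit_plane_lsq",
    "evaluate_plane",
    "two_fit_planes",
    "plane_set_for_rib",
]


@dataclass
class RibTrajectory:
    """An ordered 3-D point sequence for one rib (the per-rib scatter cloud)."""

    points: np.ndarray            # (N, 3) mm, ordered by frame
    frames: np.ndarray            # (N,) source frame indices
    track_ids: tuple[int, ...]
    side: str | None = None      # "left" | "right"
    rib_index: int | None = None  # 1..12

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.frames = np.asarray(self.frames, dtype=np.int64)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def label(self) -> str | None:
        if self.side is None or self.rib_index is None:
            return None
        return f"{self.side[0].upper()}{self.rib_index}"


@dataclass
class FittedPlane:
    """A least-squares plane ``z = a x + b y + c`` with its fit metrics.

    ``degenerate`` marks fits where the metrics are undefined: the z
    variance is below tolerance (a near-horizontal trajectory) or the
    (x, y) support is nearly collinear, so the plane orientation is not
    constrained by the data.
    """

    coef: tuple[float, float, float]
    normal: np.ndarray
    r: float
    r2: float
    degenerate: bool
    index_range: tuple[int, int]  # [start, stop) into the trajectory

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance of each point from the plane, in mm."""
        a, b, c = self.coef
        p = np.asarray(points, dtype=np.float64)
        return np.abs(a * p[:, 0] + b * p[:, 1] + c - p[:, 2]) / np.sqrt(a * a + b * b + 1.0)


@dataclass
class PlaneSet:
    """One- or two-plane description of a rib trajectory."""

    method: str                    # "one_fit" | "two_fit"
    planes: list[FittedPlane]
    split_index: int | None = None

    def plane_for_point(self, i: int) -> FittedPlane:
        for pl in self.planes:
            if pl.index_range[0] <= i < pl.index_range[1]:
                return pl
        raise IndexError(f"point index {i} outside plane ranges")


@dataclass
class EvalConfig:
    """Plane-evaluation parameters.

    ``threshold`` is the accept gate applied to both r and R^2 (0.99);
    ``min_segment_fraction`` keeps two-fit segments from collapsing to a
    handful of points; the degeneracy tolerances flag fits with no usable
    z variance or nearly collinear in-plane support.
    """

    threshold: float = 0.99
    min_segment_fraction: float = 0.2
    min_segment_points: int = 3
    split_guard_points: int = 1
    z_var_tol: float = 1e-9
    xy_collinearity_tol_mm: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Trajectory assembly and labeling
# ---------------------------------------------------------------------------


def _track_points(track: Track, spacing) -> tuple[np.ndarray, np.ndarray]:
    dx, dy, dz = spacing
    frames = np.array(track.frames, dtype=np.int64)
    pts = np.array([[d.cx * dx, d.cy * dy, f * dz]
                    for f, d in track.history], dtype=np.float64)
    return pts, frames


def tracks_to_trajectories(tracks: list[Track], spacing, mode: str = "geometric",
                           merge_dist_mm: float = 15.0) -> list[RibTrajectory]:
    """Map finished tracks to mm-space trajectory candidates.

    In ``class`` mode, tracks sharing a (majority) detection class label are
    merged — the case of a rib whose arc crosses the same slice twice and
    therefore yields two tracks.  In ``geometric`` mode tracks are merged
    when their trajectory endpoints lie within ``merge_dist_mm`` of each
    other; otherwise each track stands alone.
    """
    if not tracks:
        return []
    if mode not in ("geometric", "class"):
        raise ValueError(f"unknown trajectory assembly mode {mode!r}")

    if mode == "class":
        groups: dict[str, list[Track]] = {}
        loners: list[Track] = []
        for t in tracks:
            labels = [d.class_label for d in t.detections if d.class_label
                      and d.class_label != "unknown"]
            if labels:
                vals, counts = np.unique(labels, return_counts=True)
                groups.setdefault(str(vals[np.argmax(counts)]), []).append(t)
            else:
                loners.append(t)
        merged: list[RibTrajectory] = []
        for label in sorted(groups):
            members = groups[label]
            pts = []
            frs = []
            for t in members:
                p, f = _track_points(t, spacing)
                pts.append(p)
                frs.append(f)
            points = np.vstack(pts)
            frames = np.concatenate(frs)
            order = np.argsort(frames, kind="stable")
            merged.append(RibTrajectory(points[order], frames[order],
                                        tuple(t.track_id for t in members)))
        for t in loners:
            p, f = _track_points(t, spacing)
            merged.append(RibTrajectory(p, f, (t.track_id,)))
        return merged

    # geometric mode: single-linkage merge on endpoint proximity
    items = []
    for t in tracks:
        p, f = _track_points(t, spacing)
        items.append({"points": p, "frames": f, "ids": [t.track_id]})
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                ends_a = a["points"][[0, -1]]
                ends_b = b["points"][[0, -1]]
                gap = np.linalg.norm(ends_a[:, None, :] - ends_b[None, :, :], axis=-1).min()
                if gap <= merge_dist_mm:
                    points = np.vstack([a["points"], b["points"]])
                    frames = np.concatenate([a["frames"], b["frames"]])
                    order = np.argsort(frames, kind="stable")
                    items[i] = {"points": points[order], "frames": frames[order],
                                "ids": a["ids"] + b["ids"]}
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return [RibTrajectory(it["points"], it["frames"], tuple(it["ids"])) for it in items]


@dataclass
class LabelingReport:
    """Outcome of rib-order labeling, one entry per side."""

    side_ok: dict[str, bool] = field(default_factory=dict)
    side_counts: dict[str, int] = field(default_factory=dict)

    @property
    def all_labeled(self) -> bool:
        return all(self.side_ok.get(s, False) for s in ("left", "right"))


def label_ribs(trajectories: list[RibTrajectory], volume_shape, spacing
               ) -> tuple[list[RibTrajectory], LabelingReport]:
    """Assign (side, rib 1-12) labels to trajectory candidates by rib order.

    Side is the sign of the mean x relative to the volume midline (x
    increases toward the patient's left).  Within a side, trajectories are
    sorted by their superior-most point (smallest frame index, ties broken
    by mean z then mean y) and numbered 1..12 from the top.  A side that
    does not contain exactly 12 candidates is flagged as failed; the other
    side is still labeled.
    """
    _, _, n_cols = volume_shape
    dx = spacing[0]
    midline_mm = (n_cols - 1) * dx / 2.0

    report = LabelingReport()
    by_side: dict[str, list[RibTrajectory]] = {"left": [], "right": []}
    for traj in trajectories:
        side = "left" if traj.points[:, 0].mean() > midline_mm else "right"
        by_side[side].append(traj)

    labeled: list[RibTrajectory] = []
    for side, cands in by_side.items():
        report.side_counts[side] = len(cands)
        report.side_ok[side] = len(cands) == 12
        cands = sorted(cands, key=lambda t: (int(t.frames.min()),
                                             float(t.points[:, 2].mean()),
                                             float(t.points[:, 1].mean())))
        for idx, traj in enumerate(cands, start=1):
            traj.side = side
            # Indices are assigned even on a failed side (best-effort order);
            # the report flag is the authoritative completeness signal.
            traj.rib_index = idx
            labeled.append(traj)
    labeled.sort(key=lambda t: (t.side != "left", t.rib_index))
    return labeled, report


# ---------------------------------------------------------------------------
# Plane fitting and evaluation
# ---------------------------------------------------------------------------


def fit_plane_lsq(points: np.ndarray, eval_config: EvalConfig | None = None,
                  index_range: tuple[int, int] | None = None) -> FittedPlane:
    """Ordinary least squares of z on (x, y) with intercept.

    ``R^2 = 1 - SS_res / SS_tot`` and ``r`` is the Pearson correlation
    between observed and fitted z (equal to sqrt(R^2) for this model).
    Degenerate fits (z variance below tolerance, or nearly collinear (x, y)
    support) carry NaN metrics and the degenerate flag.  Fewer than three
    points, or exactly collinear points, raise ``ValueError``.
    """
    if eval_config is None:
        eval_config = EvalConfig()
    pts = np.asarray(points, dtype=np.float64)
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"plane fit needs >= 3 points, got {n}")
    if index_range is None:
        index_range = (0, n)

    xy = pts[:, :2] - pts[:, :2].mean(axis=0)
    sv = np.linalg.svd(xy, compute_uv=False)
    if sv[1] < 1e-12 * max(1.0, sv[0]):
        raise ValueError("points are collinear; plane orientation undefined")

    design = np.column_stack([pts[:, 0], pts[:, 1], np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    a, b, c = (float(v) for v in coef)
    normal = np.array([a, b, -1.0]) / np.sqrt(a * a + b * b + 1.0)

    z = pts[:, 2]
    zhat = design @ coef
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    degenerate = (ss_tot / n) < eval_config.z_var_tol or \
        sv[1] / np.sqrt(n) < eval_config.xy_collinearity_tol_mm
    if degenerate:
        r2 = float("nan")
        r = float("nan")
    else:
        ss_res = float(np.sum((z - zhat) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        sz = z - z.mean()
        sh = zhat - zhat.mean()
        denom = np.sqrt(np.sum(sz ** 2) * np.sum(sh ** 2))
        r = float(np.sum(sz * sh) / denom) if denom > 0 else float("nan")
    return FittedPlane((a, b, c), normal, r, r2, bool(degenerate), index_range)


def evaluate_plane(plane: FittedPlane, eval_config: EvalConfig | None = None) -> bool:
    """Accept a plane iff it is non-degenerate and both r and R^2 reach the
    threshold.  Monotone: raising r or R^2 never turns accept into reject."""
    if eval_config is None:
        eval_config = EvalConfig()
    if plane.degenerate:
        return False
    return plane.r >= eval_config.threshold and plane.r2 >= eval_config.threshold


def two_fit_planes(points: np.ndarray, eval_config: EvalConfig | None = None) -> PlaneSet:
    """Split a trajectory into two contiguous segments, each with its own plane.

    Exhaustive search over split indices k (each segment at least
    ``max(min_segment_points, min_segment_fraction * N)`` points); the
    chosen k maximises ``min(R^2_1, R^2_2)``, ties broken by the smallest
    k.  ``split_guard_points`` points on each side of a candidate split are
    excluded from the segment fits (detection centroids next to a crease
    average image content from both planes, so they would otherwise drag
    the estimated split away from the bend); the returned index ranges
    still partition all points.  When every candidate split leaves a
    degenerate segment, the best achievable split is returned with the
    degenerate flags set.
    """
    if eval_config is None:
        eval_config = EvalConfig()
    pts = np.asarray(points, dtype=np.float64)
    n = pts.shape[0]
    g = max(0, int(eval_config.split_guard_points))
    min_seg = max(eval_config.min_segment_points,
                  int(np.ceil(eval_config.min_segment_fraction * n)))
    if n < 2 * (min_seg + g):
        raise ValueError(
            f"trajectory of {n} points is too small to split "
            f"(need >= {2 * (min_seg + g)})")

    best = None
    for k in range(min_seg + g, n - min_seg - g + 1):
        segs = []
        for (lo, hi), (flo, fhi) in (((0, k), (0, k - g)), ((k, n), (k + g, n))):
            try:
                fitted = fit_plane_lsq(pts[flo:fhi], eval_config, (lo, hi))
                segs.append(fitted)
            except ValueError:
                segs.append(None)
        if any(s is None for s in segs):
            continue
        n_ok = sum(not s.degenerate for s in segs)
        score = min((s.r2 for s in segs if not s.degenerate), default=-np.inf)
        key = (n_ok, score, -k)  # larger is better; -k prefers the smallest k on ties
        if best is None or key > best[0]:
            best = (key, k, segs)
    if best is None:
        raise ValueError("no admissible split found")
    _, k, segs = best
    return PlaneSet(method="two_fit", planes=segs, split_index=k)


def plane_set_for_rib(trajectory: RibTrajectory, eval_config: EvalConfig | None = None
                      ) -> PlaneSet:
    """Fit a single plane; on rejection, fall back to the two-plane split."""
    if eval_config is None:
        eval_config = EvalConfig()
    single = fit_plane_lsq(trajectory.points, eval_config)
    if evaluate_plane(single, eval_config):
        return PlaneSet(method="one_fit", planes=[single])
    return two_fit_planes(trajectory.points, eval_config)
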