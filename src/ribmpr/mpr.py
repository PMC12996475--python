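"""Oblique multiplanar resampling and a geometric completeness proxy.

An MPR image is the CT volume sampled on a regular 2-D grid lying in a
fitted rib plane.  The grid's first in-plane axis follows the rib's
principal direction projected into the plane, the second completes a
right-handed orthonormal frame with the plane normal; sample spacing
defaults to the smallest in-plane voxel spacing and a margin keeps the
projected trajectory away from the image border.  Interpolation is
trilinear, which reproduces linear HU fields exactly; samples outside the
volume are filled with air (-1000 HU) and masked.

Completeness here is a geometric proxy, not a reader judgment: the
arc-length fraction of the trajectory lying within a perpendicular
tolerance of its segment's plane.  Degenerate planes cover nothing, so a
rib whose fits all failed (the first-rib case) reports as incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import FittedPlane, PlaneSet, RibTrajectory
from .io_formats import CTVolume

__all__ = [
    "MPRGrid",
    "MPRImage",
    "CompletenessEntry",
    "build_grid",
    "resample_plane",
    "completeness",
]


@dataclass
class MPRGrid:
    """Regular sampling grid in a plane: origin plus orthonormal axes u, v."""

    origin: np.ndarray        # (3,) mm, grid sample (row 0, col 0)
    u: np.ndarray             # (3,) unit, along columns
    v: np.ndarray             # (3,) unit, along rows
    sample_spacing: float     # mm
    extent: tuple[int, int]   # (rows, cols)

    def world_points(self) -> np.ndarray:
        """(rows, cols, 3) world-mm coordinates of every grid sample."""
        rows, cols = self.extent
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return (self.origin[None, None, :]
                + cc[..., None] * self.sample_spacing * self.u[None, None, :]
                + rr[..., None] * self.sample_spacing * self.v[None, None, :])


@dataclass
class MPRImage:
    """Resampled HU image with its grid and out-of-volume mask."""

    hu: np.ndarray            # (rows, cols) float
    mask: np.ndarray          # True where the sample fell outside the volume
    grid: MPRGrid
    rib_label: str | None = None
    plane_id: int = 1


def build_grid(plane: FittedPlane, trajectory: RibTrajectory, spacing,
               margin_mm: float = 10.0, sample_spacing: float | None = None) -> MPRGrid:
    """Construct the sampling grid for one fitted plane.

    ``u`` is the unit projection of the trajectory's principal direction
    onto the plane, ``v = normal x u``; the extent covers every projected
    trajectory point plus ``margin_mm`` on each side.  Rigid-transform
    equivariant: rotating volume and trajectory together rotates the grid
    identically.
    """
    if plane.degenerate:
        raise ValueError("cannot build an MPR grid on a degenerate plane")
    if sample_spacing is None:
        sample_spacing = float(min(spacing[0], spacing[1]))
    pts = np.asarray(trajectory.points, dtype=np.float64)
    lo, hi = plane.index_range
    seg = pts[lo:hi] if hi - lo >= 2 else pts

    n = np.asarray(plane.normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    centered = seg - seg.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    u = d - np.dot(d, n) * n
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise ValueError("trajectory principal direction is parallel to the plane normal")
    u = u / nu
    v = np.cross(n, u)

    # Project trajectory points into the plane through its centroid.
    centroid = seg.mean(axis=0)
    rel = seg - centroid
    pu = rel @ u
    pv = rel @ v
    umin, umax = pu.min() - margin_mm, pu.max() + margin_mm
    vmin, vmax = pv.min() - margin_mm, pv.max() + margin_mm
    cols = int(np.ceil((umax - umin) / sample_spacing)) + 1
    rows = int(np.ceil((vmax - vmin) / sample_spacing)) + 1
    origin = centroid + umin * u + vmin * v
    return MPRGrid(origin=origin, u=u, v=v, sample_spacing=float(sample_spacing),
                   extent=(rows, cols))


def resample_plane(volume: CTVolume, grid: MPRGrid, rib_label: str | None = None,
                   plane_id: int = 1) -> MPRImage:
    """Trilinear resampling of the volume on the grid.

    Out-of-volume samples are filled with -1000 HU and flagged in the mask.
    """
    dx, dy, dz = volume.spacing
    pts = grid.world_points()            # (rows, cols, 3)
    ii = pts[..., 0] / dx
    jj = pts[..., 1] / dy
    kk = pts[..., 2] / dz
    sampled = map_coordinates(volume.voxels.astype(np.float64), [kk, jj, ii],
                              order=1, mode="constant", cval=np.nan)
    mask = np.isnan(sampled)
    sampled[mask] = -1000.0
    return MPRImage(hu=sampled, mask=mask, grid=grid, rib_label=rib_label,
                    plane_id=plane_id)


@dataclass
class CompletenessEntry:
    """Per-rib geometric completeness: covered arc-length fraction."""

    rib_label: str | None
    fraction: float
    complete: bool
    method: str


def _arc_weights(points: np.ndarray) -> np.ndarray:
    """Arc-length weight per point: half the adjacent chord lengths."""
    n = points.shape[0]
    if n == 1:
        return np.ones(1)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    w = np.zeros(n)
    w[:-1] += seg / 2.0
    w[1:] += seg / 2.0
    if w.sum() == 0:
        return np.ones(n) / n
    return w


def completeness(trajectory: RibTrajectory, plane_set: PlaneSet,
                 tolerance_mm: float = 2.0, threshold: float = 0.95) -> CompletenessEntry:
    """Covered fraction of the trajectory's arc length.

    A point counts as covered when it lies within ``tolerance_mm``
    perpendicular distance of its own segment's plane; points governed by
    a degenerate plane are uncovered.  Monotone non-decreasing in
    ``tolerance_mm``.
    """
    pts = np.asarray(trajectory.points, dtype=np.float64)
    weights = _arc_weights(pts)
    covered = np.zeros(len(pts), dtype=bool)
    for plane in plane_set.planes:
        lo, hi = plane.index_range
        if plane.degenerate:
            continue
        d = plane.distance(pts[lo:hi])
        covered[lo:hi] = d <= tolerance_mm
    fraction = float(np.sum(weights * covered) / np.sum(weights))
    return CompletenessEntry(rib_label=trajectory.label, fraction=fraction,
                             complete=bool(fraction >= threshold),
                             method=plane_set.method)
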