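"""Synthetic thorax phantom with 24 rib-like structures and exact ground truth.

The phantom stands in for clinical CT examinations: a soft-tissue body
cylinder (about 40 HU) in air (about -1000 HU) containing 24 bone-density
tubes (about 700 HU), one per rib, plus optional fracture-like defects.

Each rib centerline is an elliptical arc in plan view,

    x(t) = cx + A cos t,   y(t) = cy + B sin t,

with z given by a plane ``z = cz + p (x - cx) + q (y - cy)``; the tilt
angle against the axial plane is ``atan(q)`` (with ``p = 0`` for unbent
ribs).  A bent rib switches, at a chosen arc fraction, to a second plane
obtained by rotating the first about the lateral axis through the bend
point by the dihedral bend angle (a crease running laterally, like the
tilt change at the costal angle).  Because centerlines are plane curves by
construction, the true plane parameters exist in closed form, which is
what makes exact plane-recovery tests possible.

The tube is rasterized as the union of spheres of the tube radius centred
on a dense centerline polyline; the ground truth for each axial slice
(band centre, tight box, area) is computed from the same polyline with the
same union-of-spheres model, so ground truth and rasterization agree by
construction.

All randomness (noise, per-patient jitter, fracture sampling) flows from a
single integer seed; the same seed reproduces the volume bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_formats import CTVolume

__all__ = [
    "HU_AIR",
    "HU_SOFT_TISSUE",
    "HU_BONE",
    "HU_CALLUS",
    "FractureSpec",
    "RibSpec",
    "CrossingEntry",
    "RibTruth",
    "GroundTruth",
    "default_rib_specs",
    "default_study_spec",
    "generate_phantom",
    "insert_fracture",
]

HU_AIR = -1000.0
HU_SOFT_TISSUE = 40.0
HU_BONE = 700.0
HU_CALLUS = 1100.0

FRACTURE_TYPES = ("displaced", "non-displaced", "buckle", "old")

DEFAULT_SHAPE = (148, 240, 240)        # (slices, rows, cols)
DEFAULT_SPACING = (1.0, 1.0, 1.5)     # (dx, dy, dz) mm

_CENTERLINE_STEP_MM = 0.5


@dataclass(frozen=True)
class FractureSpec:
    """A fracture-like defect on one rib.

    ``arc_position`` is the fractional position along the centerline arc
    (0 = posterior/start, 1 = end).  Geometry parameters are stand-ins for
    the four radiological patterns: a displaced fracture offsets the distal
    fragment, a non-displaced one carves a thin low-HU gap, a buckle bulges
    the cortex locally, and an old (healed) fracture carries a high-HU
    callus sphere.
    """

    type: str
    arc_position: float
    gap_mm: float = 1.5
    offset_mm: float = 5.0
    callus_radius_mm: float = 7.0
    bulge_factor: float = 1.6

    def __post_init__(self) -> None:
        if self.type not in FRACTURE_TYPES:
            raise ValueError(f"unknown fracture type {self.type!r}; "
                             f"expected one of {FRACTURE_TYPES}")
        if not 0.0 < self.arc_position < 1.0:
            raise ValueError("arc_position must lie in (0, 1)")


@dataclass(frozen=True)
class RibSpec:
    """Geometry of one rib-like tube.

    ``center`` is the plan-view ellipse centre (mm, volume-local
    coordinates); ``semi_axes = (A, B)`` the ellipse semi-axes;
    ``arc_deg`` the start/end angles of the arc; ``tilt_deg`` the angle of
    the rib plane against the axial plane.  A non-zero ``bend_angle_deg``
    makes the distal part (beyond ``bend_fraction`` of the arc) lie in a
    second plane rotated about the lateral axis through the bend point by
    that dihedral angle, in the direction given by ``bend_sign`` (-1 makes
    the distal segment shallower).
    """

    side: str
    index: int
    center: tuple[float, float, float]
    semi_axes: tuple[float, float]
    arc_deg: tuple[float, float]
    tilt_deg: float
    tube_radius_mm: float
    bend_angle_deg: float = 0.0
    bend_fraction: float = 0.5
    bend_sign: int = 1
    bend_axis_deg: float = 0.0
    fracture: FractureSpec | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left or right, got {self.side!r}")
        if not 1 <= self.index <= 12:
            raise ValueError(f"rib index must be 1..12, got {self.index}")
        if self.tilt_deg < 0:
            raise ValueError("tilt must be >= 0")
        if self.tube_radius_mm <= 0:
            raise ValueError("tube radius must be > 0")
        if self.arc_deg[0] == self.arc_deg[1]:
            raise ValueError("arc must have non-zero length")

    @property
    def rib_id(self) -> str:
        return f"{self.side[0].upper()}{self.index}"


# ---------------------------------------------------------------------------
# Centerline construction
# ---------------------------------------------------------------------------


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def rib_centerline(spec: RibSpec) -> dict:
    """Sample the rib centerline and return it with its true plane(s).

    Returns a dict with ``points`` (N, 3), ``arc`` cumulative arc length,
    ``planes`` as a list of ``(a, b, c)`` for ``z = a x + b y + c`` with
    their sample index ranges, and for bent ribs the bend sample index and
    the z value at the bend.
    """
    cx, cy, cz = spec.center
    A, B = spec.semi_axes
    t0, t1 = np.deg2rad(spec.arc_deg[0]), np.deg2rad(spec.arc_deg[1])
    # Sample density from plan-view arc length.
    approx_len = 0.5 * (A + B) * abs(t1 - t0) * 1.5
    n = max(200, int(approx_len / _CENTERLINE_STEP_MM))
    t = np.linspace(t0, t1, n)
    x = cx + A * np.cos(t)
    y = cy + B * np.sin(t)

    q1 = np.tan(np.deg2rad(spec.tilt_deg))
    p1 = 0.0
    z = cz + p1 * (x - cx) + q1 * (y - cy)
    plane1 = (p1, q1, cz - p1 * cx - q1 * cy)
    planes = [{"coef": plane1, "range": (0, n)}]
    bend_index = None
    bend_z = None

    if spec.bend_angle_deg:
        # Locate the bend at the requested fraction of plan-view arc length.
        seg = np.hypot(np.diff(x), np.diff(y))
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        ib = int(np.searchsorted(arc, spec.bend_fraction * arc[-1]))
        ib = min(max(ib, 2), n - 3)
        pb = np.array([x[ib], y[ib], z[ib]])
        # The distal plane is the proximal one rotated by the dihedral bend
        # angle about an in-plane crease axis through the bend point;
        # ``bend_axis_deg`` is the axial-plane azimuth of that axis
        # (0 = lateral, 90 = antero-posterior).
        alpha = np.deg2rad(spec.bend_axis_deg)
        axis = np.array([np.cos(alpha), np.sin(alpha), 0.0])
        n1 = np.array([p1, q1, -1.0])
        n1 /= np.linalg.norm(n1)
        n2 = _rotation_about_axis(axis,
                                  spec.bend_sign *
                                  np.deg2rad(spec.bend_angle_deg)) @ n1
        if abs(n2[2]) < 1e-6:
            raise ValueError(f"rib {spec.rib_id}: bend makes the distal plane "
                             "near-vertical")
        a2 = -n2[0] / n2[2]
        b2 = -n2[1] / n2[2]
        c2 = pb[2] - a2 * pb[0] - b2 * pb[1]
        z = z.copy()
        z[ib:] = a2 * x[ib:] + b2 * y[ib:] + c2
        planes = [{"coef": plane1, "range": (0, ib)},
                  {"coef": (a2, b2, c2), "range": (ib, n)}]
        bend_index = ib
        bend_z = float(pb[2])

    points = np.column_stack([x, y, z])
    seg3 = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc3 = np.concatenate([[0.0], np.cumsum(seg3)])
    return {
        "points": points,
        "arc": arc3,
        "planes": planes,
        "bend_index": bend_index,
        "bend_z": bend_z,
    }


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class CrossingEntry:
    """One rib band on one axial slice: centre, tight box, and area."""

    rib_id: str
    frame: int
    center_px: tuple[float, float]
    box: tuple[float, float, float, float]  # (cx, cy, w, h) px
    area_px: float


@dataclass
class RibTruth:
    """Exact geometry of one rib: centerline, true plane(s), labels."""

    rib_id: str
    side: str
    index: int
    centerline: np.ndarray                  # (N, 3) mm
    planes: list[dict]                      # {"coef": (a, b, c), "range": (lo, hi)}
    tube_radius_mm: float
    bend_index: int | None = None
    bend_z: float | None = None
    fracture: bool = False
    fracture_type: str | None = None

    @property
    def is_bent(self) -> bool:
        return len(self.planes) == 2

    def plane_normals(self) -> list[np.ndarray]:
        out = []
        for pl in self.planes:
            a, b, _ = pl["coef"]
            v = np.array([a, b, -1.0])
            out.append(v / np.linalg.norm(v))
        return out


@dataclass
class GroundTruth:
    """Full phantom ground truth: per-rib geometry plus per-slice crossings."""

    ribs: dict[str, RibTruth]
    crossings: list[CrossingEntry]
    volume_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    _frame_index: dict[int, list[CrossingEntry]] | None = field(
        default=None, repr=False, compare=False)

    def crossings_on_frame(self, k: int) -> list[CrossingEntry]:
        if self._frame_index is None:
            idx: dict[int, list[CrossingEntry]] = {}
            for e in self.crossings:
                idx.setdefault(e.frame, []).append(e)
            self._frame_index = idx
        return self._frame_index.get(k, [])

    def frames_for_rib(self, rib_id: str) -> list[int]:
        return sorted(e.frame for e in self.crossings if e.rib_id == rib_id)

    def to_json(self, path: "str | Path") -> Path:
        payload = {
            "volume_shape": list(self.volume_shape),
            "spacing": list(self.spacing),
            "ribs": {
                rid: {
                    "side": rt.side,
                    "index": rt.index,
                    "centerline": rt.centerline.tolist(),
                    "planes": [{"coef": list(p["coef"]), "range": list(p["range"])}
                               for p in rt.planes],
                    "tube_radius_mm": rt.tube_radius_mm,
                    "bend_index": rt.bend_index,
                    "bend_z": rt.bend_z,
                    "fracture": rt.fracture,
                    "fracture_type": rt.fracture_type,
                }
                for rid, rt in self.ribs.items()
            },
            "crossings": [
                {"rib_id": e.rib_id, "frame": e.frame,
                 "center_px": list(e.center_px), "box": list(e.box),
                 "area_px": e.area_px}
                for e in self.crossings
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: "str | Path") -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        ribs = {
            rid: RibTruth(
                rib_id=rid,
                side=d["side"],
                index=d["index"],
                centerline=np.asarray(d["centerline"], dtype=np.float64),
                planes=[{"coef": tuple(p["coef"]), "range": tuple(p["range"])}
                        for p in d["planes"]],
                tube_radius_mm=d["tube_radius_mm"],
                bend_index=d["bend_index"],
                bend_z=d["bend_z"],
                fracture=d["fracture"],
                fracture_type=d["fracture_type"],
            )
            for rid, d in payload["ribs"].items()
        }
        crossings = [
            CrossingEntry(e["rib_id"], e["frame"], tuple(e["center_px"]),
                          tuple(e["box"]), e["area_px"])
            for e in payload["crossings"]
        ]
        return cls(ribs=ribs, crossings=crossings,
                   volume_shape=tuple(payload["volume_shape"]),
                   spacing=tuple(payload["spacing"]))


# ---------------------------------------------------------------------------
# Default study geometry
# ---------------------------------------------------------------------------


def default_rib_specs(size_scale: float = 1.0, z_shift_mm: float = 0.0) -> list[RibSpec]:
    """The 24-rib default geometry for the standard phantom grid.

    Ribs 2-12 share a thoracic plan-view ellipse (A = 85 mm, B = 65 mm)
    with a 30 degree tilt and 5 mm tube radius, stacked 13 mm apart.  The
    first ribs are smaller (A = 55, B = 40 mm), broader (7 mm radius) and
    exactly horizontal — the degenerate-fit case.  Ribs 9-12 carry a
    16 degree dihedral bend at mid-arc, exercising the two-plane fit.
    """
    nz, ny, nx = DEFAULT_SHAPE
    dx, dy, dz = DEFAULT_SPACING
    cx = (nx - 1) * dx / 2.0
    cy = (ny - 1) * dy / 2.0

    specs: list[RibSpec] = []
    for side in ("left", "right"):
        # Both arcs run superior -> inferior along the parameter, so the
        # bent distal half is the inferior half on either side.
        arc = (-60.0, 60.0) if side == "left" else (240.0, 120.0)
        for index in range(1, 13):
            if index == 1:
                spec = RibSpec(side=side, index=1,
                               center=(cx, cy, 12.0 + z_shift_mm),
                               semi_axes=(55.0 * size_scale, 40.0 * size_scale),
                               arc_deg=arc, tilt_deg=0.0, tube_radius_mm=8.0)
            elif index <= 8:
                zc = 45.0 + (index - 2) * 14.0 + z_shift_mm
                spec = RibSpec(side=side, index=index,
                               center=(cx, cy, zc),
                               semi_axes=(85.0 * size_scale, 65.0 * size_scale),
                               arc_deg=arc, tilt_deg=30.0, tube_radius_mm=4.0)
            else:
                # Bent lower ribs on a smaller ring, so their shallow distal
                # bands never approach the steeper ribs above on any slice.
                zc = 149.0 + (index - 9) * 20.0 + z_shift_mm
                spec = RibSpec(side=side, index=index,
                               center=(cx, cy, zc),
                               semi_axes=(66.0 * size_scale, 49.0 * size_scale),
                               arc_deg=arc, tilt_deg=30.0, tube_radius_mm=4.0,
                               bend_angle_deg=20.0, bend_fraction=0.3,
                               bend_sign=-1)
            specs.append(spec)
    return specs


def default_study_spec(n_patients: int, fracture_prevalence: float = 0.193,
                       seed: int = 0) -> list[list[RibSpec]]:
    """Per-patient rib spec sets emulating the study's case mix.

    Fracture indicators are drawn i.i.d. Bernoulli(``fracture_prevalence``)
    per rib (the per-rib analysis is the primary unit; no within-patient
    correlation is imposed).  Fracture types are sampled uniformly from the
    four categories.  Patients get a small global size jitter so volumes
    are not identical.
    """
    if not 0.0 <= fracture_prevalence <= 1.0:
        raise ValueError("fracture_prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    patients: list[list[RibSpec]] = []
    for _ in range(n_patients):
        scale = float(rng.uniform(0.98, 1.02))
        z_shift = float(rng.uniform(-1.0, 1.0))
        specs = default_rib_specs(size_scale=scale, z_shift_mm=z_shift)
        out = []
        for spec in specs:
            if rng.random() < fracture_prevalence:
                ftype = FRACTURE_TYPES[rng.integers(0, len(FRACTURE_TYPES))]
                frac = FractureSpec(type=ftype,
                                    arc_position=float(rng.uniform(0.25, 0.75)))
                spec = replace(spec, fracture=frac)
            out.append(spec)
        patients.append(out)
    return patients


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _paint_spheres(voxels: np.ndarray, spacing, centers: np.ndarray,
                   radius: float, value: float,
                   only_value: float | None = None) -> None:
    """Set voxels within ``radius`` of any centre to ``value`` (in place).

    With ``only_value`` set, only voxels currently equal to that value are
    overwritten (used to erase bone back to soft tissue without touching
    the background).
    """
    dx, dy, dz = spacing
    nz, ny, nx = voxels.shape
    for px, py, pz in centers:
        i0 = max(0, int(np.ceil((px - radius) / dx)))
        i1 = min(nx - 1, int(np.floor((px + radius) / dx)))
        j0 = max(0, int(np.ceil((py - radius) / dy)))
        j1 = min(ny - 1, int(np.floor((py + radius) / dy)))
        k0 = max(0, int(np.ceil((pz - radius) / dz)))
        k1 = min(nz - 1, int(np.floor((pz + radius) / dz)))
        if i1 < i0 or j1 < j0 or k1 < k0:
            continue
        xs = np.arange(i0, i1 + 1) * dx - px
        ys = np.arange(j0, j1 + 1) * dy - py
        zs = np.arange(k0, k1 + 1) * dz - pz
        d2 = (zs[:, None, None] ** 2 + ys[None, :, None] ** 2
              + xs[None, None, :] ** 2)
        mask = d2 <= radius * radius
        sub = voxels[k0:k1 + 1, j0:j1 + 1, i0:i1 + 1]
        if only_value is not None:
            mask &= sub == only_value
        sub[mask] = value


def _check_inside(points: np.ndarray, radius: float, shape, spacing) -> bool:
    nz, ny, nx = shape
    dx, dy, dz = spacing
    hi = np.array([(nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz])
    return bool(np.all(points - radius >= 0.0) and np.all(points + radius <= hi))


def _compute_crossings(rib: RibTruth, shape, spacing) -> list[CrossingEntry]:
    """Per-slice band centre/box/area from the union-of-spheres tube model."""
    dx, dy, dz = spacing
    nz = shape[0]
    pts = rib.centerline
    r = rib.tube_radius_mm
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    ds = np.zeros(len(pts))
    ds[:-1] += seg / 2.0
    ds[1:] += seg / 2.0

    out: list[CrossingEntry] = []
    zmin, zmax = pts[:, 2].min() - r, pts[:, 2].max() + r
    k_lo = max(0, int(np.ceil(zmin / dz)))
    k_hi = min(nz - 1, int(np.floor(zmax / dz)))
    for k in range(k_lo, k_hi + 1):
        delta = k * dz - pts[:, 2]
        mask = np.abs(delta) < r
        if not mask.any():
            continue
        # contiguous runs of in-band samples
        idx = np.flatnonzero(mask)
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, splits + 1)
        for run in runs:
            if len(run) < 2:
                continue
            w = np.sqrt(np.maximum(r * r - delta[run] ** 2, 0.0))
            weight = w * ds[run]
            total = weight.sum()
            if total <= 0:
                continue
            xr, yr = pts[run, 0], pts[run, 1]
            cx = float((weight * xr).sum() / total)
            cy = float((weight * yr).sum() / total)
            x_lo, x_hi = float((xr - w).min()), float((xr + w).max())
            y_lo, y_hi = float((yr - w).min()), float((yr + w).max())
            area = float(2.0 * (w * ds[run]).sum() / (dx * dy))
            out.append(CrossingEntry(
                rib_id=rib.rib_id,
                frame=k,
                center_px=(cx / dx, cy / dy),
                box=(cx / dx, cy / dy, (x_hi - x_lo) / dx, (y_hi - y_lo) / dy),
                area_px=area,
            ))
    return out


def generate_phantom(spec_set: list[RibSpec] | None = None,
                     volume_shape: tuple[int, int, int] = DEFAULT_SHAPE,
                     spacing: tuple[float, float, float] = DEFAULT_SPACING,
                     noise_sd: float = 1.0,
                     seed: int = 0,
                     body_semi_axes: tuple[float, float] = (100.0, 80.0),
                     ) -> tuple[CTVolume, GroundTruth]:
    """Rasterize a 24-rib phantom volume with full ground truth.

    ``volume_shape`` is (slices, rows, cols); slices play superior to
    inferior.  ``noise_sd`` is the standard deviation of additive Gaussian
    noise in HU (0 leaves every voxel at a nominal tissue value).  The
    same spec set and seed reproduce the voxel array bit for bit.
    """
    if spec_set is None:
        spec_set = default_rib_specs()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    nz, ny, nx = volume_shape
    dx, dy, dz = spacing

    voxels = np.full(volume_shape, HU_AIR, dtype=np.float32)
    # Soft-tissue body cylinder (plan-view ellipse, constant across slices).
    xs = np.arange(nx) * dx - (nx - 1) * dx / 2.0
    ys = np.arange(ny) * dy - (ny - 1) * dy / 2.0
    rx, ry = body_semi_axes
    body = (xs[None, :] / rx) ** 2 + (ys[:, None] / ry) ** 2 <= 1.0
    voxels[:, body] = HU_SOFT_TISSUE

    ribs: dict[str, RibTruth] = {}
    outside: list[str] = []
    for spec in spec_set:
        cl = rib_centerline(spec)
        if not _check_inside(cl["points"], spec.tube_radius_mm, volume_shape, spacing):
            outside.append(spec.rib_id)
            continue
        rib = RibTruth(
            rib_id=spec.rib_id, side=spec.side, index=spec.index,
            centerline=cl["points"], planes=cl["planes"],
            tube_radius_mm=spec.tube_radius_mm,
            bend_index=cl["bend_index"], bend_z=cl["bend_z"],
        )
        ribs[spec.rib_id] = rib
        _paint_spheres(voxels, spacing, cl["points"], spec.tube_radius_mm, HU_BONE)
    if outside:
        raise ValueError(f"rib tube(s) exit the volume: {', '.join(sorted(outside))}")

    gt = GroundTruth(ribs=ribs, crossings=[], volume_shape=volume_shape,
                     spacing=spacing)

    # Fracture defects before noise, so defects have crisp nominal HU.
    for spec in spec_set:
        if spec.fracture is not None:
            _apply_fracture(voxels, gt, spec.rib_id, spec.fracture, spacing)

    crossings: list[CrossingEntry] = []
    for rid in sorted(ribs):
        crossings.extend(_compute_crossings(ribs[rid], volume_shape, spacing))
    crossings.sort(key=lambda e: (e.frame, e.center_px[1], e.center_px[0]))
    gt.crossings = crossings

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        voxels = voxels + rng.normal(0.0, noise_sd, size=voxels.shape).astype(np.float32)

    return CTVolume(voxels, spacing), gt


# ---------------------------------------------------------------------------
# Fracture insertion
# ---------------------------------------------------------------------------


def _apply_fracture(voxels: np.ndarray, gt: GroundTruth, rib_id: str,
                    fspec: FractureSpec, spacing) -> None:
    rib = gt.ribs[rib_id]
    pts = rib.centerline
    r = rib.tube_radius_mm
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    i_f = int(np.searchsorted(arc, fspec.arc_position * arc[-1]))
    i_f = min(max(i_f, 1), len(pts) - 2)
    p_f = pts[i_f]

    if fspec.type == "non-displaced":
        # Thin low-HU gap: a slab, normal to the local tangent, through the tube.
        tangent = pts[min(i_f + 1, len(pts) - 1)] - pts[max(i_f - 1, 0)]
        tangent = tangent / np.linalg.norm(tangent)
        near = np.abs(arc - arc[i_f]) <= (r + fspec.gap_mm)
        dx_, dy_, dz_ = spacing
        lo = p_f - (r + fspec.gap_mm)
        hi = p_f + (r + fspec.gap_mm)
        i0, i1 = max(0, int(lo[0] / dx_)), min(voxels.shape[2] - 1, int(np.ceil(hi[0] / dx_)))
        j0, j1 = max(0, int(lo[1] / dy_)), min(voxels.shape[1] - 1, int(np.ceil(hi[1] / dy_)))
        k0, k1 = max(0, int(lo[2] / dz_)), min(voxels.shape[0] - 1, int(np.ceil(hi[2] / dz_)))
        kk, jj, ii = np.meshgrid(np.arange(k0, k1 + 1), np.arange(j0, j1 + 1),
                                 np.arange(i0, i1 + 1), indexing="ij")
        world = np.stack([ii * dx_, jj * dy_, kk * dz_], axis=-1)
        d2 = ((world[..., None, :] - pts[near][None, None, None, :, :]) ** 2).sum(-1)
        in_tube = d2.min(axis=-1) <= (r + 0.25) ** 2
        slab = np.abs((world - p_f) @ tangent) <= fspec.gap_mm / 2.0
        sub = voxels[k0:k1 + 1, j0:j1 + 1, i0:i1 + 1]
        sub[in_tube & slab & (sub == HU_BONE)] = HU_SOFT_TISSUE
    elif fspec.type == "displaced":
        offset = np.array([0.0, 0.0, fspec.offset_mm])
        distal = pts[i_f:]
        proximal = pts[:i_f]
        # Erase the distal fragment, restore the junction, redraw displaced.
        _paint_spheres(voxels, spacing, distal, r, HU_SOFT_TISSUE,
                       only_value=HU_BONE)
        _paint_spheres(voxels, spacing, proximal, r, HU_BONE)
        new_distal = distal + offset
        _paint_spheres(voxels, spacing, new_distal, r, HU_BONE)
        rib.centerline = np.vstack([proximal, new_distal])
    elif fspec.type == "buckle":
        near = np.abs(arc - arc[i_f]) <= r
        _paint_spheres(voxels, spacing, pts[near], r * fspec.bulge_factor, HU_BONE)
    elif fspec.type == "old":
        _paint_spheres(voxels, spacing, p_f[None, :], fspec.callus_radius_mm,
                       HU_CALLUS)
    rib.fracture = True
    rib.fracture_type = fspec.type


def insert_fracture(volume: CTVolume, ground_truth: GroundTruth, rib_id: str,
                    fracture_spec: FractureSpec) -> tuple[CTVolume, GroundTruth]:
    """Insert a fracture-like defect into an existing phantom.

    Returns a new ``(CTVolume, GroundTruth)`` pair; the inputs are not
    modified.  Per-slice crossings of the affected rib are recomputed from
    the (possibly displaced) centerline.
    """
    if rib_id not in ground_truth.ribs:
        raise KeyError(f"unknown rib id {rib_id!r}")
    import copy

    voxels = volume.voxels.copy()
    gt = copy.deepcopy(ground_truth)
    gt._frame_index = None
    _apply_fracture(voxels, gt, rib_id, fracture_spec, volume.spacing)
    gt.crossings = [e for e in gt.crossings if e.rib_id != rib_id]
    gt.crossings.extend(_compute_crossings(gt.ribs[rib_id], gt.volume_shape,
                                           gt.spacing))
    gt.crossings.sort(key=lambda e: (e.frame, e.center_px[1], e.center_px[0]))
    return CTVolume(voxels, volume.spacing, volume.origin), gt
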