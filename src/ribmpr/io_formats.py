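"""Readers and writers for CT volumes, detection tables, and MPR exports.

Coordinate convention
---------------------
Voxel indices are ``(slice k, row j, col i)``, 0-based, with slices stored
superior to inferior so the frame index increases toward the feet (rib 1
appears at the smallest frame index).  Volume-local millimetre coordinates
are ``x = i * dx``, ``y = j * dy``, ``z = k * dz``; ``x`` increases toward
the patient's left, ``y`` posteriorly, ``z`` inferiorly along the stored
slice order.

Detection boxes are ``(cx, cy, w, h)`` in floating-point pixel units,
centre plus width/height; conversion to corner form happens only inside
IoU computations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CTVolume",
    "read_ct_volume",
    "write_ct_volume",
    "write_detections",
    "read_detections",
    "write_mpr_image",
    "read_mpr_sidecar",
]

DETECTIONS_SCHEMA_VERSION = 1
_DETECTION_COLUMNS = ("frame_index", "cx", "cy", "w", "h", "score", "class_label")


@dataclass
class CTVolume:
    """A 3-D CT grid in Hounsfield units.

    Attributes
    ----------
    voxels:
        ``(n_slices, n_rows, n_cols)`` float array of HU values.
    spacing:
        ``(dx, dy, dz)`` voxel spacing in mm (col, row, slice).
    origin:
        World-mm position of voxel (0, 0, 0).
    axis_convention:
        Tag describing slice ordering; ``"superior-inferior"`` means frame
        index increases toward the feet.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_convention: str = "superior-inferior"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3-D array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slice_hu(self, k: int) -> np.ndarray:
        """Axial slice ``k`` as a 2-D HU array (rows, cols)."""
        return self.voxels[k]


# ---------------------------------------------------------------------------
# CT volume I/O
# ---------------------------------------------------------------------------


def read_ct_volume(path: "str | Path", format_hint: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Slices are returned superior to inferior (strictly decreasing world z
    with increasing frame index).  DICOM pixel values are rescaled to HU
    with ``stored * RescaleSlope + RescaleIntercept``.
    """
    path = Path(path)
    fmt = format_hint
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
            fmt = "nifti"
        else:
            raise ValueError(f"cannot infer volume format for {path}")
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format hint {fmt!r}")


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)  # (i, j, k)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    voxels = np.ascontiguousarray(data.T)  # -> (k, j, i)
    # World z decreases with k in our convention; NIfTI is RAS (+z superior),
    # so a positive k-step in world z means the file stores inferior->superior
    # and must be flipped.
    if affine[2, 2] > 0:
        voxels = voxels[::-1].copy()
    origin = tuple(float(v) for v in affine[:3, 3])
    return CTVolume(voxels, tuple(float(z) for z in zooms), origin)


def write_ct_volume(volume: CTVolume, path: "str | Path") -> Path:
    """Write a volume as NIfTI-1; round-trips losslessly through
    :func:`read_ct_volume`."""
    import nibabel as nib

    path = Path(path)
    dx, dy, dz = volume.spacing
    affine = np.diag([dx, dy, -dz, 1.0])
    affine[:3, 3] = volume.origin
    data = np.asarray(volume.voxels, dtype=np.float32).T  # (i, j, k)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))
    return path


def _read_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM images found in {directory}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent series: mixed slice shapes {sorted(shapes)}")

    zs = [float(ds.ImagePositionPatient[2]) for ds in datasets]
    if len(set(np.round(zs, 6))) != len(zs):
        raise ValueError("unsortable series: duplicate slice positions")
    # Superior -> inferior: sort by world z descending.
    order = np.argsort(zs)[::-1]
    datasets = [datasets[i] for i in order]
    zs_sorted = np.array([zs[i] for i in order])

    if len(datasets) > 1:
        steps = np.diff(zs_sorted)
        if not np.all(steps < 0):
            raise ValueError("unsortable series: non-monotone slice positions")
        if np.ptp(np.abs(steps)) > 1e-3 * np.abs(steps).mean():
            raise ValueError("inconsistent series: non-uniform slice spacing")
        dz = float(np.abs(steps).mean())
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    voxels = np.stack(slices, axis=0)

    ps = datasets[0].PixelSpacing  # (row spacing, col spacing)
    spacing = (float(ps[1]), float(ps[0]), dz)
    ipp = datasets[0].ImagePositionPatient
    origin = (float(ipp[0]), float(ipp[1]), float(ipp[2]))
    return CTVolume(voxels, spacing, origin)


# ---------------------------------------------------------------------------
# Detection tables
# ---------------------------------------------------------------------------


def _validate_record(rec, line: str) -> None:
    if rec.w <= 0 or rec.h <= 0:
        raise ValueError(f"{line}: box width/height must be > 0, got w={rec.w}, h={rec.h}")
    if not 0.0 <= rec.score <= 1.0:
        raise ValueError(f"{line}: score must lie in [0, 1], got {rec.score}")
    if rec.frame_index < 0:
        raise ValueError(f"{line}: frame_index must be >= 0, got {rec.frame_index}")


def write_detections(records, path: "str | Path") -> Path:
    """Write detections to CSV (or JSON if the suffix is ``.json``).

    The CSV schema (version 1) is
    ``frame_index,cx,cy,w,h,score,class_label`` preceded by a comment line
    carrying the schema version.  Round-trips are lossless.
    """
    path = Path(path)
    for i, rec in enumerate(records):
        _validate_record(rec, f"record {i}")
    if path.suffix == ".json":
        payload = {
            "schema_version": DETECTIONS_SCHEMA_VERSION,
            "records": [
                {
                    "frame_index": int(r.frame_index),
                    "cx": float(r.cx),
                    "cy": float(r.cy),
                    "w": float(r.w),
                    "h": float(r.h),
                    "score": float(r.score),
                    "class_label": r.class_label,
                }
                for r in records
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path
    lines = [f"# ribmpr-detections v{DETECTIONS_SCHEMA_VERSION}"]
    lines.append(",".join(_DETECTION_COLUMNS))
    for r in records:
        label = "" if r.class_label is None else str(r.class_label)
        lines.append(
            f"{int(r.frame_index)},{r.cx!r},{r.cy!r},{r.w!r},{r.h!r},{r.score!r},{label}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_detections(path: "str | Path"):
    """Read a detection table written by :func:`write_detections`.

    Malformed rows raise ``ValueError`` naming the 1-based line number.
    """
    from .detection import Detection

    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        out = []
        for i, d in enumerate(payload["records"]):
            rec = Detection(
                frame_index=int(d["frame_index"]),
                cx=float(d["cx"]),
                cy=float(d["cy"]),
                w=float(d["w"]),
                h=float(d["h"]),
                score=float(d["score"]),
                class_label=d.get("class_label"),
            )
            _validate_record(rec, f"record {i}")
            out.append(rec)
        return out

    out = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if tuple(line.split(",")) != _DETECTION_COLUMNS:
                raise ValueError(f"line {lineno}: unexpected header {line!r}")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != len(_DETECTION_COLUMNS):
            raise ValueError(
                f"line {lineno}: expected {len(_DETECTION_COLUMNS)} fields, got {len(parts)}"
            )
        try:
            rec = Detection(
                frame_index=int(parts[0]),
                cx=float(parts[1]),
                cy=float(parts[2]),
                w=float(parts[3]),
                h=float(parts[4]),
                score=float(parts[5]),
                class_label=parts[6] or None,
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed row ({exc})") from None
        _validate_record(rec, f"line {lineno}")
        out.append(rec)
    if not header_seen:
        raise ValueError("line 1: missing header")
    return out


# ---------------------------------------------------------------------------
# MPR image export
# ---------------------------------------------------------------------------


def write_mpr_image(image: np.ndarray, path: "str | Path", window,
                    sidecar: dict | None = None) -> Path:
    """Export a 2-D HU image as an 8-bit PNG/TIFF after windowing.

    ``sidecar`` (plane parameters, grid geometry) is written next to the
    image as ``<path>.json`` for provenance.  NaN pixels are rejected: the
    resampler is responsible for filling out-of-volume samples first.
    """
    import imageio.v3 as iio

    from .windowing import apply_window, resolve_window

    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D HU image, got shape {image.shape}")
    if np.isnan(image).any():
        raise ValueError("image contains NaN pixels; fill out-of-volume values first")
    window = resolve_window(window)
    path = Path(path)
    iio.imwrite(path, apply_window(image, window))
    meta = dict(sidecar or {})
    meta.setdefault("window", {"name": window.name, "width": window.width,
                               "level": window.level})
    meta["shape"] = list(image.shape)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_mpr_sidecar(path: "str | Path") -> dict:
    """Read the JSON sidecar written by :func:`write_mpr_image`."""
    return json.loads(Path(str(path) + ".json").read_text())
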