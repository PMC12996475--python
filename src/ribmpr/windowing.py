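"""CT window/level transforms and slice-to-frame conversion.

A CT window maps the Hounsfield interval ``[WL - WW/2, WL + WW/2]`` linearly
onto the 8-bit display range ``[0, 255]``; values outside the interval are
clamped.  Six named presets (lung, fat, liver, bone, soft tissue, vessel)
cover the anatomical contexts relevant to rib imaging, and applying all six
to a volume expands the slice set six-fold ("multiwindow" expansion).

Quantization rounds half-up, so a value landing exactly on ``x.5`` maps to
``x + 1``.  The window interval is closed on both ends: HU exactly at the
lower bound maps to 0 and exactly at the upper bound to 255.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CTVolume

__all__ = [
    "WindowSetting",
    "FrameSequence",
    "PRESETS",
    "apply_window",
    "frames_from_volume",
    "multiwindow_expand",
]


@dataclass(frozen=True)
class WindowSetting:
    """A CT display window: width ``WW`` (HU, > 0) and level ``WL`` (HU)."""

    width: float
    level: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


#: The six named presets used for multiwindow dataset expansion, as
#: (WW, WL) pairs in HU.
PRESETS: dict[str, WindowSetting] = {
    "lung": WindowSetting(1500, -500, "lung"),
    "fat": WindowSetting(200, -100, "fat"),
    "liver": WindowSetting(120, 60, "liver"),
    "bone": WindowSetting(2000, 300, "bone"),
    "soft_tissue": WindowSetting(400, 40, "soft_tissue"),
    "vessel": WindowSetting(700, 300, "vessel"),
}


@dataclass
class FrameSequence:
    """Ordered stack of 2-D 8-bit frames derived from a volume.

    ``frames[k]`` is slice ``k`` after windowing; frame index equals slice
    index, so the sequence plays superior to inferior like a video.
    """

    frames: np.ndarray  # (n_frames, rows, cols) uint8
    window_name: str

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, k: int) -> np.ndarray:
        return self.frames[k]


def resolve_window(window: "WindowSetting | str") -> WindowSetting:
    """Return a ``WindowSetting``, resolving preset names."""
    if isinstance(window, WindowSetting):
        return window
    try:
        return PRESETS[window]
    except KeyError:
        raise KeyError(
            f"unknown window preset {window!r}; known presets: {sorted(PRESETS)}"
        ) from None


def apply_window(hu: np.ndarray, window: "WindowSetting | str") -> np.ndarray:
    """Map an HU array to 8-bit gray levels under ``window``.

    The map is linear from ``[WL - WW/2, WL + WW/2]`` to ``[0, 255]``,
    clamped outside, rounded half-up.  Monotone non-decreasing in HU.
    """
    window = resolve_window(window)
    hu = np.asarray(hu, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    lo = window.level - window.width / 2.0
    scaled = (hu - lo) * (255.0 / window.width)
    return np.clip(np.floor(scaled + 0.5), 0.0, 255.0).astype(np.uint8)


def frames_from_volume(volume: CTVolume, window: "WindowSetting | str") -> FrameSequence:
    """Convert a volume into an ordered frame sequence (one frame per slice)."""
    window = resolve_window(window)
    frames = apply_window(volume.voxels, window)
    return FrameSequence(frames=frames, window_name=window.name)


def multiwindow_expand(volume: CTVolume) -> dict[str, FrameSequence]:
    """Apply all six named presets to ``volume``.

    Returns one ``FrameSequence`` per preset; the total frame count is
    exactly six times the slice count.
    """
    return {name: frames_from_volume(volume, w) for name, w in PRESETS.items()}
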