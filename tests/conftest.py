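"""Shared fixtures: phantoms and pipeline runs are expensive, so the
canonical study phantom (seed 7) is generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ribmpr.phantom import generate_phantom
from ribmpr.pipeline import PipelineConfig, run_detection, run_reconstruction

CANONICAL_SEED = 7


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free default 24-rib phantom (exact nominal HU values)."""
    return generate_phantom(noise_sd=0.0, seed=CANONICAL_SEED)


@pytest.fixture(scope="session")
def phantom_noisy():
    """Default phantom with 1 HU additive Gaussian noise."""
    return generate_phantom(noise_sd=1.0, seed=CANONICAL_SEED)


@pytest.fixture(scope="session")
def clean_detections(phantom_clean):
    volume, _ = phantom_clean
    return run_detection(volume)


@pytest.fixture(scope="session")
def reconstruction(phantom_noisy):
    """Full pipeline result on the noisy canonical phantom (no image export)."""
    volume, _ = phantom_noisy
    return run_reconstruction(volume, PipelineConfig(render_mpr=False))


def angle_deg(u, v) -> float:
    """Acute angle between two directions, in degrees (sign-agnostic)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = abs(float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
    return float(np.degrees(np.arccos(min(1.0, c))))
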