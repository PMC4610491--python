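"""Shared fixtures.

The expensive inputs — the simulated texture blur grid with its
estimator outputs, and a small trained group registry — are built once
per session and shared by the unit and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from blurage import (
    MotionBlurParams,
    apply_motion_blur,
    estimate_direction,
    estimate_length,
    extract_profile,
    fit_sinc,
    focus_score,
    log_power_spectrum,
)
from blurage.age_estimator import FaceSample, train_registry
from blurage.config import RunConfig
from blurage.synthetic import FixtureSpec, make_face, make_texture

GRID_DIRECTIONS = (0.0, 45.0, 90.0, 135.0)
GRID_LENGTHS = (3, 5, 7, 9, 11, 13, 15)
N_TEXTURES = 25
TEXTURE_SIZE = 256
SNAP_GRID = (1, 3, 5, 7, 9, 11, 13, 15)


@dataclass(frozen=True)
class GridEstimate:
    seed: int
    theta_true: float
    length_true: int
    theta_est: float
    length_est: float
    length_raw: float
    fs: float


@dataclass(frozen=True)
class GridRun:
    """Estimator outputs over the simulated texture blur grid."""

    focused_fs: np.ndarray  # one per unblurred texture
    records: list[GridEstimate]  # one per blurred variant


@pytest.fixture(scope="session")
def grid_run() -> GridRun:
    """25 seeded textures x {4 directions x 7 lengths}, fully estimated."""
    focused_fs = []
    records: list[GridEstimate] = []
    for seed in range(N_TEXTURES):
        texture = make_texture(FixtureSpec(seed=seed, size=TEXTURE_SIZE))
        focused_fs.append(focus_score(log_power_spectrum(texture)))
        for theta in GRID_DIRECTIONS:
            for length in GRID_LENGTHS:
                blurred = apply_motion_blur(
                    texture, MotionBlurParams(theta_deg=theta, length=length)
                )
                spectrum = log_power_spectrum(blurred)
                theta_est = estimate_direction(spectrum)
                profile = extract_profile(spectrum, theta_est)
                try:
                    # length estimation runs on images the protocol has
                    # already classified as blurred, so the feasible
                    # null spacing is capped at N/2 (motion length >= 2)
                    d = fit_sinc(
                        profile,
                        d_range=(TEXTURE_SIZE / 16.0, TEXTURE_SIZE / 2.0),
                    )
                    length_raw = estimate_length(d, TEXTURE_SIZE)
                    length_est = estimate_length(d, TEXTURE_SIZE, snap_grid=SNAP_GRID)
                except ValueError:
                    length_raw = length_est = 1.0
                records.append(
                    GridEstimate(
                        seed=seed,
                        theta_true=theta,
                        length_true=length,
                        theta_est=theta_est,
                        length_est=length_est,
                        length_raw=length_raw,
                        fs=focus_score(spectrum),
                    )
                )
    return GridRun(focused_fs=np.array(focused_fs), records=records)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def face_samples() -> list[FaceSample]:
    """A dozen synthetic faces spanning the age range."""
    rng = np.random.default_rng(42)
    ages = np.linspace(20, 90, 12) + rng.uniform(-1, 1, 12)
    samples = []
    for i, age in enumerate(ages):
        img, eyes, label = make_face(
            FixtureSpec(seed=500 + i, size=140, kind="face", age=float(age),
                        noise_sigma=2.0)
        )
        samples.append(FaceSample(image=img, eyes=eyes, age=label))
    return samples


@pytest.fixture(scope="session")
def tiny_registry(face_samples, run_config):
    """A small but complete registry: all nine groups trained."""
    return train_registry(
        face_samples, run_config, seed=7, directions=GRID_DIRECTIONS,
        lengths=(5, 11),
    )
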