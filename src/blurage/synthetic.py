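"""Seeded synthetic fixtures: textures, face-like images, and blur grids.

Real face databases with age labels cannot be bundled, so every test
input is generated here:

* :func:`make_texture` — broadband natural-image-like textures whose
  spectra carry enough high-frequency content for the blur estimators
  to read the sinc structure out of;
* :func:`make_face` — a face-like image (elliptical head, two eye
  blobs at known coordinates) whose wrinkle-band texture in the five
  canonical wrinkle regions grows in amplitude and spatial frequency
  with a latent age, so the age signal is recoverable by design;
* :func:`make_blur_grid` — the full simulated blur protocol: every base
  image crossed with a grid of directions and motion lengths, each
  record tagged with its ground-truth parameters and blur group.

All generators are pure functions of their spec (seed included): the
same spec always yields the identical image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from skimage.draw import line_aa

from .blur_estimation import FocusDecision, assign_group
from .blur_model import MotionBlurParams, apply_motion_blur
from .face_preprocess import EyeAnnotation, wrinkle_regions

__all__ = [
    "FixtureSpec",
    "BlurRecord",
    "make_texture",
    "make_face",
    "make_blur_grid",
    "DEFAULT_DIRECTIONS",
    "DEFAULT_LENGTHS",
    "AGE_RANGE",
]

#: Blur grid of the simulated protocol: four directions, odd lengths 3..15.
DEFAULT_DIRECTIONS = (0.0, 45.0, 90.0, 135.0)
DEFAULT_LENGTHS = (3, 5, 7, 9, 11, 13, 15)

#: Age range of the face generator, years.
AGE_RANGE = (18, 93)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic image.

    Parameters
    ----------
    seed : int
        Seed of the generator; same spec, same pixels.
    size : int
        Image side length in pixels.
    kind : str
        ``"texture"`` or ``"face"``.
    age : float, optional
        Latent age in years (face only), within ``AGE_RANGE``.
    noise_sigma : float
        Additive Gaussian pixel noise.
    """

    seed: int
    size: int = 256
    kind: str = "texture"
    age: float | None = None
    noise_sigma: float = 0.0


def make_texture(spec: FixtureSpec) -> np.ndarray:
    """Broadband texture: 1/f-shaped noise plus oriented edge fragments.

    The 1/f envelope mimics the spectral falloff of natural images; a
    few dozen short anti-aliased edge fragments at uniformly random
    orientations add the localized high-frequency structure that
    elongates under motion blur.  Orientations are dense and isotropic
    on average so the unblurred spectrum has no dominant direction and
    the focus score of a clean texture stays high.
    """
    if spec.size < 64:
        raise ValueError("texture size must be at least 64")
    n = spec.size
    rng = np.random.default_rng(spec.seed)
    # 1/f field: shape white noise in the frequency domain.
    white = rng.normal(size=(n, n))
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    radial = np.sqrt(fx * fx + fy * fy)
    envelope = 1.0 / (radial + 1.0 / n)
    base = np.fft.ifft2(np.fft.fft2(white) * envelope).real
    base = (base - base.min()) / np.ptp(base)

    # Oriented edge fragments, orientation uniform on [0, 180).
    edges = np.zeros((n, n))
    n_frag = 60
    for _ in range(n_frag):
        cx, cy = rng.uniform(10, n - 10, size=2)
        theta = rng.uniform(0.0, np.pi)
        half = rng.uniform(5, 15)
        amp = rng.uniform(0.3, 1.0)
        x0 = int(np.clip(cx - half * np.cos(theta), 0, n - 1))
        y0 = int(np.clip(cy - half * np.sin(theta), 0, n - 1))
        x1 = int(np.clip(cx + half * np.cos(theta), 0, n - 1))
        y1 = int(np.clip(cy + half * np.sin(theta), 0, n - 1))
        rr, cc, val = line_aa(y0, x0, y1, x1)
        edges[rr, cc] += amp * val

    img = 180.0 * base + 40.0 * edges
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 255.0)


def _fill_ellipse(img: np.ndarray, cy: float, cx: float, ry: float, rx: float,
                  value: float) -> None:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    img[mask] = value


def make_face(spec: FixtureSpec) -> tuple[np.ndarray, EyeAnnotation, float]:
    """Face-like image with eye landmarks and age-dependent wrinkles.

    Renders an elliptical head on a dark background, two dark eye blobs
    at known coordinates, and additive oriented sinusoid "wrinkle" bands
    inside the five canonical wrinkle regions (forehead, both eye
    corners, both under-eye areas).  Band amplitude and spatial
    frequency grow linearly with the latent age::

        a(age) = 5 + 28 * (age - 18) / 75
        f(age) = 0.06 + 0.10 * (age - 18) / 75   [cycles/pixel]

    so older faces carry stronger, finer texture — a monotone age signal
    the feature extractors can recover.  Returns the image, the eye
    annotation (right eye = smaller x), and the age label.
    """
    if spec.age is None:
        raise ValueError("face fixtures require a latent age")
    lo, hi = AGE_RANGE
    if not (lo <= spec.age <= hi):
        raise ValueError(f"age must lie in [{lo}, {hi}], got {spec.age}")
    n = spec.size if spec.size >= 96 else 96
    rng = np.random.default_rng(spec.seed)

    img = np.full((n, n), 50.0)
    cy, cx = n * 0.52, n * 0.5
    _fill_ellipse(img, cy, cx, n * 0.42, n * 0.33, 180.0)

    eye_y = n * 0.40
    eye_dx = n * 0.145
    right = (cx - eye_dx, eye_y)  # smaller x = viewer's left = subject's right
    left = (cx + eye_dx, eye_y)
    for ex, ey in (right, left):
        _fill_ellipse(img, ey, ex, n * 0.022, n * 0.035, 60.0)
    eyes = EyeAnnotation(right_eye=right, left_eye=left)

    # Per-person texture variation unrelated to age.
    img += rng.normal(0.0, 1.5, size=img.shape)

    u = (spec.age - lo) / (hi - lo)
    amp = 5.0 + 28.0 * u
    freq = 0.06 + 0.10 * u

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    regions = wrinkle_regions(eyes, image_shape=img.shape)
    # Wrinkles run roughly horizontally on the forehead and under the
    # eyes, diagonally at the eye corners.
    orient = {
        "forehead": 90.0,
        "left_eye_corner": 135.0,
        "right_eye_corner": 45.0,
        "left_under_eye": 90.0,
        "right_under_eye": 90.0,
    }
    phase = rng.uniform(0, 2 * np.pi, size=len(orient))
    for k, (name, rect) in enumerate(sorted(regions.regions.items())):
        x0, y0, x1, y1 = rect
        th = np.deg2rad(orient[name])
        # waves vary along the direction normal to the wrinkle lines
        proj = xx * np.cos(th) + yy * np.sin(th)
        band = amp * np.sin(2 * np.pi * freq * proj + phase[k])
        sl = np.s_[y0:y1, x0:x1]
        img[sl] += band[sl]

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 255.0), eyes, float(spec.age)


@dataclass(frozen=True)
class BlurRecord:
    """One entry of a simulated blur grid: image plus ground truth."""

    image: np.ndarray = field(repr=False)
    theta_deg: float  # ground-truth direction; 0.0 for unblurred records
    length: int  # ground-truth motion length; 1 = no blur
    group: str  # blur group implied by the ground truth
    base_index: int
    age: float | None = None
    eyes: EyeAnnotation | None = None


def _truth_group(theta: float, length: int) -> str:
    label = "focused" if length == 1 else "blurred"
    return assign_group(
        FocusDecision(score=0.0, threshold=0.0, label=label),
        theta_est=theta,
        length_est=float(length),
    )


def make_blur_grid(
    base_images: Sequence[np.ndarray],
    directions: Sequence[float] = DEFAULT_DIRECTIONS,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    noise_sigma: float = 0.0,
    seed: int = 0,
    *,
    ages: Sequence[float] | None = None,
    eyes: Sequence[EyeAnnotation] | None = None,
) -> Iterator[BlurRecord]:
    """Cross base images with a direction x length blur grid.

    Yields each base image unblurred (length 1) followed by every
    (direction, length) variant, tagged with ground-truth parameters
    and the blur group they imply.  B bases, D directions and K lengths
    give ``B * (1 + D*K)`` records.  Records are yielded lazily so large
    grids never need to be held in memory at once.
    """
    if len(base_images) == 0:
        raise ValueError("base image set must be non-empty")
    rng = np.random.default_rng(seed)
    for i, base in enumerate(base_images):
        age = None if ages is None else ages[i]
        eye = None if eyes is None else eyes[i]
        yield BlurRecord(
            image=np.asarray(base, dtype=float),
            theta_deg=0.0,
            length=1,
            group=_truth_group(0.0, 1),
            base_index=i,
            age=age,
            eyes=eye,
        )
        for theta in directions:
            for length in lengths:
                params = MotionBlurParams(theta_deg=theta, length=int(length))
                blurred = apply_motion_blur(
                    base, params, noise_sigma=noise_sigma, rng=rng
                )
                yield BlurRecord(
                    image=blurred,
                    theta_deg=float(theta),
                    length=int(length),
                    group=_truth_group(float(theta), int(length)),
                    base_index=i,
                    age=age,
                    eyes=eye,
                )
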