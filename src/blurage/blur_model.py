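"""Linear motion-blur model: PSF construction, blur simulation, and spectra.

Linear motion blur smears every scene point along a straight line of
``length`` pixels at angle ``theta_deg``.  The observed image is the
convolution of the latent sharp image with this point-spread function
(PSF), optionally plus sensor noise.  In the frequency domain the PSF is
a sinc whose nulls form dark parallel bands orthogonal to the motion
direction; those bands are what the estimators in
:mod:`blurage.blur_estimation` read out of the log power spectrum.

Conventions
-----------
Images are 2-D ``float64`` arrays indexed ``[row, col]`` with x (columns)
increasing rightward and y (rows) increasing downward.  Motion direction
is measured counterclockwise from the +x axis as seen on screen, i.e. a
45-degree blur smears toward the upper right.  Directions live on the
half-turn ``[0, 180)`` because a line has no sense of travel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MotionBlurParams",
    "SpectrumImage",
    "make_linear_psf",
    "apply_motion_blur",
    "hann_window",
    "log_power_spectrum",
]

#: Relative floor added inside the log so exact spectral zeros (sinc
#: nulls, windowed borders) stay finite.  The power spectrum of a
#: natural image spans far more than six decades between DC and the
#: mid-frequency background, so the floor sits twelve decades below the
#: peak to keep the sinc nulls visible instead of clipping them.
LOG_EPS = 1e-12


@dataclass(frozen=True)
class MotionBlurParams:
    """Parameters of a linear motion-blur PSF.

    Parameters
    ----------
    theta_deg : float
        Motion direction in degrees on the half-turn ``[0, 180)``.
    length : int
        Motion length L in pixels; the PSF has exactly L taps of weight
        1/L.  ``length == 1`` is the identity kernel (no blur).
    """

    theta_deg: float
    length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_deg < 180.0):
            raise ValueError(
                f"theta_deg must lie in [0, 180), got {self.theta_deg!r}"
            )
        if not float(self.length).is_integer() or self.length < 1:
            raise ValueError(f"length must be a positive integer, got {self.length!r}")
        object.__setattr__(self, "length", int(self.length))


@dataclass(frozen=True)
class SpectrumImage:
    """Centered log power spectrum of a real image.

    ``values[r, c]`` is ``log(|F|^2 + eps)`` with the DC component at
    ``(height // 2, width // 2)``.  ``source_size`` records the
    height/width of the image the spectrum came from, which the length
    estimator needs to convert a null spacing into a motion length.
    """

    values: np.ndarray
    source_size: tuple[int, int]

    @property
    def center(self) -> tuple[int, int]:
        return self.values.shape[0] // 2, self.values.shape[1] // 2


def _direction_cosines(theta_deg: float) -> tuple[float, float]:
    """Unit step (dx, dy) of the motion direction in image coordinates.

    y grows downward, so a counterclockwise on-screen angle has dy =
    -sin(theta).
    """
    t = np.deg2rad(theta_deg)
    return float(np.cos(t)), float(-np.sin(t))


def make_linear_psf(params: MotionBlurParams) -> np.ndarray:
    """Build the uniform line-segment PSF for linear motion blur.

    The kernel is a centered uniform segment of *physical* length L
    pixels at angle ``theta_deg``, rasterized nearest-pixel (Bresenham
    style) with one tap per step of the major axis and equal weights
    summing to 1.  For axis-aligned directions this is exactly L taps
    of value 1/L; at oblique angles the tap count is
    ``round(L * max(|cos|, |sin|))`` so that the segment's extent along
    the motion direction — the quantity the spectral null spacing
    ``d = N / L`` responds to — stays L rather than inflating to
    L * sqrt(2) on the diagonal.

    Returns
    -------
    numpy.ndarray
        Odd-sized square kernel.
    """
    L = params.length
    if L == 1:
        return np.ones((1, 1))
    dx, dy = _direction_cosines(params.theta_deg)
    major = max(abs(dx), abs(dy))
    n_taps = max(1, int(round(L * major)))
    if n_taps == 1:
        return np.ones((1, 1))

    def _round_half_up(v: np.ndarray) -> np.ndarray:
        # np.round's banker's rounding would collide the two central
        # taps of an even-tap kernel; round half toward +inf instead.
        return np.floor(np.asarray(v) + 0.5).astype(int)

    # One tap per unit step of the major axis: taps are distinct and the
    # segment spans n_taps / max(|cos|,|sin|) ~ L along the motion line.
    steps = np.arange(n_taps, dtype=float) - (n_taps - 1) / 2.0
    if abs(dx) >= abs(dy):
        xs = _round_half_up(steps * (1.0 if dx >= 0 else -1.0))
        ys = _round_half_up(xs * (dy / dx))
    else:
        ys = _round_half_up(steps * (1.0 if dy >= 0 else -1.0))
        xs = _round_half_up(ys * (dx / dy))
    half = int(max(np.abs(xs).max(), np.abs(ys).max()))
    size = 2 * half + 1
    kernel = np.zeros((size, size))
    kernel[ys + half, xs + half] = 1.0 / n_taps
    if np.count_nonzero(kernel) != n_taps:
        raise RuntimeError("PSF rasterization produced colliding taps")
    return kernel


def apply_motion_blur(
    image: np.ndarray,
    params: MotionBlurParams,
    noise_sigma: float = 0.0,
    *,
    boundary: str = "reflect",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate linear motion blur: convolve with the PSF, add noise.

    Parameters
    ----------
    image : numpy.ndarray
        2-D grayscale image, larger than the kernel in both dimensions.
    params : MotionBlurParams
    noise_sigma : float
        Standard deviation of additive zero-mean Gaussian noise; 0 gives
        the noiseless model.
    boundary : str
        Padding mode for the convolution: ``"reflect"`` (default, avoids
        injecting dark borders into the spectrum) or ``"wrap"``
        (circular, matching the frequency-domain product exactly).
    rng : numpy.random.Generator, optional
        Noise source; required when ``noise_sigma > 0`` for
        reproducibility, a fresh generator is used otherwise.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    kernel = make_linear_psf(params)
    if kernel.shape[0] > image.shape[0] or kernel.shape[1] > image.shape[1]:
        raise ValueError(
            f"kernel {kernel.shape} larger than image {image.shape}"
        )
    if boundary not in ("reflect", "wrap"):
        raise ValueError(f"unsupported boundary mode {boundary!r}")
    blurred = ndimage.convolve(image, kernel, mode=boundary)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        blurred = blurred + rng.normal(0.0, noise_sigma, size=blurred.shape)
    return blurred


def hann_window(image: np.ndarray) -> np.ndarray:
    """Taper an image with the separable 2-D Hann (raised-cosine) window.

    ``W(x) = (1 - cos(2 pi x / N)) / 2`` along each axis, sized to the
    image; W(0) = 0 and W(N/2) = 1, so borders go to zero and the center
    is untouched.  This suppresses the cross-shaped boundary artifact
    that otherwise contaminates the power spectrum.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    wy = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(h) / h))
    wx = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(w) / w))
    return image * wy[:, None] * wx[None, :]


def log_power_spectrum(image: np.ndarray, windowed: bool = True) -> SpectrumImage:
    """Centered log power spectrum, optionally Hann-windowed first.

    Returns ``log(|DFT|^2 + eps)`` with the DC bin shifted to the grid
    center.  ``eps`` is a relative floor (``LOG_EPS`` times the spectral
    maximum) so sinc nulls stay finite; an all-zero image yields the
    constant floor rather than failing.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValueError("image must be 2-D and at least 16x16")
    if windowed:
        image = hann_window(image)
    ps = np.abs(np.fft.fftshift(np.fft.fft2(image))) ** 2
    floor = LOG_EPS * max(ps.max(), 1.0)
    return SpectrumImage(values=np.log(ps + floor), source_size=image.shape)
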