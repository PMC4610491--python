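"""Motion-blur parameter estimation from the log power spectrum.

A linear motion blur of length L at direction theta multiplies the image
spectrum by a sinc whose bright central ridge runs orthogonal to the
motion and whose nulls repeat every ``d = N / L`` frequency bins along
the motion direction.  Three estimators exploit this:

* **direction** — a Radon transform restricted to a low-frequency circle
  of the spectrum, summed over a small band of offsets rho per angle
  (the rho-range summation); the angle of the dominant ridge, mapped to
  its orthogonal, is the motion direction;
* **length** — the spectral profile along the motion direction is fit by
  a log-sinc^2 model and L recovered as N / d from the null spacing d;
* **focus score** — ``FS = 100 * S_(theta+90) / S_theta`` compares the
  ridge-orthogonal to the ridge-parallel spectral mass; isotropic
  (focused) spectra score near 100, blurred ones lower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .blur_model import SpectrumImage

__all__ = [
    "RadonMap",
    "DirectionScore",
    "SpectralProfile",
    "FocusDecision",
    "GROUP_IDS",
    "CANONICAL_DIRECTIONS",
    "modified_radon",
    "rho_range_sum",
    "estimate_direction",
    "extract_profile",
    "radon_profile",
    "fit_sinc",
    "estimate_length",
    "focus_score",
    "focus_and_direction",
    "learn_focus_threshold",
    "assign_group",
]

#: Canonical blur directions of the grouped protocol, degrees.
CANONICAL_DIRECTIONS = (0.0, 45.0, 90.0, 135.0)

#: The nine blur groups: focused, plus {slight, blurred} x direction.
GROUP_IDS = (
    "focused",
    "slight-0", "slight-45", "slight-90", "slight-135",
    "blurred-0", "blurred-45", "blurred-90", "blurred-135",
)

# Length bin edges separating focused / slightly blurred / blurred.
_SLIGHT_EDGE = 4.5
_BLURRED_EDGE = 10.0

# cache of detrended log-sinc model matrices keyed by fit geometry
_SINC_MODEL_CACHE: dict[tuple, np.ndarray] = {}


@dataclass(frozen=True)
class RadonMap:
    """R(rho, theta) of the circle-restricted Radon transform.

    ``values[i, j]`` is the line sum at offset ``rhos[i]`` and angle
    ``thetas_deg[j]``; only points inside the circle of ``radius``
    spectrum pixels about the center contribute.
    """

    values: np.ndarray
    rhos: np.ndarray
    thetas_deg: np.ndarray
    radius: float


@dataclass(frozen=True)
class DirectionScore:
    """P(theta): Radon mass summed over rho in [-margin, margin]."""

    p: np.ndarray
    thetas_deg: np.ndarray
    margin: int


@dataclass(frozen=True)
class SpectralProfile:
    """Spectrum values read along the line through the center.

    ``samples[k]`` sits at signed offset ``(k - len//2) * spacing``
    pixels from the DC bin; the sample count is odd with the center at
    the midpoint.
    """

    samples: np.ndarray
    spacing: float
    theta_deg: float

    @property
    def offsets(self) -> np.ndarray:
        n = len(self.samples)
        return (np.arange(n) - n // 2) * self.spacing


@dataclass(frozen=True)
class FocusDecision:
    """Focus score, the threshold applied, and the resulting label."""

    score: float
    threshold: float
    label: str  # "focused" | "blurred"


def _bilinear(values: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear samples of ``values`` at fractional (row, col) points.

    Out-of-bounds points return 0 (they are excluded by the circle mask
    before accumulation anyway).
    """
    return ndimage.map_coordinates(
        values, np.vstack([rows.ravel(), cols.ravel()]), order=1, mode="constant"
    ).reshape(rows.shape)


#: Default estimator geometry, as fractions of the smaller spectrum
#: dimension, plus the rho-range margin and the Gaussian sigma used to
#: smooth the log spectrum before accumulation.  Calibrated on the
#: synthetic texture generator; see the methods note.
RADIUS_FACTOR = 0.49
INNER_FACTOR = 0.0625
DEFAULT_MARGIN = 12
SMOOTH_SIGMA = 2.0


def modified_radon(
    spectrum: SpectrumImage,
    radius: float,
    *,
    theta_step: float = 1.0,
    rhos: np.ndarray | None = None,
    inner_radius: float = 0.0,
    presmoothed: np.ndarray | None = None,
) -> RadonMap:
    """Radon transform of the spectrum restricted to a center circle.

    For each angle theta and offset rho, sums bilinearly interpolated
    spectrum values along the line ``x cos(theta) + y sin(theta) = rho``
    (x rightward, y downward from the spectrum center), keeping only
    points within ``radius`` of the center.  Restricting to the circle
    equalizes the number of contributing pixels across angles and keeps
    the accumulation on the low-frequency region where the directional
    ridge concentrates.

    Values are min-shifted to non-negative before accumulation so that
    the downstream argmax and focus-score ratio are sign-consistent.

    Parameters
    ----------
    spectrum : SpectrumImage
    radius : float
        Circle radius in spectrum pixels; must be positive and at most
        half the smaller spectrum dimension.
    theta_step : float
        Angular sampling in degrees over [0, 180).
    rhos : numpy.ndarray, optional
        Offsets to evaluate; defaults to all integers in [-radius, radius].
    inner_radius : float
        When positive, points closer than this to the center are also
        excluded.  The innermost bins carry almost no directional
        contrast (the sinc is flat there) but plenty of spectral noise,
        so skipping them sharpens the angular response.
    presmoothed : numpy.ndarray, optional
        Already-preprocessed spectrum values to accumulate instead of
        ``spectrum.values`` (used internally to share the smoothing
        between the direction and focus estimators).
    """
    vals = spectrum.values if presmoothed is None else presmoothed
    if radius <= 0:
        raise ValueError("radius must be positive")
    if radius > min(vals.shape) / 2:
        raise ValueError("radius exceeds half the smaller spectrum dimension")
    if not (0.0 <= inner_radius < radius):
        raise ValueError("inner_radius must lie in [0, radius)")
    vals = vals - vals.min()
    cy, cx = spectrum.center
    if rhos is None:
        r = int(np.floor(radius))
        rhos = np.arange(-r, r + 1, dtype=float)
    else:
        rhos = np.asarray(rhos, dtype=float)
    thetas = np.arange(0.0, 180.0, theta_step)
    # Parametrize each line as rho*(cos t, sin t) + s*(-sin t, cos t) in
    # (x, y); unit steps in s, clipped to the chord inside the circle.
    smax = int(np.floor(radius))
    s = np.arange(-smax, smax + 1, dtype=float)
    out = np.zeros((len(rhos), len(thetas)))
    r_in_sq = inner_radius * inner_radius
    for j, th in enumerate(np.deg2rad(thetas)):
        ct, st = np.cos(th), np.sin(th)
        # points for all (rho, s) at once
        x = rhos[:, None] * ct - s[None, :] * st
        y = rhos[:, None] * st + s[None, :] * ct
        rr = x * x + y * y
        inside = (rr <= radius * radius + 1e-9) & (rr >= r_in_sq)
        sampled = _bilinear(vals, y + cy, x + cx)
        out[:, j] = np.where(inside, sampled, 0.0).sum(axis=1)
    return RadonMap(values=out, rhos=rhos, thetas_deg=thetas, radius=float(radius))


def rho_range_sum(radon: RadonMap, margin: int) -> DirectionScore:
    """P(theta): sum R(rho, theta) over rho in [-margin, margin].

    Acts as a (2*margin + 1)-tap box filter across offsets, pooling the
    evidence of the dominant ridge instead of trusting a single line.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin >= radon.radius:
        raise ValueError("margin must be smaller than the circle radius")
    mask = np.abs(radon.rhos) <= margin + 1e-9
    if mask.sum() != 2 * margin + 1:
        raise ValueError("RadonMap does not sample all offsets in [-margin, margin]")
    p = radon.values[mask].sum(axis=0)
    return DirectionScore(p=p, thetas_deg=radon.thetas_deg, margin=margin)


def _direction_score(
    spectrum: SpectrumImage,
    radius: float | None,
    margin: int,
    theta_step: float,
    smooth_sigma: float = SMOOTH_SIGMA,
) -> DirectionScore:
    """P(theta) with the default estimator geometry.

    The log spectrum is lightly Gaussian-smoothed before accumulation —
    like the rho-range summation itself, this pools the chi-square
    noise of individual spectral bins without moving the ridge.
    """
    mindim = min(spectrum.values.shape)
    if radius is None:
        radius = RADIUS_FACTOR * mindim
    inner = INNER_FACTOR * mindim
    if inner >= radius:
        inner = 0.0
    vals = spectrum.values
    if smooth_sigma > 0:
        vals = ndimage.gaussian_filter(vals, smooth_sigma)
    rhos = np.arange(-margin, margin + 1, dtype=float)
    radon = modified_radon(
        spectrum,
        radius,
        theta_step=theta_step,
        rhos=rhos,
        inner_radius=inner,
        presmoothed=vals,
    )
    return rho_range_sum(radon, margin)


def _argmax_smallest(p: np.ndarray) -> int:
    """Index of the maximum; ties resolve to the smallest index."""
    return int(np.argmax(p))


def estimate_direction(
    spectrum: SpectrumImage,
    radius: float | None = None,
    margin: int = DEFAULT_MARGIN,
    theta_step: float = 1.0,
) -> float:
    """Estimate the motion direction in degrees on [0, 180).

    Finds the Radon angle whose rho-range sum P(theta) is largest — the
    dominant bright ridge of the spectrum — and maps it to the motion
    direction, which is orthogonal to the ridge.  With the spectrum's
    y axis pointing down and the Radon line at angle phi running along
    the on-screen direction (90 - phi), the ridge angle for motion theta
    is phi = (180 - theta) mod 180, hence the inversion below.

    On a near-isotropic spectrum the argmax is still returned; callers
    guard with the focus score.  Ties take the smallest angle.
    """
    score = _direction_score(spectrum, radius, margin, theta_step)
    phi = score.thetas_deg[_argmax_smallest(score.p)]
    return float((180.0 - phi) % 180.0)


def extract_profile(
    spectrum: SpectrumImage, theta_deg: float, spacing: float = 1.0
) -> SpectralProfile:
    """Read the spectrum along the motion direction through the center.

    Samples the full line at angle ``theta_deg`` (on-screen convention,
    y down) at unit-pixel spacing with bilinear interpolation; the
    returned sample count is odd with the DC bin at the midpoint.
    """
    if not (0.0 <= theta_deg < 180.0):
        raise ValueError("theta_deg must lie in [0, 180)")
    vals = spectrum.values
    cy, cx = spectrum.center
    half = int((min(vals.shape) // 2 - 1) / spacing)
    t = np.arange(-half, half + 1, dtype=float) * spacing
    th = np.deg2rad(theta_deg)
    x = t * np.cos(th)
    y = -t * np.sin(th)  # y down: on-screen CCW angle
    samples = _bilinear(vals, y + cy, x + cx)
    return SpectralProfile(samples=samples, spacing=float(spacing), theta_deg=float(theta_deg))


def radon_profile(
    spectrum: SpectrumImage,
    theta_deg: float,
    radius: float | None = None,
    smooth_sigma: float = 0.0,
) -> SpectralProfile:
    """Noise-pooled spectral profile along the motion direction.

    The sinc attenuation of a motion blur at direction theta depends
    only on the offset rho along theta, so every point of the ridge
    -parallel line at offset rho carries the same attenuation.  Reading
    the circle-restricted Radon transform at the ridge angle and
    averaging each line over its chord therefore yields the same
    log-sinc profile as :func:`extract_profile` but with the per-bin
    spectral noise averaged over the whole chord — much more robust on
    images whose spectrum is not broadband (faces).  Offsets run over
    the integers in (-radius, radius), odd count, center at DC.
    """
    if not (0.0 <= theta_deg < 180.0):
        raise ValueError("theta_deg must lie in [0, 180)")
    vals = spectrum.values
    if smooth_sigma > 0:
        vals = ndimage.gaussian_filter(vals, smooth_sigma)
    vals = vals - vals.min()
    if radius is None:
        radius = min(vals.shape) // 2 - 1
    cy, cx = spectrum.center
    r = int(np.floor(radius))
    rhos = np.arange(-r + 1, r, dtype=float)
    # ridge lines run orthogonal to the motion; offset rho advances
    # along the motion direction (x, y down) = (cos theta, -sin theta)
    th = np.deg2rad(theta_deg)
    ux, uy = np.cos(th), -np.sin(th)
    smax = r
    s = np.arange(-smax, smax + 1, dtype=float)
    x = rhos[:, None] * ux - s[None, :] * uy
    y = rhos[:, None] * uy + s[None, :] * ux
    inside = x * x + y * y <= radius * radius + 1e-9
    sampled = _bilinear(vals, y + cy, x + cx)
    sums = np.where(inside, sampled, 0.0).sum(axis=1)
    counts = np.maximum(inside.sum(axis=1), 1)
    return SpectralProfile(
        samples=sums / counts, spacing=1.0, theta_deg=float(theta_deg)
    )


def _log_sinc_sq(t: np.ndarray, d: float, eps: float = 1e-6) -> np.ndarray:
    return np.log(np.sinc(t / d) ** 2 + eps)


def fit_sinc(
    profile: SpectralProfile,
    d_range: tuple[float, float] | None = None,
    *,
    exclude_center: int = 3,
    background: str = "log",
    full_output: bool = False,
) -> float | tuple[float, float]:
    """Null spacing d of the best-fit sinc to a spectral profile.

    Fits the log-domain model ``log(sinc^2(t/d) + eps)`` plus a nuisance
    background by least squares; d is scanned on a coarse grid over the
    feasible range and then refined by golden-section search.  Samples
    within ``exclude_center`` pixels of DC are excluded (DC spike).

    Two background treatments are available:

    * ``"log"`` — a global ``c + a*log(1 + |t|)`` term fit jointly in
      closed form, absorbing the radially decaying (1/f-like)
      background of broadband natural-image spectra;
    * ``"local"`` — both the profile and the candidate model are
      high-pass filtered by subtracting a Gaussian-smoothed copy
      (sigma proportional to the candidate d), so only the periodic
      null comb is compared.  More robust on spectra whose background
      is not log-linear (faces), at the price of discarding the
      envelope evidence.

    Parameters
    ----------
    profile : SpectralProfile
    d_range : (float, float), optional
        Feasible null spacings; defaults to ``(n_half / 16, 2 * n_half)``
        where ``n_half`` is the one-sided profile length, covering
        motion lengths from none up to the supported maximum.

    Returns
    -------
    float, or (float, float) when ``full_output`` is set
        Estimated null spacing in spectrum pixels (and the residual
        sum of squares of the winning fit, comparable across profiles
        of the same length).

    Raises
    ------
    ValueError
        If the profile is too short or flat (no blur structure).
    """
    if background not in ("log", "local"):
        raise ValueError(f"unknown background mode {background!r}")
    s = np.asarray(profile.samples, dtype=float)
    if len(s) < 17:
        raise ValueError("profile too short for sinc fitting")
    t = profile.offsets
    keep = np.abs(t) > exclude_center
    t, s = t[keep], s[keep]
    if np.ptp(s) < 1e-12:
        raise ValueError("flat profile: no blur structure to fit")
    n_half = np.abs(t).max()
    if d_range is None:
        d_range = (n_half / 16.0, 2.0 * n_half)
    lo, hi = d_range

    basis = np.column_stack([np.ones_like(t), np.log1p(np.abs(t))])
    # Precompute the projector for the linear background part.
    q, _ = np.linalg.qr(basis)

    def sse(d: float) -> float:
        model = _log_sinc_sq(t, d)
        if background == "local":
            sb = max(2.0, 0.35 * d)
            resid = (s - ndimage.gaussian_filter1d(s, sb)) - (
                model - ndimage.gaussian_filter1d(model, sb)
            )
        else:
            resid = s - model
            resid = resid - q @ (q.T @ resid)
        return float(resid @ resid)

    # Coarse scan.  The detrended candidate models depend only on the
    # offset grid and the d grid, so they are cached and shared across
    # profiles of the same geometry (the direction refinement in the
    # face pipeline fits many profiles of identical shape).
    n_coarse = 300
    ds = np.linspace(lo, hi, n_coarse)
    if background == "local":
        key = (t.tobytes(), float(lo), float(hi), n_coarse)
        cached = _SINC_MODEL_CACHE.get(key)
        if cached is None:
            models = np.empty((n_coarse, len(t)))
            for j, d in enumerate(ds):
                m = _log_sinc_sq(t, d)
                models[j] = m - ndimage.gaussian_filter1d(m, max(2.0, 0.35 * d))
            if len(_SINC_MODEL_CACHE) < 64:
                _SINC_MODEL_CACHE[key] = models
            cached = models
        s_detr = np.empty((n_coarse, len(t)))
        for j, d in enumerate(ds):
            s_detr[j] = s - ndimage.gaussian_filter1d(s, max(2.0, 0.35 * d))
        errs = ((s_detr - cached) ** 2).sum(axis=1)
    else:
        errs = np.array([sse(d) for d in ds])
    i = int(np.argmin(errs))
    a = ds[max(i - 1, 0)]
    b = ds[min(i + 1, len(ds) - 1)]
    # Golden-section refinement on the bracketing interval.
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = sse(x1), sse(x2)
    for _ in range(40):
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = sse(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = sse(x2)
    d_hat = float((a + b) / 2.0)
    if full_output:
        return d_hat, sse(d_hat)
    return d_hat


def estimate_length(
    d: float,
    image_size: int,
    *,
    snap_grid: tuple[int, ...] | None = None,
) -> float:
    """Motion length L = N / d from the null spacing d.

    Parameters
    ----------
    d : float
        Null spacing in spectrum pixels (> 0).
    image_size : int
        N, the side length of the (square) image the spectrum came from.
    snap_grid : tuple of int, optional
        When given, the raw N/d is snapped to the nearest value of the
        grid (ties toward the smaller length), as in the grouped
        protocol whose lengths are the odd values 1..15.
    """
    if d <= 0:
        raise ValueError("null spacing d must be positive")
    raw = image_size / d
    if snap_grid is None:
        return float(raw)
    grid = np.asarray(snap_grid, dtype=float)
    return float(grid[int(np.argmin(np.abs(grid - raw)))])


def focus_score(
    spectrum: SpectrumImage,
    radius: float | None = None,
    margin: int = DEFAULT_MARGIN,
    theta_step: float = 1.0,
) -> float:
    """Focus score FS = 100 * S_(theta+90) / S_theta.

    ``theta`` is the Radon angle maximizing the rho-range sum P (the
    dominant ridge), ``S_theta = P(theta)`` and ``S_(theta+90)`` the
    orthogonal sum.  Isotropic (focused) spectra give FS near 100;
    motion blur depresses the orthogonal sum, lowering FS.  Because
    theta is the argmax, FS never exceeds 100 beyond interpolation
    noise.
    """
    score = _direction_score(spectrum, radius, margin, theta_step)
    p = score.p
    i = _argmax_smallest(p)
    n = len(p)
    j = (i + int(round(90.0 / (180.0 / n)))) % n
    s_dom = p[i]
    if s_dom <= 0:
        return 100.0  # degenerate flat spectrum: perfectly isotropic
    return float(100.0 * p[j] / s_dom)


def focus_and_direction(
    spectrum: SpectrumImage,
    radius: float | None = None,
    margin: int = DEFAULT_MARGIN,
    theta_step: float = 1.0,
) -> tuple[float, float]:
    """Focus score and motion-direction estimate from one accumulation.

    Equivalent to calling :func:`focus_score` and
    :func:`estimate_direction` but sharing the Radon pass they both
    need; used by the prediction pipeline where both are required.
    """
    score = _direction_score(spectrum, radius, margin, theta_step)
    p = score.p
    i = _argmax_smallest(p)
    n = len(p)
    j = (i + int(round(90.0 / (180.0 / n)))) % n
    fs = 100.0 if p[i] <= 0 else float(100.0 * p[j] / p[i])
    theta = float((180.0 - score.thetas_deg[i]) % 180.0)
    return fs, theta


def learn_focus_threshold(
    focused_scores: np.ndarray, blurred_scores: np.ndarray
) -> tuple[float, float]:
    """Learn the focused/blurred decision threshold from training scores.

    Classifies ``score >= threshold`` as focused.  The returned
    threshold minimizes the total number of misclassifications over the
    training scores; when an interval of thresholds is optimal, its
    midpoint is returned.  Also reports the equal-error-rate operating
    point (the rate at which the false-focused and false-blurred rates
    coincide, found by exhaustive sweep).

    Returns
    -------
    (threshold, eer) : tuple of float
        ``eer`` is a rate in [0, 1].
    """
    f = np.sort(np.asarray(focused_scores, dtype=float))
    b = np.sort(np.asarray(blurred_scores, dtype=float))
    if len(f) == 0 or len(b) == 0:
        raise ValueError("both score sets must be non-empty")
    cand = np.unique(np.concatenate([f, b]))
    # Candidate thresholds: each observed score and just above the top.
    # A threshold th in the interval (cand[k-1], cand[k]] classifies
    # identically to th = cand[k], so candidates stand for intervals.
    cand = np.concatenate([cand, [cand[-1] + 1.0]])
    # errors(th) = #focused below th + #blurred at/above th
    fn = np.searchsorted(f, cand, side="left")  # focused misclassified
    fp = len(b) - np.searchsorted(b, cand, side="left")  # blurred misclassified
    total = fn + fp
    best = total.min()
    opt = np.where(total == best)[0]
    lo_i, hi_i = opt[0], opt[-1]
    # midpoint of the full optimal interval (open at the score below
    # the first optimal candidate)
    lo_bound = cand[lo_i - 1] if lo_i > 0 else cand[0] - 1.0
    threshold = float((lo_bound + cand[hi_i]) / 2.0)

    fnr = fn / len(f)
    fpr = fp / len(b)
    k = int(np.argmin(np.abs(fnr - fpr)))
    eer = float((fnr[k] + fpr[k]) / 2.0)
    return threshold, eer


def assign_group(
    focus: FocusDecision,
    theta_est: float | None = None,
    length_est: float | None = None,
) -> str:
    """Map a (focus decision, direction, length) triple to one of 9 groups.

    Focused images go straight to ``"focused"``.  Blurred ones are
    binned by estimated length — below 4.5 focused (covers the no-blur
    and trivial length-3 cases), 4.5 to 10 slight, 10 and up blurred —
    and by the nearest canonical direction of {0, 45, 90, 135} modulo
    180 (ties toward the smaller angle).  Total and deterministic.
    """
    if focus.label == "focused":
        return "focused"
    if focus.label != "blurred":
        raise ValueError(f"unknown focus label {focus.label!r}")
    if theta_est is None or length_est is None:
        raise ValueError("blurred images require direction and length estimates")
    if length_est < _SLIGHT_EDGE:
        return "focused"
    severity = "slight" if length_est < _BLURRED_EDGE else "blurred"
    th = float(theta_est) % 180.0
    dists = [min(abs(th - c), 180.0 - abs(th - c)) for c in CANONICAL_DIRECTIONS]
    nearest = CANONICAL_DIRECTIONS[int(np.argmin(dists))]
    return f"{severity}-{int(nearest)}"
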