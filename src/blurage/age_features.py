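"""Age-related texture features: MLBP, Gabor wrinkle features, fusion, PCA.

Two complementary descriptors feed the age regressor:

* **MLBP** (multi-level local binary patterns) — per-pixel binary codes
  comparing each pixel's circular neighbors to its center, histogrammed
  over the "uniform" partition in non-overlapping sub-blocks at several
  (radius, neighbor-count, grid) levels and concatenated.  Captures the
  global micro-texture of the face (spots, roughness, fine wrinkles).
* **Gabor wrinkle features** — mean and standard deviation of each of
  five wrinkle regions filtered by a bank of even (cosine-phase) Gabor
  kernels at 4 scales and 6 orientations, 5 x 4 x 6 x 2 = 240 numbers
  measuring oriented wrinkle strength where wrinkles actually form.

The streams are Z-score normalized with statistics learned on the
training set, concatenated (MLBP first), and reduced by PCA before the
support-vector regressor sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .face_preprocess import WrinkleRegions

__all__ = [
    "LBPConfig",
    "MLBPConfig",
    "DEFAULT_MLBP",
    "GaborBank",
    "FeatureVector",
    "NormalizationStats",
    "lbp_code",
    "uniform_partition",
    "mlbp_feature",
    "gabor_kernel",
    "gabor_wrinkle_features",
    "zscore_fit",
    "zscore_apply",
    "fuse",
    "pca_fit",
    "pca_project",
]

#: Fixed ordering of the five wrinkle regions in the Gabor vector.
REGION_ORDER = (
    "forehead",
    "left_eye_corner",
    "right_eye_corner",
    "left_under_eye",
    "right_under_eye",
)

_STD_FLOOR = 1e-8


@dataclass(frozen=True)
class LBPConfig:
    """One LBP level: circle radius R, neighbor count P, sub-block grid."""

    radius: float = 1.0
    neighbors: int = 8
    grid: tuple[int, int] = (4, 4)  # (Mn, Nn) blocks vertically, horizontally

    def __post_init__(self) -> None:
        if not (4 <= self.neighbors <= 24):
            raise ValueError("neighbor count must be in 4..24")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if min(self.grid) < 1:
            raise ValueError("grid counts must be >= 1")

    @property
    def n_bins(self) -> int:
        p = self.neighbors
        return p * (p - 1) + 3


@dataclass(frozen=True)
class MLBPConfig:
    """Ordered list of LBP levels; order fixes the concatenation."""

    entries: tuple[LBPConfig, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("MLBP needs at least one LBP level")

    @property
    def feature_length(self) -> int:
        return sum(c.grid[0] * c.grid[1] * c.n_bins for c in self.entries)


#: Default two-level configuration: fine texture on a coarse grid and
#: slightly coarser texture on a fine grid.
DEFAULT_MLBP = MLBPConfig(
    entries=(
        LBPConfig(radius=1, neighbors=8, grid=(4, 4)),
        LBPConfig(radius=2, neighbors=8, grid=(8, 8)),
    )
)


@dataclass(frozen=True)
class GaborBank:
    """Even-symmetric Gabor bank: 4 scales x 6 orientations.

    Scale 0 uses ``(sigma_x, sigma_y, base_freq)``; each subsequent
    scale multiplies the sigmas and divides the frequency by
    ``scale_step``, moving toward coarser wrinkles.  The defaults put
    the four center frequencies at 0.17, 0.12, 0.085 and 0.06
    cycles/pixel with one-octave bandwidth (sigma ~ 0.56 wavelengths),
    spanning the wrinkle wavelengths of a face imaged at a few tens of
    pixels of inter-eye distance.
    """

    sigma_x: float = 3.3
    sigma_y: float = 3.3
    base_freq: float = 0.17
    scale_step: float = 2.0 ** 0.5
    n_scales: int = 4
    orientations_deg: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigmas must be positive")
        if self.n_scales != 4 or len(self.orientations_deg) != 6:
            raise ValueError("the wrinkle protocol uses exactly 4 scales x 6 orientations")

    @property
    def feature_length(self) -> int:
        return len(REGION_ORDER) * self.n_scales * len(self.orientations_deg) * 2


@dataclass(frozen=True)
class NormalizationStats:
    """Per-dimension mean and (floored) standard deviation of a stream."""

    mean: np.ndarray
    std: np.ndarray


@dataclass(frozen=True)
class FeatureVector:
    """Feature values plus the provenance of each span.

    ``block_map`` lists ``(label, start, stop)`` half-open spans telling
    which extractor (and block) produced which slice of ``values``.
    """

    values: np.ndarray
    block_map: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# LBP


def _neighbor_offsets(radius: float, neighbors: int) -> list[tuple[float, float]]:
    """(dy, dx) of neighbor i at angle 2*pi*i/P on the radius-R circle,
    counterclockwise on screen (y down)."""
    out = []
    for i in range(neighbors):
        a = 2.0 * np.pi * i / neighbors
        out.append((-radius * np.sin(a), radius * np.cos(a)))
    return out


def lbp_code(patch: np.ndarray, radius: float = 1.0, neighbors: int = 8) -> int:
    """LBP code of the center pixel of ``patch``.

    Neighbor i sits at angle ``2*pi*i/P`` on the radius-R circle around
    the center and is read with bilinear interpolation; it contributes
    bit ``2**i`` when its value is greater than or equal to the center
    (ties count as 1).
    """
    patch = np.asarray(patch, dtype=float)
    cy, cx = (patch.shape[0] - 1) / 2.0, (patch.shape[1] - 1) / 2.0
    if cy < radius or cx < radius:
        raise ValueError("patch too small: the R-circle falls outside it")
    gc = patch[int(round(cy)), int(round(cx))]
    code = 0
    for i, (dy, dx) in enumerate(_neighbor_offsets(radius, neighbors)):
        gi = ndimage.map_coordinates(
            patch, [[cy + dy], [cx + dx]], order=1, mode="nearest"
        )[0]
        if gi - gc >= 0:
            code |= 1 << i
    return code


@lru_cache(maxsize=32)
def uniform_partition(neighbors: int) -> np.ndarray:
    """Lookup table code -> histogram bin under the uniform partition.

    A code is *uniform* when its circular bit string has at most two
    0-1 transitions; each uniform code gets its own bin (in ascending
    code order) and all non-uniform codes share the final bin, for
    ``P*(P-1) + 3`` bins in total.
    """
    p = neighbors
    if p < 4:
        raise ValueError("need at least 4 neighbors")
    codes = np.arange(2 ** p)
    bits = (codes[:, None] >> np.arange(p)[None, :]) & 1
    transitions = (bits != np.roll(bits, -1, axis=1)).sum(axis=1)
    uniform = transitions <= 2
    table = np.full(2 ** p, -1, dtype=np.int64)
    table[uniform] = np.arange(uniform.sum())
    table[~uniform] = uniform.sum()
    return table


def _code_image(image: np.ndarray, radius: float, neighbors: int) -> np.ndarray:
    """Per-pixel LBP codes for the valid interior of ``image``.

    Vectorized: each neighbor position is a constant subpixel shift of
    the whole image, read bilinearly; the border of ceil(R) pixels is
    dropped because its circles leave the image.
    """
    image = np.asarray(image, dtype=float)
    m = int(np.ceil(radius))
    if image.shape[0] <= 2 * m or image.shape[1] <= 2 * m:
        raise ValueError("image smaller than the LBP circle")
    codes = np.zeros(image.shape, dtype=np.int64)
    for i, (dy, dx) in enumerate(_neighbor_offsets(radius, neighbors)):
        shifted = ndimage.shift(image, (-dy, -dx), order=1, mode="nearest")
        codes |= (shifted - image >= 0).astype(np.int64) << i
    return codes[m:-m, m:-m]


def mlbp_feature(roi: np.ndarray, config: MLBPConfig = DEFAULT_MLBP) -> FeatureVector:
    """Multi-level LBP histogram feature of a face ROI.

    For each level: compute per-pixel codes, split the valid code image
    into Mn x Nn non-overlapping blocks, histogram each block over the
    uniform partition, L1-normalize each block histogram to sum 1, and
    concatenate; levels are then concatenated in config order.
    """
    roi = np.asarray(roi, dtype=float)
    pieces: list[np.ndarray] = []
    block_map: list[tuple[str, int, int]] = []
    pos = 0
    for level, cfg in enumerate(config.entries):
        codes = _code_image(roi, cfg.radius, cfg.neighbors)
        table = uniform_partition(cfg.neighbors)
        bins = table[codes]
        n_bins = cfg.n_bins
        mn, nn = cfg.grid
        h, w = bins.shape
        if h < mn or w < nn:
            raise ValueError(
                f"level {level}: code image {bins.shape} smaller than grid {cfg.grid}"
            )
        # equal-size blocks; a remainder of < grid pixels at the
        # right/bottom edge is ignored
        bh, bw = h // mn, w // nn
        if bh < 2 * cfg.radius + 1 or bw < 2 * cfg.radius + 1:
            raise ValueError(f"level {level}: blocks smaller than the LBP circle")
        trimmed = bins[: mn * bh, : nn * bw]
        block_idx = (
            (np.arange(mn * bh) // bh)[:, None] * nn
            + (np.arange(nn * bw) // bw)[None, :]
        )
        flat = block_idx.ravel() * n_bins + trimmed.ravel()
        hist = np.bincount(flat, minlength=mn * nn * n_bins).astype(float)
        hist = hist.reshape(mn * nn, n_bins)
        hist /= hist.sum(axis=1, keepdims=True)
        vec = hist.ravel()
        pieces.append(vec)
        block_map.append(
            (f"mlbp[{level}]R{cfg.radius}P{cfg.neighbors}", pos, pos + len(vec))
        )
        pos += len(vec)
    return FeatureVector(values=np.concatenate(pieces), block_map=tuple(block_map))


# ---------------------------------------------------------------------------
# Gabor


def gabor_kernel(
    bank: GaborBank, scale: int, orientation_idx: int
) -> np.ndarray:
    """Even (cosine-phase) Gabor kernel at one scale and orientation.

    ``R(x', y') = exp(-(x'^2/sx^2 + y'^2/sy^2)/2) * cos(2 pi W x')
    / (2 pi sx sy)`` with (x', y') the coordinates rotated by the
    orientation; the value at the origin is ``1 / (2 pi sx sy)``.
    Support is truncated at 2.5 sigma on an odd-sized grid.
    """
    if not (0 <= scale < bank.n_scales):
        raise ValueError("scale index out of range")
    factor = bank.scale_step ** scale
    sx, sy = bank.sigma_x * factor, bank.sigma_y * factor
    w = bank.base_freq / factor
    phi = np.deg2rad(bank.orientations_deg[orientation_idx])
    half = int(np.ceil(2.5 * max(sx, sy)))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = x * np.cos(phi) + y * np.sin(phi)
    yr = -x * np.sin(phi) + y * np.cos(phi)
    envelope = np.exp(-0.5 * (xr ** 2 / sx ** 2 + yr ** 2 / sy ** 2))
    return envelope * np.cos(2.0 * np.pi * w * xr) / (2.0 * np.pi * sx * sy)


@lru_cache(maxsize=8)
def _bank_kernels(bank: GaborBank) -> tuple[tuple[int, int, np.ndarray], ...]:
    return tuple(
        (s, o, gabor_kernel(bank, s, o))
        for s in range(bank.n_scales)
        for o in range(len(bank.orientations_deg))
    )


_FFT_CACHE: dict[tuple, np.ndarray] = {}


def _filtered_stats(region: np.ndarray, kernel: np.ndarray, key: tuple) -> tuple[float, float]:
    """Mean and std of region (*) kernel over the region support.

    The region is edge-replicated by the kernel half-width before the
    FFT convolution so border pixels see real intensities rather than
    zeros — a constant region then filters to a constant.  Kernel FFTs
    are cached per (kernel, padded shape) because the same bank is
    applied to thousands of identically shaped regions.
    """
    rh, rw = region.shape
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(region, ((ph, ph), (pw, pw)), mode="edge")
    sh = (padded.shape[0] + kh - 1, padded.shape[1] + kw - 1)
    ck = ("k", key, sh)
    kf = _FFT_CACHE.get(ck)
    if kf is None:
        kf = np.fft.rfft2(kernel, sh)
        if len(_FFT_CACHE) < 4096:
            _FFT_CACHE[ck] = kf
    rf = np.fft.rfft2(padded, sh)
    full = np.fft.irfft2(rf * kf, sh)
    y0, x0 = (kh - 1) // 2 + ph, (kw - 1) // 2 + pw
    same = full[y0 : y0 + rh, x0 : x0 + rw]
    return float(same.mean()), float(same.std())


def gabor_wrinkle_features(
    image: np.ndarray,
    regions: WrinkleRegions,
    bank: GaborBank = GaborBank(),
) -> FeatureVector:
    """240-dimensional wrinkle descriptor of an aligned face image.

    For each of the five wrinkle regions and each (scale, orientation)
    of the bank, the region crop is convolved with the kernel and the
    mean and standard deviation of the filtered region are recorded:
    5 regions x 4 scales x 6 orientations x 2 statistics = 240 values,
    ordered region-major, then scale, orientation, (mean, std).
    """
    image = np.asarray(image, dtype=float)
    values: list[float] = []
    block_map: list[tuple[str, int, int]] = []
    kernels = _bank_kernels(bank)
    pos = 0
    for name in REGION_ORDER:
        x0, y0, x1, y1 = regions.regions[name]
        crop = image[y0:y1, x0:x1]
        if crop.size == 0:
            raise ValueError(f"empty wrinkle region {name!r}")
        start = pos
        for s, o, k in kernels:
            mu, sd = _filtered_stats(crop, k, (hash(bank), s, o))
            values.extend((mu, sd))
            pos += 2
        block_map.append((f"gabor:{name}", start, pos))
    return FeatureVector(values=np.asarray(values), block_map=tuple(block_map))


# ---------------------------------------------------------------------------
# Normalization, fusion, PCA


def zscore_fit(training: np.ndarray) -> NormalizationStats:
    """Per-dimension mean/std over training rows; std floored at 1e-8."""
    x = np.asarray(training, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    return NormalizationStats(
        mean=x.mean(axis=0), std=np.maximum(x.std(axis=0), _STD_FLOOR)
    )


def zscore_apply(vector: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return (np.asarray(vector, dtype=float) - stats.mean) / stats.std


def fuse(f1: FeatureVector, f2: FeatureVector) -> FeatureVector:
    """Concatenate two normalized streams, first stream first."""
    values = np.concatenate([f1.values, f2.values])
    offset = len(f1.values)
    bm = list(f1.block_map) + [(n, a + offset, b + offset) for n, a, b in f2.block_map]
    return FeatureVector(values=values, block_map=tuple(bm))


def pca_fit(training: np.ndarray, components: int | float = 0.98) -> PCA:
    """Principal basis of the (mean-centered) training vectors.

    ``components``: an int k keeps min(k, n-1, dim) components; a float
    in (0, 1) keeps enough components for that cumulative explained
    variance, capped at n-1.  Components are ordered by descending
    explained variance.
    """
    x = np.asarray(training, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if isinstance(components, (int, np.integer)):
        if components <= 0:
            raise ValueError("component count must be positive")
        n_comp: int | float = min(int(components), max_rank)
    else:
        if not (0.0 < components < 1.0):
            raise ValueError("variance fraction must lie in (0, 1)")
        n_comp = components
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(x)
    return pca


def pca_project(vector: np.ndarray, basis: PCA) -> np.ndarray:
    v = np.asarray(vector, dtype=float)
    squeeze = v.ndim == 1
    out = basis.transform(np.atleast_2d(v))
    return out[0] if squeeze else out
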