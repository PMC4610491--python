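"""Per-blur-group age estimation: training, routing, prediction, MAE.

The full pipeline mirrors the grouped protocol: a face image is
aligned from its eye positions, classified focused/blurred by the focus
score, its blur parameters estimated when blurred, routed to one of
nine blur groups, and finally scored by that group's own age model —
Z-score normalization, PCA reduction and an RBF support-vector
regressor trained on images with the same kind of blur.  Training
simulates the blur grid on sharp training faces so every group sees
images that genuinely belong to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import resize
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

from .age_features import (
    FeatureVector,
    NormalizationStats,
    fuse,
    gabor_wrinkle_features,
    mlbp_feature,
    pca_fit,
    pca_project,
    zscore_apply,
    zscore_fit,
)
from .blur_estimation import (
    FocusDecision,
    assign_group,
    estimate_length,
    fit_sinc,
    focus_and_direction,
    focus_score,
    learn_focus_threshold,
    radon_profile,
)
from .blur_model import log_power_spectrum
from .config import RunConfig
from .face_preprocess import EyeAnnotation, align, redefine_face_roi, wrinkle_regions
from .synthetic import make_blur_grid

__all__ = [
    "FaceSample",
    "TrainedAgeModel",
    "GroupModelRegistry",
    "AgePrediction",
    "TrainingRecord",
    "extract_features",
    "estimate_blur_state",
    "train_group",
    "prepare_training_records",
    "train_registry_from_records",
    "train_registry",
    "predict",
    "predict_with_model",
    "mae",
]


@dataclass(frozen=True)
class FaceSample:
    """A face image with its eye annotation and chronological age."""

    image: np.ndarray = field(repr=False)
    eyes: EyeAnnotation
    age: float


@dataclass(frozen=True)
class TrainedAgeModel:
    """One group's age estimator and everything needed to apply it."""

    group_id: str
    mlbp_stats: NormalizationStats
    gabor_stats: NormalizationStats
    pca: object
    svr: SVR
    n_train: int
    seed: int
    age_min: float
    age_max: float


@dataclass(frozen=True)
class GroupModelRegistry:
    """Trained models for all nine groups plus the focus threshold."""

    models: dict[str, TrainedAgeModel]
    focus_threshold: float
    config_hash: str
    seed: int


@dataclass(frozen=True)
class AgePrediction:
    """Predicted age with the routing decisions that produced it."""

    age: float
    group: str
    focus: FocusDecision
    theta_est: float | None
    length_est: float | None


@dataclass(frozen=True)
class TrainingRecord:
    """A (possibly blur-simulated) training image reduced to features."""

    base_index: int
    theta_deg: float
    length: int
    group: str
    fs: float
    mlbp: np.ndarray
    gabor: np.ndarray
    age: float


# ---------------------------------------------------------------------------
# Feature extraction and blur routing on single images


def _spectral_crop(image: np.ndarray, size: int) -> np.ndarray:
    """Centered square crop (side = min(h, w, size)) for spectral ops.

    Cropping rather than resizing keeps the pixel scale, so estimated
    motion lengths stay in original-image pixels.
    """
    h, w = image.shape
    side = min(h, w, size)
    y0 = (h - side) // 2
    x0 = (w - side) // 2
    return image[y0 : y0 + side, x0 : x0 + side]


def extract_features(
    image: np.ndarray, eyes: EyeAnnotation, config: RunConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (un-normalized) MLBP and Gabor feature streams of one face.

    Aligns the face, crops the redefined face ROI and resizes it to the
    configured square for MLBP; reads the Gabor wrinkle features from
    the five wrinkle regions of the aligned image at native scale.
    """
    aligned, eyes_a = align(np.asarray(image, dtype=float), eyes)
    roi = redefine_face_roi(eyes_a, aligned.shape, config.roi_ratios)
    x0, y0, x1, y1 = roi.bounds
    crop = aligned[y0:y1, x0:x1]
    std_roi = resize(
        crop, (config.roi_size, config.roi_size), order=1, preserve_range=True,
        anti_aliasing=True,
    )
    f_mlbp = mlbp_feature(std_roi, config.mlbp)
    regions = wrinkle_regions(eyes_a, aligned.shape, config.roi_ratios)
    f_gabor = gabor_wrinkle_features(aligned, regions, config.gabor)
    return f_mlbp.values, f_gabor.values


def estimate_blur_state(
    image: np.ndarray, config: RunConfig, threshold: float
) -> tuple[FocusDecision, float | None, float | None]:
    """Focus decision and, when blurred, (direction, snapped length)."""
    crop = _spectral_crop(np.asarray(image, dtype=float), config.spectral_window)
    spectrum = log_power_spectrum(crop)
    mindim = min(spectrum.values.shape)
    radius = config.radius_factor * mindim
    fs, theta0 = focus_and_direction(
        spectrum, radius, config.rho_margin, config.theta_step_deg
    )
    if fs >= threshold:
        return FocusDecision(score=fs, threshold=threshold, label="focused"), None, None
    decision = FocusDecision(score=fs, threshold=threshold, label="blurred")
    # Jointly refine direction and null spacing: the null comb of a
    # strong blur is dense, so a few degrees of direction error smears
    # it out of the pooled profile.  Scan candidate angles around the
    # Radon estimate and keep the (theta, d) pair whose detrended sinc
    # fit matches best.  The focus score already says "blurred", so the
    # feasible spacing is capped at N/2 (L >= 2), which keeps the fit
    # off the degenerate smooth-background solution.
    d_range = (mindim / 16.0, mindim / 2.0)
    best: tuple[float, float, float] | None = None  # (sse, theta, d)
    for delta in np.arange(-6.0, 6.1, 2.0):
        cand = (theta0 + delta) % 180.0
        profile = radon_profile(spectrum, cand)
        try:
            d, err = fit_sinc(
                profile, d_range=d_range, background="local", full_output=True
            )
        except ValueError:
            continue
        if best is None or err < best[0]:
            best = (err, cand, d)
    if best is None:
        return decision, theta0, 1.0
    _, theta, d = best
    length = estimate_length(d, mindim, snap_grid=config.length_grid)
    return decision, theta, length


# ---------------------------------------------------------------------------
# Training


def _feature_matrices(
    mlbp_rows: Sequence[np.ndarray], gabor_rows: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    return np.vstack(mlbp_rows), np.vstack(gabor_rows)


def train_group(
    mlbp_features: np.ndarray,
    gabor_features: np.ndarray,
    ages: Sequence[float],
    group_id: str,
    config: RunConfig,
    seed: int,
) -> TrainedAgeModel:
    """Fit one group's Z-score stats, PCA basis and SVR age model.

    ``mlbp_features`` and ``gabor_features`` are the raw per-sample
    feature rows of the group's training images (use
    :func:`extract_features`).  The SVR regularization constant is
    chosen by a small seeded K-fold grid search.  Deterministic given
    the seed.
    """
    x1 = np.asarray(mlbp_features, dtype=float)
    x2 = np.asarray(gabor_features, dtype=float)
    y = np.asarray(list(ages), dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"group {group_id!r}: need at least 10 samples, got {n}")
    if x1.shape[0] != n or x2.shape[0] != n:
        raise ValueError("feature row counts must match the number of ages")

    s1, s2 = zscore_fit(x1), zscore_fit(x2)
    fused = np.hstack([(x1 - s1.mean) / s1.std, (x2 - s2.mean) / s2.std])
    pca = pca_fit(fused, config.pca_components)
    z = pca.transform(fused)

    svr = SVR(kernel="rbf", gamma=config.svr_gamma, epsilon=config.svr_epsilon)
    if len(config.svr_c_grid) > 1:
        folds = max(2, min(config.cv_folds, n // 5))
        search = GridSearchCV(
            svr,
            {"C": list(config.svr_c_grid)},
            cv=KFold(n_splits=folds, shuffle=True, random_state=seed),
            scoring="neg_mean_absolute_error",
        )
        search.fit(z, y)
        svr = search.best_estimator_
    else:
        svr.set_params(C=config.svr_c_grid[0])
        svr.fit(z, y)

    return TrainedAgeModel(
        group_id=group_id,
        mlbp_stats=s1,
        gabor_stats=s2,
        pca=pca,
        svr=svr,
        n_train=n,
        seed=seed,
        age_min=float(y.min()),
        age_max=float(y.max()),
    )


def prepare_training_records(
    samples: Sequence[FaceSample],
    config: RunConfig,
    directions: Sequence[float],
    lengths: Sequence[int],
    seed: int,
) -> list[TrainingRecord]:
    """Simulate the blur grid on training faces and extract features.

    Every face contributes its sharp original plus each
    (direction, length) blurred variant; records carry the ground-truth
    group (training uses images that truly belong to each group), the
    focus score (for threshold learning) and both raw feature streams.
    """
    records: list[TrainingRecord] = []
    grid = make_blur_grid(
        [s.image for s in samples],
        directions=directions,
        lengths=lengths,
        seed=seed,
        ages=[s.age for s in samples],
        eyes=[s.eyes for s in samples],
    )
    for rec in grid:
        crop = _spectral_crop(rec.image, config.spectral_window)
        spectrum = log_power_spectrum(crop)
        radius = config.radius_factor * min(spectrum.values.shape)
        fs = focus_score(spectrum, radius, config.rho_margin, config.theta_step_deg)
        mlbp_row, gabor_row = extract_features(rec.image, rec.eyes, config)
        records.append(
            TrainingRecord(
                base_index=rec.base_index,
                theta_deg=rec.theta_deg,
                length=rec.length,
                group=rec.group,
                fs=fs,
                mlbp=mlbp_row,
                gabor=gabor_row,
                age=float(rec.age),
            )
        )
    return records


def train_registry_from_records(
    records: Sequence[TrainingRecord], config: RunConfig, seed: int
) -> GroupModelRegistry:
    """Train the focus threshold and all nine group models from records."""
    focused_fs = np.array([r.fs for r in records if r.length == 1])
    blurred_fs = np.array([r.fs for r in records if r.length > 1])
    threshold, _ = learn_focus_threshold(focused_fs, blurred_fs)

    groups: dict[str, list[TrainingRecord]] = {}
    for r in records:
        groups.setdefault(r.group, []).append(r)

    from .blur_estimation import GROUP_IDS

    models: dict[str, TrainedAgeModel] = {}
    for gid in GROUP_IDS:
        if gid not in groups:
            raise ValueError(
                f"training set leaves blur group {gid!r} empty; "
                "extend the blur grid or the sample set"
            )
        rows = groups[gid]
        models[gid] = train_group(
            np.vstack([r.mlbp for r in rows]),
            np.vstack([r.gabor for r in rows]),
            [r.age for r in rows],
            gid,
            config,
            seed,
        )
    return GroupModelRegistry(
        models=models,
        focus_threshold=float(threshold),
        config_hash=config.config_hash,
        seed=seed,
    )


def train_registry(
    samples: Sequence[FaceSample],
    config: RunConfig | None = None,
    seed: int = 0,
    directions: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
    lengths: Sequence[int] = (3, 5, 7, 9, 11, 13, 15),
) -> GroupModelRegistry:
    """End-to-end training: simulate the blur grid, train all groups."""
    config = config or RunConfig()
    records = prepare_training_records(samples, config, directions, lengths, seed)
    return train_registry_from_records(records, config, seed)


# ---------------------------------------------------------------------------
# Prediction and evaluation


def predict_with_model(
    model: TrainedAgeModel, mlbp_row: np.ndarray, gabor_row: np.ndarray
) -> float:
    """Apply one group model to raw feature streams; clamps to the
    model's training age range (SVR can extrapolate wildly)."""
    f1 = FeatureVector(values=zscore_apply(mlbp_row, model.mlbp_stats))
    f2 = FeatureVector(values=zscore_apply(gabor_row, model.gabor_stats))
    z = pca_project(fuse(f1, f2).values, model.pca)
    age = float(model.svr.predict(np.atleast_2d(z))[0])
    return float(np.clip(age, model.age_min, model.age_max))


def predict(
    image: np.ndarray,
    eyes: EyeAnnotation,
    registry: GroupModelRegistry,
    config: RunConfig | None = None,
) -> AgePrediction:
    """Full pipeline: align, classify blur, route to a group, estimate age."""
    config = config or RunConfig()
    aligned, eyes_a = align(np.asarray(image, dtype=float), eyes)
    decision, theta, length = estimate_blur_state(
        aligned, config, registry.focus_threshold
    )
    group = assign_group(decision, theta, length)
    model = registry.models.get(group)
    if model is None:
        raise KeyError(f"registry has no model for group {group!r}")
    mlbp_row, gabor_row = extract_features(image, eyes, config)
    age = predict_with_model(model, mlbp_row, gabor_row)
    return AgePrediction(
        age=age, group=group, focus=decision, theta_est=theta, length_est=length
    )


def mae(predictions: Sequence[float], truths: Sequence[float]) -> float:
    """Mean absolute error between predicted and true ages, in years."""
    p = np.asarray(list(predictions), dtype=float)
    t = np.asarray(list(truths), dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predictions and truths must be equal-length 1-D sequences")
    if len(p) == 0:
        raise ValueError("need at least one prediction")
    return float(np.mean(np.abs(p - t)))
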