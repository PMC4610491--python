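"""Run configuration: every tunable of the pipeline in one validated place.

The estimators and the age pipeline have a number of free parameters
(Radon geometry, length grid, MLBP levels, Gabor bank, ROI ratios, PCA
setting, SVR grid, seeds).  ``RunConfig`` carries them all with
defaults, round-trips through YAML, rejects unknown keys, and exposes a
stable content hash that trained-model archives record so a registry
can warn when loaded under a different configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .age_features import DEFAULT_MLBP, GaborBank, LBPConfig, MLBPConfig
from .blur_estimation import (
    DEFAULT_MARGIN,
    INNER_FACTOR,
    RADIUS_FACTOR,
    SMOOTH_SIGMA,
)
from .face_preprocess import DEFAULT_ROI_RATIOS, RoiRatios

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables with their defaults."""

    # blur estimation geometry
    radius_factor: float = RADIUS_FACTOR
    inner_factor: float = INNER_FACTOR
    rho_margin: int = DEFAULT_MARGIN
    theta_step_deg: float = 1.0
    smooth_sigma: float = SMOOTH_SIGMA
    # length protocol
    length_grid: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15)
    spectral_window: int = 128  # square crop side for face spectral ops
    # geometry
    roi_ratios: RoiRatios = DEFAULT_ROI_RATIOS
    roi_size: int = 128  # MLBP operates on the ROI resized to this square
    # features
    mlbp: MLBPConfig = DEFAULT_MLBP
    gabor: GaborBank = field(default_factory=GaborBank)
    pca_components: int | float = 10
    # SVR hyperparameter grid
    svr_c_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    svr_epsilon: float = 1.0
    svr_gamma: str = "scale"
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.radius_factor <= 0.5):
            raise ValueError("radius_factor must lie in (0, 0.5]")
        if not (0.0 <= self.inner_factor < self.radius_factor):
            raise ValueError("inner_factor must lie in [0, radius_factor)")
        if self.rho_margin < 0:
            raise ValueError("rho_margin must be non-negative")
        if self.theta_step_deg <= 0 or self.theta_step_deg > 45:
            raise ValueError("theta_step_deg must lie in (0, 45]")
        if len(self.length_grid) == 0 or any(l < 1 for l in self.length_grid):
            raise ValueError("length_grid must contain positive lengths")
        if self.roi_size < 16:
            raise ValueError("roi_size too small for texture features")
        if not self.svr_c_grid:
            raise ValueError("svr_c_grid must be non-empty")

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [conv(v) for v in obj]
            return obj

        return {k: conv(getattr(self, k)) for k in _FIELD_NAMES}

    @property
    def config_hash(self) -> str:
        """Stable short hash of the full configuration content."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(_FIELD_NAMES)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key, value in data.items():
            if key == "roi_ratios":
                kwargs[key] = RoiRatios(**value)
            elif key == "mlbp":
                entries = tuple(
                    LBPConfig(
                        radius=e["radius"],
                        neighbors=e["neighbors"],
                        grid=tuple(e["grid"]),
                    )
                    for e in value["entries"]
                )
                kwargs[key] = MLBPConfig(entries=entries)
            elif key == "gabor":
                value = dict(value)
                if "orientations_deg" in value:
                    value["orientations_deg"] = tuple(value["orientations_deg"])
                kwargs[key] = GaborBank(**value)
            elif key in ("length_grid", "svr_c_grid"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


_FIELD_NAMES = tuple(f.name for f in dataclasses.fields(RunConfig))


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
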