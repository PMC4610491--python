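"""Image, annotation and model-registry I/O.

Images are read from PNG/JPEG/BMP and converted to grayscale with the
ITU-R 601 luminance weights.  Eye annotations travel as a CSV sidecar
with columns ``image_path, right_eye_x, right_eye_y, left_eye_x,
left_eye_y, age``.  Trained registries serialize to a directory archive
with a JSON manifest (format version, config hash, seed, group list)
and one joblib file per group model, and refuse to load across format
versions or with groups missing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .age_estimator import GroupModelRegistry, TrainedAgeModel
from .blur_estimation import GROUP_IDS
from .face_preprocess import EyeAnnotation

__all__ = [
    "AnnotationRecord",
    "read_image",
    "write_image",
    "read_annotations",
    "write_annotations",
    "save_registry",
    "load_registry",
]

logger = logging.getLogger("blurage")

REGISTRY_FORMAT_VERSION = 1

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R 601

ANNOTATION_COLUMNS = (
    "image_path",
    "right_eye_x",
    "right_eye_y",
    "left_eye_x",
    "left_eye_y",
    "age",
)


@dataclass(frozen=True)
class AnnotationRecord:
    image_path: str
    eyes: EyeAnnotation
    age: float


def read_image(path: str | Path) -> np.ndarray:
    """Load an image as float grayscale in [0, 255].

    Color inputs are reduced with the ITU-R 601 luminance weights
    (0.299 R + 0.587 G + 0.114 B); 8-bit grayscale files round-trip
    bit-exactly.  Unreadable or truncated files raise ``ValueError``
    with the path in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        with Image.open(path) as img:
            img.load()
            if img.mode in ("L", "I", "I;16", "F"):
                arr = np.asarray(img, dtype=float)
                if img.mode in ("I", "I;16"):
                    arr = arr * (255.0 / 65535.0)
                return arr
            rgb = np.asarray(img.convert("RGB"), dtype=float)
            return rgb @ _LUMA
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Save a float grayscale image (clipped to [0, 255]) as 8-bit."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_annotations(
    csv_path: str | Path, image_shape: tuple[int, int] | None = None
) -> list[AnnotationRecord]:
    """Parse and validate an eye-annotation CSV.

    Rejects rows with missing fields, vertically aligned eye pairs
    (``right_eye_x == left_eye_x``), coordinates outside the image (when
    a shape is given) or ages outside the sanity bound [0, 130]; errors
    name the offending line number (1-based, header = line 1).
    """
    df = pd.read_csv(csv_path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    records: list[AnnotationRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        if row[list(ANNOTATION_COLUMNS)].isna().any():
            problems.append(f"line {line}: missing fields")
            continue
        rx, ry = float(row.right_eye_x), float(row.right_eye_y)
        lx, ly = float(row.left_eye_x), float(row.left_eye_y)
        age = float(row.age)
        if rx == lx:
            problems.append(f"line {line}: eyes vertically aligned (Rx == Lx)")
            continue
        if not (0.0 <= age <= 130.0):
            problems.append(f"line {line}: implausible age {age}")
            continue
        if image_shape is not None:
            h, w = image_shape
            if not all(0 <= v < w for v in (rx, lx)) or not all(
                0 <= v < h for v in (ry, ly)
            ):
                problems.append(f"line {line}: eye coordinates outside the image")
                continue
        if rx > lx:
            # normalize handedness: right eye is the smaller-x eye
            rx, ry, lx, ly = lx, ly, rx, ry
        records.append(
            AnnotationRecord(
                image_path=str(row.image_path),
                eyes=EyeAnnotation(right_eye=(rx, ry), left_eye=(lx, ly)),
                age=age,
            )
        )
    if problems:
        raise ValueError("invalid annotation rows: " + "; ".join(problems))
    return records


def write_annotations(records: list[AnnotationRecord], csv_path: str | Path) -> None:
    rows = [
        {
            "image_path": r.image_path,
            "right_eye_x": r.eyes.right_eye[0],
            "right_eye_y": r.eyes.right_eye[1],
            "left_eye_x": r.eyes.left_eye[0],
            "left_eye_y": r.eyes.left_eye[1],
            "age": r.age,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(csv_path, index=False)


def save_registry(registry: GroupModelRegistry, path: str | Path) -> None:
    """Write a registry archive: manifest.json + one joblib per group."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": REGISTRY_FORMAT_VERSION,
        "config_hash": registry.config_hash,
        "seed": registry.seed,
        "focus_threshold": registry.focus_threshold,
        "groups": sorted(registry.models),
    }
    with open(path / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    for gid, model in registry.models.items():
        joblib.dump(model, path / f"group_{gid}.joblib")


def load_registry(
    path: str | Path, expected_config_hash: str | None = None
) -> GroupModelRegistry:
    """Load a registry archive, checking version and completeness.

    A manifest config hash differing from ``expected_config_hash`` is
    logged as a warning (the models may have been trained under other
    tunables); a missing group or a format-version mismatch is an error
    naming the problem.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"not a registry archive (no manifest.json): {path}")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    version = manifest.get("format_version")
    if version != REGISTRY_FORMAT_VERSION:
        raise ValueError(
            f"registry format version {version} unsupported "
            f"(expected {REGISTRY_FORMAT_VERSION})"
        )
    if expected_config_hash and manifest.get("config_hash") != expected_config_hash:
        logger.warning(
            "registry config hash %s differs from current config %s",
            manifest.get("config_hash"),
            expected_config_hash,
        )
    models: dict[str, TrainedAgeModel] = {}
    for gid in GROUP_IDS:
        f = path / f"group_{gid}.joblib"
        if not f.exists():
            raise ValueError(f"registry archive missing group {gid!r}")
        models[gid] = joblib.load(f)
    return GroupModelRegistry(
        models=models,
        focus_threshold=float(manifest["focus_threshold"]),
        config_hash=str(manifest["config_hash"]),
        seed=int(manifest["seed"]),
    )
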