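"""Face alignment and region geometry from eye positions.

Given the two eye centers (from any external detector, or from the
synthetic generator), this module levels the in-plane rotation of the
head, redefines a tight face region of interest, and places the five
wrinkle regions — forehead, the two outer eye corners and the two
under-eye areas — where age-related wrinkle texture concentrates.

All geometry is expressed in ratios of the inter-eye distance D, so it
is equivariant under uniform image scaling.  Coordinates are 0-based
with x rightward and y downward; rectangles are half-open
``(x0, y0, x1, y1)`` with ``x0 <= x < x1`` and ``y0 <= y < y1``.  The
"right" eye is the one with the smaller x coordinate (the subject's
right, the viewer's left).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _rotate_image

__all__ = [
    "EyeAnnotation",
    "FaceROI",
    "WrinkleRegions",
    "RoiRatios",
    "DEFAULT_ROI_RATIOS",
    "inplane_angle",
    "align",
    "redefine_face_roi",
    "wrinkle_regions",
]

Rect = tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open


@dataclass(frozen=True)
class EyeAnnotation:
    """Detected eye centers, pixels: right = smaller x (viewer's left)."""

    right_eye: tuple[float, float]
    left_eye: tuple[float, float]

    def __post_init__(self) -> None:
        if self.right_eye[0] == self.left_eye[0]:
            raise ValueError("eyes must be horizontally distinct (Rx != Lx)")
        if self.right_eye[0] > self.left_eye[0]:
            raise ValueError(
                "right eye must have the smaller x coordinate; swap the annotation"
            )

    @property
    def midpoint(self) -> tuple[float, float]:
        return (
            (self.right_eye[0] + self.left_eye[0]) / 2.0,
            (self.right_eye[1] + self.left_eye[1]) / 2.0,
        )

    @property
    def distance(self) -> float:
        dx = self.left_eye[0] - self.right_eye[0]
        dy = self.left_eye[1] - self.right_eye[1]
        return float(np.hypot(dx, dy))


@dataclass(frozen=True)
class FaceROI:
    """Redefined face rectangle and the eye distance it was derived from."""

    bounds: Rect
    eye_distance: float


@dataclass(frozen=True)
class WrinkleRegions:
    """The five wrinkle rectangles, keyed by anatomical name."""

    regions: dict[str, Rect]
    clipped: tuple[str, ...] = ()  # regions truncated at the image border

    def __post_init__(self) -> None:
        expected = {
            "forehead",
            "left_eye_corner",
            "right_eye_corner",
            "left_under_eye",
            "right_under_eye",
        }
        if set(self.regions) != expected:
            raise ValueError(f"regions must be exactly {sorted(expected)}")


@dataclass(frozen=True)
class RoiRatios:
    """Face-ROI and wrinkle-region geometry as multiples of eye distance D.

    The face rectangle is ``width x height = (roi_width * D) x
    (roi_height * D)`` centered horizontally on the eye midpoint with
    its top edge ``roi_top * D`` above the eye line.  Wrinkle boxes are
    placed analogously; see :func:`wrinkle_regions`.
    """

    roi_width: float = 2.0
    roi_top: float = 0.6
    roi_height: float = 2.4
    forehead_w: float = 1.6
    forehead_h: float = 0.5
    forehead_up: float = 0.7
    corner_size: float = 0.4
    under_w: float = 0.5
    under_h: float = 0.35
    under_down: float = 0.45


DEFAULT_ROI_RATIOS = RoiRatios()


def inplane_angle(eyes: EyeAnnotation) -> float:
    """In-plane head-rotation angle, degrees: atan((Ry - Ly)/(Rx - Lx)).

    Zero when the eyes are level; positive when the right (smaller-x)
    eye sits lower than the left in image coordinates.
    """
    rx, ry = eyes.right_eye
    lx, ly = eyes.left_eye
    return float(np.degrees(np.arctan((ry - ly) / (rx - lx))))


def _rotate_point(
    p: tuple[float, float], center: tuple[float, float], angle_deg: float
) -> tuple[float, float]:
    """Rotate a point about a center by the same transform align() applies
    to pixel content (angle positive = counterclockwise on screen)."""
    a = np.deg2rad(angle_deg)
    x, y = p[0] - center[0], p[1] - center[1]
    # y grows downward, so an on-screen CCW rotation is (x cos + y sin,
    # -x sin + y cos) in image coordinates.
    return (
        center[0] + x * np.cos(a) + y * np.sin(a),
        center[1] - x * np.sin(a) + y * np.cos(a),
    )


def align(
    image: np.ndarray, eyes: EyeAnnotation
) -> tuple[np.ndarray, EyeAnnotation]:
    """Rotate the image about the eye midpoint so the eye line is level.

    Uses bilinear interpolation; the returned eye annotation is the
    input one passed through the same rotation, so recomputing
    :func:`inplane_angle` on it gives approximately zero.
    """
    theta = inplane_angle(eyes)
    center = eyes.midpoint
    if abs(theta) < 1e-12:
        return np.asarray(image, dtype=float), eyes
    # skimage.rotate's positive angle turns the content CCW on screen
    # about (col, row) = center; rotating by -theta levels the eyes.
    rotated = _rotate_image(
        np.asarray(image, dtype=float),
        theta,
        center=center,
        order=1,
        mode="edge",
        preserve_range=True,
    )
    new_eyes = EyeAnnotation(
        right_eye=_rotate_point(eyes.right_eye, center, theta),
        left_eye=_rotate_point(eyes.left_eye, center, theta),
    )
    return rotated, new_eyes


def _clip_rect(rect: Rect, shape: tuple[int, int] | None) -> tuple[Rect, bool]:
    if shape is None:
        return rect, False
    h, w = shape
    x0, y0, x1, y1 = rect
    cx0, cy0 = max(x0, 0), max(y0, 0)
    cx1, cy1 = min(x1, w), min(y1, h)
    return (cx0, cy0, cx1, cy1), (cx0, cy0, cx1, cy1) != rect


def redefine_face_roi(
    eyes: EyeAnnotation,
    image_shape: tuple[int, int] | None = None,
    ratios: RoiRatios = DEFAULT_ROI_RATIOS,
) -> FaceROI:
    """Tight face rectangle from the (aligned) eye positions.

    Width ``roi_width * D`` centered on the eye midpoint, top edge
    ``roi_top * D`` above the eye line, height ``roi_height * D``;
    clipped to the image when a shape is given.
    """
    d = eyes.distance
    if d < 2.0:
        raise ValueError(f"degenerate eye distance {d:.2f}")
    mx, my = eyes.midpoint
    x0 = int(round(mx - ratios.roi_width * d / 2.0))
    x1 = int(round(mx + ratios.roi_width * d / 2.0))
    y0 = int(round(my - ratios.roi_top * d))
    y1 = int(round(y0 + ratios.roi_height * d))
    rect, _ = _clip_rect((x0, y0, x1, y1), image_shape)
    if rect[2] <= rect[0] or rect[3] <= rect[1]:
        raise ValueError("face ROI collapsed after clipping to the image")
    return FaceROI(bounds=rect, eye_distance=d)


def _box(cx: float, cy: float, w: float, h: float) -> Rect:
    return (
        int(round(cx - w / 2.0)),
        int(round(cy - h / 2.0)),
        int(round(cx + w / 2.0)),
        int(round(cy + h / 2.0)),
    )


def wrinkle_regions(
    eyes: EyeAnnotation,
    image_shape: tuple[int, int] | None = None,
    ratios: RoiRatios = DEFAULT_ROI_RATIOS,
) -> WrinkleRegions:
    """The five wrinkle rectangles for an aligned face.

    Forehead centered ``forehead_up * D`` above the eye midpoint; a
    square box outward of each eye corner; an under-eye box
    ``under_down * D`` below each eye.  Left/right boxes are mirror
    images about the vertical through the eye midpoint.  Regions that
    had to be clipped at the image border are flagged in ``clipped``.
    """
    d = eyes.distance
    mx, my = eyes.midpoint
    rxe, rye = eyes.right_eye
    lxe, lye = eyes.left_eye
    r = ratios
    raw: dict[str, Rect] = {
        "forehead": _box(mx, my - r.forehead_up * d, r.forehead_w * d, r.forehead_h * d),
        "right_eye_corner": _box(
            rxe - (0.5 + r.corner_size / 2.0) * 0.5 * d, rye,
            r.corner_size * d, r.corner_size * d,
        ),
        "left_eye_corner": _box(
            lxe + (0.5 + r.corner_size / 2.0) * 0.5 * d, lye,
            r.corner_size * d, r.corner_size * d,
        ),
        "right_under_eye": _box(rxe, rye + r.under_down * d, r.under_w * d, r.under_h * d),
        "left_under_eye": _box(lxe, lye + r.under_down * d, r.under_w * d, r.under_h * d),
    }
    clipped: list[str] = []
    out: dict[str, Rect] = {}
    for name, rect in raw.items():
        c, was_clipped = _clip_rect(rect, image_shape)
        if c[2] <= c[0] or c[3] <= c[1]:
            raise ValueError(f"wrinkle region {name!r} fell outside the image")
        out[name] = c
        if was_clipped:
            clipped.append(name)
    return WrinkleRegions(regions=out, clipped=tuple(sorted(clipped)))
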