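"""Pixel-to-millimetre calibration from the in-image size-reference label.

Every bunch-zone image carries a colored reference label of known physical
length fixed to the trellis wire. The label is located as the largest
connected component inside a chroma window distinct from all berry color
classes; its major-axis length in pixels against the known length in mm
gives the image scale. Images without a label stay uncalibrated (their
berry sizes remain in pixels and are excluded from mm statistics) rather
than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

MIN_LABEL_AREA_PX = 150


class LabelNotFoundError(RuntimeError):
    """No reference label found; the image is flagged uncalibrated."""


class UncalibratedError(RuntimeError):
    """Millimetre output requested for an image without a calibration."""


@dataclass(frozen=True)
class LabelColorSpec:
    """Chroma window of the reference label (inclusive channel bounds).

    Default matches the generator's magenta label: strong red and blue,
    suppressed green — a region of RGB space no berry class occupies.
    """

    r_min: float = 150.0
    g_max: float = 110.0
    b_min: float = 150.0

    def mask(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, float)
        return (
            (img[:, :, 0] >= self.r_min)
            & (img[:, :, 1] <= self.g_max)
            & (img[:, :, 2] >= self.b_min)
        )


@dataclass(frozen=True)
class ScaleCalibration:
    mm_per_pixel: float
    label_bbox: tuple[int, int, int, int]  # x0, y0, x1, y1 (exclusive)
    confidence: float = 1.0


def locate_reference_label(
    image: np.ndarray,
    color_spec: LabelColorSpec | None = None,
    min_area_px: int = MIN_LABEL_AREA_PX,
) -> tuple[int, int, int, int]:
    """Bounding box of the largest in-window connected component.

    Raises :class:`LabelNotFoundError` when no component reaches
    ``min_area_px`` — the caller flags the image uncalibrated.
    """
    spec = color_spec or LabelColorSpec()
    mask = spec.mask(image)
    if not mask.any():
        raise LabelNotFoundError("no pixels in the label chroma window")
    regions = regionprops(cc_label(mask))
    best = max(regions, key=lambda rg: rg.area)
    if best.area < min_area_px:
        raise LabelNotFoundError(
            f"largest label-colored component has area {best.area} < {min_area_px} px"
        )
    y0, x0, y1, x1 = best.bbox
    return (int(x0), int(y0), int(x1), int(y1))


def compute_scale(
    label_bbox: tuple[int, int, int, int], known_length_mm: float
) -> ScaleCalibration:
    """mm-per-pixel from the label's major-axis length.

    Reading along the longer bbox side keeps the scale robust to small
    label rotations and to whether the label hangs lengthwise or upright.
    """
    if known_length_mm <= 0:
        raise ValueError("known_length_mm must be positive")
    x0, y0, x1, y1 = label_bbox
    length_px = max(x1 - x0, y1 - y0)
    if length_px < 2 or min(x1 - x0, y1 - y0) < 1:
        raise ValueError(f"degenerate label bbox {label_bbox}")
    return ScaleCalibration(
        mm_per_pixel=known_length_mm / length_px,
        label_bbox=tuple(int(v) for v in label_bbox),
    )


def calibrate_image(
    image: np.ndarray,
    known_length_mm: float,
    color_spec: LabelColorSpec | None = None,
) -> ScaleCalibration:
    """Locate the label and compute the image scale in one step."""
    return compute_scale(locate_reference_label(image, color_spec), known_length_mm)


def berry_diameter_mm(radius_px: float, calibration: ScaleCalibration | None) -> float:
    """Berry diameter in millimetres; refuses silent pixel output."""
    if calibration is None:
        raise UncalibratedError("image has no scale calibration; size stays in px")
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    return 2.0 * radius_px * calibration.mm_per_pixel
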