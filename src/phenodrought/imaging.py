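"""Leaf green area (LGA) from RGB images and relative growth rate.

The estimator is the pixel-ratio method: a 100 cm² blue calibration card
is photographed alongside the plant, pixels are classed as green
(foliage), blue (card) or background by hue/saturation/value thresholds,
and

    LGA [cm²] = card_area × green_pixels / blue_pixels.

The method assumes card and canopy sit at comparable optical scale
(no perspective correction is applied — a stated estimator assumption).
Relative growth rate between two imaging dates is the log-difference of
the two LGA estimates divided by the elapsed days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label

__all__ = [
    "SegmentationThresholds",
    "LGAEstimate",
    "CalibrationCardNotFoundError",
    "read_image",
    "segment_pixels",
    "estimate_lga",
    "estimate_lga_from_image",
    "compute_rgr",
]


class CalibrationCardNotFoundError(ValueError):
    """No blue calibration-card pixels were detected in the image."""


@dataclass(frozen=True)
class SegmentationThresholds:
    """Hue/saturation/value gates for the green and blue pixel classes.

    Hue in degrees on [0, 360); saturation and value as fractions.  The
    defaults separate foliage from a blue card under diffuse light and
    leave white/grey backgrounds (low saturation) unclassified.
    """

    green_hue_range: tuple[float, float] = (70.0, 165.0)
    blue_hue_range: tuple[float, float] = (190.0, 260.0)
    min_saturation: float = 0.25
    min_value: float = 0.15

    def __post_init__(self) -> None:
        g0, g1 = self.green_hue_range
        b0, b1 = self.blue_hue_range
        if not (0 <= g0 < g1 < 360 and 0 <= b0 < b1 < 360):
            raise ValueError("hue ranges must be non-empty and within [0, 360)")
        if g1 > b0 and b1 > g0:
            raise ValueError("green and blue hue ranges must be disjoint")
        if not (0 <= self.min_saturation <= 1 and 0 <= self.min_value <= 1):
            raise ValueError("saturation/value thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class LGAEstimate:
    green_pixels: int
    blue_pixels: int
    card_area_cm2: float
    lga_cm2: float


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as an (H, W, 3) uint8 RGB array (alpha dropped)."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return np.asarray(img[..., :3])


def _remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    if min_size <= 1:
        return mask
    lab = label(mask, connectivity=2)
    keep = np.zeros(lab.max() + 1, dtype=bool)
    counts = np.bincount(lab.ravel())
    keep[counts >= min_size] = True
    keep[0] = False
    return keep[lab]


def segment_pixels(
    image: np.ndarray,
    thresholds: SegmentationThresholds | None = None,
    min_blob_size: int = 0,
) -> tuple[int, int]:
    """Count green (plant) and blue (calibration card) pixels.

    Each pixel falls into at most one of green/blue/background by the HSV
    gates.  ``min_blob_size`` optionally removes connected components
    smaller than the given pixel count (off by default so the counts stay
    bit-predictable).

    Raises :class:`CalibrationCardNotFoundError` if no blue pixel is found.
    """
    thresholds = thresholds or SegmentationThresholds()
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3 or arr.size == 0:
        raise ValueError("expected a non-empty (H, W, 3) RGB image")
    hsv = rgb2hsv(arr)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    vivid = (sat >= thresholds.min_saturation) & (val >= thresholds.min_value)
    g0, g1 = thresholds.green_hue_range
    b0, b1 = thresholds.blue_hue_range
    green = vivid & (hue >= g0) & (hue <= g1)
    blue = vivid & (hue >= b0) & (hue <= b1)
    green = _remove_small(green, min_blob_size)
    blue = _remove_small(blue, min_blob_size)
    n_blue = int(blue.sum())
    if n_blue == 0:
        raise CalibrationCardNotFoundError(
            "calibration card not found: no blue pixels detected"
        )
    return int(green.sum()), n_blue


def estimate_lga(
    green_pixels: int, blue_pixels: int, card_area_cm2: float = 100.0
) -> float:
    """Leaf green area in cm² from the green:blue pixel ratio."""
    if blue_pixels <= 0:
        raise ValueError("blue_pixels must be positive (card area reference)")
    if green_pixels < 0:
        raise ValueError("green_pixels must be non-negative")
    return card_area_cm2 * green_pixels / blue_pixels


def estimate_lga_from_image(
    image: np.ndarray,
    thresholds: SegmentationThresholds | None = None,
    card_area_cm2: float = 100.0,
    min_blob_size: int = 0,
) -> LGAEstimate:
    g, b = segment_pixels(image, thresholds, min_blob_size)
    return LGAEstimate(g, b, card_area_cm2, estimate_lga(g, b, card_area_cm2))


def compute_rgr(lga1: float, lga2: float, day1: int, day2: int) -> float:
    """Relative growth rate per day between two imaging dates.

    ``(ln lga2 − ln lga1) / (day2 − day1)``; negative when the canopy
    shrank.  Both areas must be positive and day2 must follow day1.
    """
    if lga1 <= 0 or lga2 <= 0:
        raise ValueError("leaf areas must be positive for log growth rate")
    if day2 <= day1:
        raise ValueError("second imaging date must be after the first")
    return (math.log(lga2) - math.log(lga1)) / (day2 - day1)
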