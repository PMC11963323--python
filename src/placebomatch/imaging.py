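"""Mean-color extraction from powder photographs.

Powders are photographed flat in round containers against a near-100%
reflectance whiteboard. Two steps turn a raster into a query color:

1. :func:`whiteboard_calibrate` — per-channel linear gain that maps the
   measured whiteboard color to (255, 255, 255), normalizing the light
   source.
2. :func:`roi_mean_rgb` — arithmetic mean over pixels whose centers fall
   inside the circular container region.

Locating the container (an object-detection task) is out of scope; the
circle is taken as input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colors import RGBColor

__all__ = ["CircularROI", "roi_mean_rgb", "whiteboard_calibrate"]


@dataclass(frozen=True)
class CircularROI:
    """Circle in pixel coordinates: 0-based center (cx rightward, cy
    downward) and radius > 0."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 color image, got shape {img.shape}")
    return img


def roi_mean_rgb(image: np.ndarray, roi: CircularROI) -> RGBColor:
    """Mean RGB over pixels with (x-cx)^2 + (y-cy)^2 <= radius^2.

    Pixel (x, y) is included when its integer center satisfies the
    inequality (<= comparison), so the result matches a per-pixel loop
    exactly. Raises if no pixel center falls inside the circle.
    """
    img = _check_image(image)
    h, w = img.shape[:2]
    ys, xs = np.mgrid[0:h, 0:w]
    mask = (xs - roi.cx) ** 2 + (ys - roi.cy) ** 2 <= roi.radius**2
    if not mask.any():
        raise ValueError("circular ROI contains no pixel centers within the image")
    mean = img[mask].mean(axis=0)
    return RGBColor(float(mean[0]), float(mean[1]), float(mean[2]))


def whiteboard_calibrate(image: np.ndarray, whiteboard_mean: RGBColor) -> np.ndarray:
    """Scale each channel by 255 / whiteboard channel and clip to [0, 255].

    Once the whiteboard itself maps to 255 the correction is the
    identity, so applying it twice is a no-op (up to clipping).
    """
    img = _check_image(image)
    wb = whiteboard_mean.as_array()
    if np.any(wb <= 0):
        raise ValueError("whiteboard channels must all be positive")
    return np.clip(img * (255.0 / wb), 0.0, 255.0)
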