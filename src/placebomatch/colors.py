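"""Color representations and color-difference metrics.

Granule powders are measured as mean RGB triplets (0-255 per channel).
Perceptual comparison between a reference granule and its candidate
placebo happens in CIELAB space: the Euclidean distance there (``delta_e``)
grades how visible a mismatch is, with conventional perceptibility bands
at 1 / 3 / 6 / 9 / 12. A second, intensity-insensitive similarity is the
cosine of the angle between raw RGB vectors (``cosine_similarity``).

The RGB->Lab conversion uses the sRGB companding curve and the D65 2deg
white point — the de facto convention for industrial camera RGB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "RGBColor",
    "LabColor",
    "DeltaEBand",
    "DELTA_E_BANDS",
    "rgb_to_lab",
    "lab_to_rgb",
    "delta_e",
    "cosine_similarity",
    "classify_delta_e",
    "round_half_up",
]


@dataclass(frozen=True)
class RGBColor:
    """A color as red/green/blue intensities in [0, 255].

    Channels are real-valued so that means over pixels can be carried
    exactly; values read from 8-bit images are integers.
    """

    r: float
    g: float
    b: float

    def __post_init__(self) -> None:
        for name, v in (("r", self.r), ("g", self.g), ("b", self.b)):
            if not math.isfinite(v) or not (0.0 <= v <= 255.0):
                raise ValueError(f"channel {name}={v!r} outside [0, 255]")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)


@dataclass(frozen=True)
class LabColor:
    """CIELAB color: lightness L in [0, 100], opponent axes a (green-red)
    and b (blue-yellow)."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.L) or not (0.0 <= self.L <= 100.0 + 1e-9):
            raise ValueError(f"L={self.L!r} outside [0, 100]")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class DeltaEBand:
    """One perceptibility band of the delta-E scale; the interval is
    half-open [lower, upper)."""

    label: str
    lower: float
    upper: float

    def __contains__(self, d: float) -> bool:
        return self.lower <= d < self.upper


#: Half-open partition of [0, inf) into perceptibility grades.
DELTA_E_BANDS: tuple[DeltaEBand, ...] = (
    DeltaEBand("nearly_undetectable", 0.0, 1.0),
    DeltaEBand("very_small", 1.0, 3.0),
    DeltaEBand("slight", 3.0, 6.0),
    DeltaEBand("fair", 6.0, 9.0),
    DeltaEBand("clear", 9.0, 12.0),
    DeltaEBand("different", 12.0, math.inf),
)


def _as_rgb(c: "RGBColor | Iterable[float]") -> RGBColor:
    if isinstance(c, RGBColor):
        return c
    r, g, b = c
    return RGBColor(float(r), float(g), float(b))


def rgb_to_lab(c: "RGBColor | Iterable[float]") -> LabColor:
    """Convert an 8-bit-scaled RGB color to CIELAB (sRGB companding,
    D65 2deg observer). White (255,255,255) maps to L=100, a=b=0."""
    c = _as_rgb(c)
    lab = _skcolor.rgb2lab(c.as_array().reshape(1, 1, 3) / 255.0)[0, 0]
    # guard against float roundoff pushing L a hair past 100
    return LabColor(float(np.clip(lab[0], 0.0, 100.0)), float(lab[1]), float(lab[2]))


def lab_to_rgb(c: LabColor) -> RGBColor:
    """Inverse conversion (values clipped into gamut), mainly for
    round-trip checking."""
    rgb = _skcolor.lab2rgb(c.as_array().reshape(1, 1, 3))[0, 0]
    rgb = np.clip(rgb, 0.0, 1.0) * 255.0
    return RGBColor(float(rgb[0]), float(rgb[1]), float(rgb[2]))


def delta_e(x: LabColor, y: LabColor) -> float:
    """Euclidean color difference in CIELAB:
    sqrt((L-L0)^2 + (a-a0)^2 + (b-b0)^2)."""
    return float(np.linalg.norm(x.as_array() - y.as_array()))


def cosine_similarity(u: "RGBColor | Iterable[float]", v: "RGBColor | Iterable[float]") -> float:
    """Cosine of the angle between two raw RGB vectors; 1 means identical
    hue direction regardless of intensity scale.

    Raises ValueError for an all-zero vector (the angle is undefined).
    """
    ua, va = _as_rgb(u).as_array(), _as_rgb(v).as_array()
    nu, nv = np.linalg.norm(ua), np.linalg.norm(va)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for the zero vector")
    return float(np.dot(ua, va) / (nu * nv))


def classify_delta_e(d: float) -> DeltaEBand:
    """Map a color difference to its perceptibility band."""
    if not math.isfinite(d) or d < 0.0:
        raise ValueError(f"delta E must be a finite non-negative number, got {d!r}")
    for band in DELTA_E_BANDS:
        if d in band:
            return band
    raise AssertionError("unreachable: bands partition [0, inf)")


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal half-up rounding used when rendering delta-E / COS tables
    (Python's round() is half-even)."""
    q = 10.0**ndigits
    return math.floor(x * q + 0.5) / q
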