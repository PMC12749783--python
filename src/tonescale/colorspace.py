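"""Color space conversions and the individual typology angle (ITA).

Implements the standard sRGB → linear RGB → XYZ → CIELAB chain (IEC
61966-2-1 transfer function and primaries, D65 white point, 2° standard
observer) and the dermatologic ITA formula

    ITA = arctan((L* - 50) / b*) · 180/π   [degrees]

which maps skin color onto a single lightness axis: larger angles mean
lighter skin. All functions are pure; identical inputs give bit-identical
outputs. Forward and inverse conversions are provided so synthetic skin
patches can be rendered at a known CIELAB color.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateChromaticity

__all__ = [
    "Rgb8",
    "LabColor",
    "ItaDegrees",
    "srgb_to_linear",
    "linear_to_srgb",
    "linear_to_xyz",
    "xyz_to_linear",
    "xyz_to_lab",
    "lab_to_xyz",
    "rgb_to_lab",
    "lab_to_rgb",
    "ita_from_lab",
    "DEFAULT_B_FLOOR",
]

# sRGB (D65) RGB→XYZ matrix, 2° observer.
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ_TO_RGB = np.linalg.inv(_RGB_TO_XYZ)

# D65 reference white, taken as the exact row sums of the matrix so the
# neutral axis (r = g = b) maps to a* = b* = 0 identically.
WHITE_POINT = tuple(float(v) for v in _RGB_TO_XYZ.sum(axis=1))

# CIELAB companding constants: delta = 6/29.
_DELTA = 6.0 / 29.0
_DELTA3 = _DELTA**3

#: Below this |b*| magnitude ITA is treated as undefined (neutral axis).
DEFAULT_B_FLOOR = 1e-6


@dataclass(frozen=True)
class Rgb8:
    """An 8-bit sRGB triplet, each channel in [0, 255]."""

    r: int
    g: int
    b: int

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0 <= v <= 255) or int(v) != v:
                raise ValueError(f"channel {name}={v!r} outside integer [0, 255]")


@dataclass(frozen=True)
class LabColor:
    """A CIELAB point: L* in [0,100], a*/b* chromaticities in [-127, 127]."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.L <= 100.0):
            raise ValueError(f"L*={self.L} outside [0, 100]")
        for name in ("a", "b"):
            v = getattr(self, name)
            if not (-127.0 <= v <= 127.0):
                raise ValueError(f"{name}*={v} outside [-127, 127]")


@dataclass(frozen=True)
class ItaDegrees:
    """An individual typology angle in degrees, strictly inside (-90, 90)."""

    value: float

    def __post_init__(self) -> None:
        if not (-90.0 < self.value < 90.0):
            raise ValueError(f"ITA {self.value} outside (-90, 90)")


def _channel_to_linear(c8: int) -> float:
    c = c8 / 255.0
    if c <= 0.04045:
        return c / 12.92
    return ((c + 0.055) / 1.055) ** 2.4


def _channel_to_srgb8(lin: float) -> int:
    lin = min(max(lin, 0.0), 1.0)
    if lin <= 0.0031308:
        c = 12.92 * lin
    else:
        c = 1.055 * lin ** (1.0 / 2.4) - 0.055
    return int(round(c * 255.0))


def srgb_to_linear(c: Rgb8) -> tuple[float, float, float]:
    """Decode an 8-bit sRGB triplet to linear-light reflectances in [0, 1]."""
    return (_channel_to_linear(c.r), _channel_to_linear(c.g), _channel_to_linear(c.b))


def linear_to_srgb(rgb_linear) -> Rgb8:
    """Encode linear-light reflectances back to 8-bit sRGB (clipping to gamut)."""
    r, g, b = rgb_linear
    return Rgb8(_channel_to_srgb8(r), _channel_to_srgb8(g), _channel_to_srgb8(b))


def linear_to_xyz(rgb_linear) -> tuple[float, float, float]:
    """Map linear sRGB to XYZ tristimulus values (linear, D65)."""
    x, y, z = _RGB_TO_XYZ @ np.asarray(rgb_linear, dtype=float)
    return (float(x), float(y), float(z))


def xyz_to_linear(xyz) -> tuple[float, float, float]:
    r, g, b = _XYZ_TO_RGB @ np.asarray(xyz, dtype=float)
    return (float(r), float(g), float(b))


def _f(t: float) -> float:
    if t > _DELTA3:
        return t ** (1.0 / 3.0)
    return t / (3.0 * _DELTA**2) + 4.0 / 29.0


def _f_inv(u: float) -> float:
    if u > _DELTA:
        return u**3
    return 3.0 * _DELTA**2 * (u - 4.0 / 29.0)


def xyz_to_lab(xyz) -> LabColor:
    """Convert XYZ to CIELAB against the D65 white point."""
    x, y, z = (v / w for v, w in zip(xyz, WHITE_POINT))
    fx, fy, fz = _f(x), _f(y), _f(z)
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    # Guard tiny negative L from float noise at black.
    return LabColor(min(max(L, 0.0), 100.0), a, b)


def lab_to_xyz(c: LabColor) -> tuple[float, float, float]:
    fy = (c.L + 16.0) / 116.0
    fx = fy + c.a / 500.0
    fz = fy - c.b / 200.0
    return tuple(
        _f_inv(u) * w for u, w in zip((fx, fy, fz), WHITE_POINT)
    )  # type: ignore[return-value]


def rgb_to_lab(c: Rgb8) -> LabColor:
    """Full chain: decode sRGB, map to XYZ, convert to CIELAB."""
    return xyz_to_lab(linear_to_xyz(srgb_to_linear(c)))


def lab_to_rgb(c: LabColor) -> Rgb8:
    """Inverse chain, used to render patches at a target CIELAB color.

    Out-of-gamut colors are clipped channel-wise; the round trip is exact to
    ±1 per channel only for in-gamut colors.
    """
    return linear_to_srgb(xyz_to_linear(lab_to_xyz(c)))


def ita_from_lab(c: LabColor, b_floor: float = DEFAULT_B_FLOOR) -> ItaDegrees:
    """Individual typology angle of a CIELAB color, in degrees.

    Uses arctan (not atan2) exactly as the formula is written, so a negative
    b* flips the sign of the angle rather than wrapping the quadrant.

    Raises
    ------
    DegenerateChromaticity
        If ``|b*| < b_floor``: on the neutral axis the angle is undefined.
    """
    if abs(c.b) < b_floor:
        raise DegenerateChromaticity(
            f"|b*|={abs(c.b):.3g} below floor {b_floor:g}; ITA undefined"
        )
    return ItaDegrees(math.atan((c.L - 50.0) / c.b) * 180.0 / math.pi)


def ita_values(L: np.ndarray, b: np.ndarray, b_floor: float = DEFAULT_B_FLOOR) -> np.ndarray:
    """Vectorized ITA over parallel L*/b* arrays; NaN where |b*| is below floor."""
    L = np.asarray(L, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.degrees(np.arctan((L - 50.0) / np.where(np.abs(b) < b_floor, np.nan, b)))
    return out
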