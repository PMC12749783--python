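"""Representative color and ITA extraction from dermoscopy-style image patches.

The extraction mirrors the pixel-wise procedure used for dermoscopic images:
take the per-channel (marginal) median of the 8-bit RGB pixels, then run the
median color through the sRGB → CIELAB chain and the ITA formula. The median
is computed on integer channels *before* linearization, matching the order
"extract RGB, then convert". An optional boolean mask restricts which pixels
participate (dark dermoscopy corners, stickers); masking is off by default.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image

from .colorspace import ItaDegrees, LabColor, Rgb8, ita_from_lab, rgb_to_lab
from .errors import EmptyMask

__all__ = ["ImagePatch", "median_rgb", "image_ita", "load_patch", "ita_table"]


@dataclass
class ImagePatch:
    """A grid of 8-bit RGB pixels with an optional inclusion mask.

    ``pixels`` has shape (H, W, 3), dtype uint8; ``mask`` (H, W) boolean,
    True where the pixel participates in extraction. ``mask=None`` means all
    pixels participate.
    """

    pixels: np.ndarray
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.pixels.size == 0:
            raise ValueError("empty pixel grid")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValueError("mask shape must match pixel grid")

    def included(self) -> np.ndarray:
        """Return the (N, 3) array of participating pixels."""
        if self.mask is None:
            return self.pixels.reshape(-1, 3)
        return self.pixels[self.mask]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def median_rgb(img: ImagePatch) -> Rgb8:
    """Per-channel median color of the included pixels.

    Odd pixel counts take the central order statistic; even counts average
    the two central values and round half away from zero. Raises
    :class:`EmptyMask` when the mask excludes every pixel.
    """
    px = img.included()
    if px.shape[0] == 0:
        raise EmptyMask("inclusion mask selects no pixel")
    med = np.median(px.astype(np.int64), axis=0)
    return Rgb8(*(min(max(_round_half_away(float(m)), 0), 255) for m in med))


def image_ita(img: ImagePatch):
    """ITA of the patch's median color: ``ita_from_lab(rgb_to_lab(median_rgb))``.

    Propagates :class:`~tonescale.errors.DegenerateChromaticity` for neutral
    (gray) patches.
    """
    return ita_from_lab(rgb_to_lab(median_rgb(img)))


def load_patch(path: str | Path) -> ImagePatch:
    """Read a PNG or JPEG file into an :class:`ImagePatch` (RGB, no mask)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return ImagePatch(arr)


def ita_table(paths: Iterable[str | Path], out_csv: str | Path | None = None) -> list[dict]:
    """Extract median color and ITA for each image; optionally write a CSV.

    One row per image: path, median R/G/B, L*, a*, b*, ITA (empty when the
    chromaticity is degenerate).
    """
    rows: list[dict] = []
    for p in paths:
        patch = load_patch(p)
        med = median_rgb(patch)
        lab = rgb_to_lab(med)
        try:
            ita: float | str = ita_from_lab(lab).value
        except Exception:
            ita = ""
        rows.append(
            {
                "path": str(p),
                "median_r": med.r,
                "median_g": med.g,
                "median_b": med.b,
                "L": lab.L,
                "a": lab.a,
                "b": lab.b,
                "ita": ita,
            }
        )
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()) if rows else ["path"])
            writer.writeheader()
            writer.writerows(rows)
    return rows
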