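"""Skin-tone scale constants and the Pantone swatch code codec.

Scales
------
* FST (Fitzpatrick Skin Type): 6 photosensitivity classes I..VI, coded 1..6.
  Not a color scale — the analyses exist to test exactly that.
* MST (Monk Skin Tone): 10 shades, 1 (lightest) .. 10 (darkest).
* Pantone SkinTone Guide: swatches coded by undertone (5R..1R, 1Y..5Y) and
  pigment/lightness (1..15). For ordinal analysis the undertone is mapped to
  10 ordered levels 5R,4R,3R,2R,1R,1Y,2Y,3Y,4Y,5Y (1..10) — the only
  ordering that makes "5R to 5Y" an ordinal range — and pigment is its own
  15-level scale. A swatch code is written like ``"3Y08"``.
"""
from __future__ import annotations

K_FST = 6
K_MST = 10
K_PANTONE_PIGMENT = 15
K_PANTONE_UNDERTONE = 10

#: The 11 standardized non-lesional body sites.
ANATOMIC_SITES = (
    "forehead",
    "chest",
    "abdomen",
    "inner_upper_arm",
    "inner_wrist",
    "forearm",
    "upper_back",
    "lower_back",
    "shin",
    "calf",
    "sole",
)

DERMOSCOPY_MODES = ("P-C", "P-NC", "NP-C", "NP-NC")
TBP_MODES = ("xp", "wl")


def pantone_code(undertone: int, pigment: int) -> str:
    """Compose a swatch code from ordinal undertone (1..10) and pigment (1..15)."""
    if not (1 <= undertone <= K_PANTONE_UNDERTONE):
        raise ValueError(f"undertone ordinal {undertone} outside [1, 10]")
    if not (1 <= pigment <= K_PANTONE_PIGMENT):
        raise ValueError(f"pigment {pigment} outside [1, 15]")
    if undertone <= 5:
        level, letter = 6 - undertone, "R"
    else:
        level, letter = undertone - 5, "Y"
    return f"{level}{letter}{pigment:02d}"


def parse_pantone(code: str) -> tuple[int, int]:
    """Split a swatch code into (ordinal undertone 1..10, pigment 1..15)."""
    code = code.strip().upper()
    if len(code) < 3 or code[1] not in "RY":
        raise ValueError(f"malformed Pantone code {code!r}")
    level = int(code[0])
    if not (1 <= level <= 5):
        raise ValueError(f"undertone level {level} outside [1, 5] in {code!r}")
    pigment = int(code[2:])
    if not (1 <= pigment <= K_PANTONE_PIGMENT):
        raise ValueError(f"pigment {pigment} outside [1, 15] in {code!r}")
    undertone = 6 - level if code[1] == "R" else 5 + level
    return undertone, pigment
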