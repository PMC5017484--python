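"""Masked colour-average features of a section.

Seven component planes are derived from the normalised RGB raster —
hue, saturation, value, red, green, blue and grey — each scaled to unit
range.  Grey is the luma combination Y = 0.299 R + 0.587 G + 0.114 B.
For each component C the scalar feature is the mask-normalised average

    Fav^C = (1 / A_E) * sum over section pixels of P^C(x, y),

which removes the effect of varying acorn size.

Hue needs two adjustments before it can support single-threshold
discrimination.  Acorn hues aggregate near the 0/1 wrap-around of the
hue circle, so the stored hue plane is pre-processed with
P^H = mod(H + 0.5, 1.0); averages and thresholds then act on a
monotonic scale.  Saturation can have inverted polarity on some
acquisition setups (germinating seeds less saturated); the feature can
be flipped as Fav^S* = 1 - Fav^S, recorded by a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .errors import DegenerateMaskError
from .segmentation import CircleMask

GREY_WEIGHTS = (0.299, 0.587, 0.114)

COMPONENTS = ("H", "S", "V", "R", "G", "B", "Y")

#: feature-table column for each component
COMPONENT_COLUMNS = {
    "H": "fav_h", "S": "fav_s", "V": "fav_v", "R": "fav_r",
    "G": "fav_g", "B": "fav_b", "Y": "fav_y",
}


@dataclass(frozen=True)
class FeatureVector:
    """The seven unit-range masked averages for one section."""

    fav_h: float
    fav_s: float
    fav_v: float
    fav_r: float
    fav_g: float
    fav_b: float
    fav_y: float
    sequence_id: int = 0
    saturation_flipped: bool = False

    def component(self, name: str) -> float:
        return getattr(self, COMPONENT_COLUMNS[name])

    def as_dict(self) -> dict:
        return {
            "sequence_id": self.sequence_id,
            **{col: getattr(self, col) for col in COMPONENT_COLUMNS.values()},
            "saturation_flipped": self.saturation_flipped,
        }


def rgb_to_hsv(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hexcone HSV with hue scaled to [0, 1); H = S = 0 where max = min."""
    hsv = rgb2hsv(pixels)
    return hsv[..., 0], hsv[..., 1], hsv[..., 2]


def grey_from_rgb(pixels: np.ndarray) -> np.ndarray:
    wr, wg, wb = GREY_WEIGHTS
    return wr * pixels[..., 0] + wg * pixels[..., 1] + wb * pixels[..., 2]


def offset_hue(h: np.ndarray) -> np.ndarray:
    """P^H = mod(H + 0.5, 1.0): moves the red wrap-around to mid-scale."""
    return np.mod(np.asarray(h) + 0.5, 1.0)


def average_component(plane: np.ndarray, mask: CircleMask) -> float:
    """(1 / A_E) * sum of the plane over mask-true pixels."""
    if plane.shape != mask.mask.shape:
        raise ValueError("plane and mask must share the raster shape")
    if mask.area <= 0:
        raise DegenerateMaskError("section mask has zero area")
    return float(plane[mask.mask].sum() / mask.area)


def extract_features(pixels: np.ndarray, mask: CircleMask,
                     sequence_id: int = 0,
                     flip_s: bool = False) -> FeatureVector:
    """All seven masked averages on one (normalised) RGB raster.

    The hue average is taken on the offset plane; every undefined hue
    (zero saturation) contributes offset value 0.5, since the sum runs
    over all section pixels unconditionally.
    """
    h, s, v = rgb_to_hsv(pixels)
    planes = {
        "fav_h": offset_hue(h),
        "fav_s": s,
        "fav_v": v,
        "fav_r": pixels[..., 0],
        "fav_g": pixels[..., 1],
        "fav_b": pixels[..., 2],
        "fav_y": grey_from_rgb(pixels),
    }
    favs = {k: average_component(p, mask) for k, p in planes.items()}
    if flip_s:
        favs["fav_s"] = flip_saturation(favs["fav_s"])
    return FeatureVector(sequence_id=sequence_id, saturation_flipped=flip_s, **favs)


def flip_saturation(fav_s: float) -> float:
    """Polarity flip Fav^S* = 1 - Fav^S."""
    return 1.0 - fav_s
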