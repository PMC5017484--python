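"""Single-pass white balance and brightness normalisation.

Every acquired image carries a square patch of the white holder material
in its upper-left corner.  Because the patch is neutral, its channel
means estimate the illuminant: the red and blue channels are first
rebalanced toward the patch's green mean (grey-world on the reference
patch, with green as the anchor), then all three channels are multiplied
by ``Gain = green_target / mean_green`` so the patch lands on the fixed
target level GreenT = 0.824.  The target sits below the upper limit of
the range so that bright pixels rarely saturate; corrected values are
clipped to [0, 1] and a warning is logged if more than 0.1% of pixels
clip.

The correction equalises colour components across an acquisition
sequence; it does not restore colorimetrically absolute colour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateReferenceError, GeometryError
from .scenes import RawScene

log = logging.getLogger(__name__)

#: fixed post-normalisation level of the reference patch's green mean
GREEN_TARGET = 0.824

#: warn when more than this fraction of pixels clip at 1.0
_CLIP_WARN_FRACTION = 1e-3


@dataclass(frozen=True)
class ReferenceStats:
    """Channel means over the reference patch."""

    mean_red: float
    mean_green: float
    mean_blue: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_red, self.mean_green, self.mean_blue])


@dataclass
class NormalisationResult:
    """Corrected raster plus the correction actually applied."""

    pixels: np.ndarray
    gain: float
    balance_factors: tuple[float, float, float]
    green_target: float = GREEN_TARGET


def compute_reference_stats(scene: RawScene) -> ReferenceStats:
    """Arithmetic mean of each channel over the scene's patch region."""
    x, y, w, h = scene.patch_region
    H, W = scene.pixels.shape[:2]
    if not (0 <= x and 0 <= y and x + w <= W and y + h <= H):
        raise GeometryError("patch region lies outside the raster")
    patch = scene.pixels[y:y + h, x:x + w]
    m = patch.reshape(-1, 3).mean(axis=0)
    return ReferenceStats(float(m[0]), float(m[1]), float(m[2]))


def _patch_stats(pixels: np.ndarray,
                 patch_region: tuple[int, int, int, int]) -> ReferenceStats:
    return compute_reference_stats(RawScene(pixels=pixels, patch_region=patch_region))


def _clip_with_warning(pixels: np.ndarray, stage: str) -> np.ndarray:
    n_clip = int(np.count_nonzero(pixels > 1.0))
    if n_clip > _CLIP_WARN_FRACTION * pixels.size:
        log.warning("%s clipped %.2f%% of samples", stage,
                    100.0 * n_clip / pixels.size)
    return np.clip(pixels, 0.0, 1.0)


def white_balance(pixels: np.ndarray,
                  stats: ReferenceStats) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Scale red and blue toward the patch's green mean; green unchanged.

    After scaling the patch means of all three channels are equal (to
    numerical tolerance).  Values are clipped to [0, 1].
    """
    if stats.mean_red <= 0.0 or stats.mean_green <= 0.0 or stats.mean_blue <= 0.0:
        raise DegenerateReferenceError("zero patch channel mean: cannot balance")
    factors = (stats.mean_green / stats.mean_red, 1.0,
               stats.mean_green / stats.mean_blue)
    out = _clip_with_warning(pixels * np.array(factors), "white balance")
    return out, factors


def apply_gain(pixels: np.ndarray,
               stats_after_balance: ReferenceStats,
               green_target: float = GREEN_TARGET) -> NormalisationResult:
    """Brightness correction: multiply all channels by GreenT / mean_green."""
    if stats_after_balance.mean_green <= 0.0:
        raise DegenerateReferenceError("zero patch green mean: cannot set gain")
    gain = green_target / stats_after_balance.mean_green
    out = _clip_with_warning(pixels * gain, "gain")
    return NormalisationResult(pixels=out, gain=gain,
                               balance_factors=(1.0, 1.0, 1.0),
                               green_target=green_target)


def normalise(scene: RawScene,
              green_target: float = GREEN_TARGET) -> NormalisationResult:
    """White balance then brightness normalisation, in a single pass.

    Afterwards the reference-patch means equal
    ``(green_target,) * 3`` to within ~1e-3 (exactly, up to clipping
    elsewhere in the frame).
    """
    stats = compute_reference_stats(scene)
    balanced, factors = white_balance(scene.pixels, stats)
    stats2 = _patch_stats(balanced, scene.patch_region)
    result = apply_gain(balanced, stats2, green_target)
    result.balance_factors = factors
    return result
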