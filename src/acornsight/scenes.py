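"""Synthetic scarified-acorn scenes.

No public image set accompanies the screening method this package
implements, so the generator below emulates the statistical structure the
pipeline relies on: a neutral white-fiberboard holder with a square
reference patch in the upper-left corner, a darker circular cross-section
made of two bright cotyledons separated by a dark edge and ringed by dark
pericarp, optional dark low-saturation mummification blobs on spoiled
seeds, and multiplicative illumination drift (per-image brightness gain
and per-channel colour cast) across an acquisition sequence.

Reflectance levels are expressed on a unit scale with the holder — the
brightest material in the scene — exposed near half scale.  That headroom
mirrors raw 12-bit acquisition practice: even under a 1.9x combined
gain/cast excursion no holder or patch pixel saturates, which is the
property that makes the patch usable as a normalisation reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError

log = logging.getLogger(__name__)

Triplet = tuple[float, float, float]

#: label codes in the composition map
BACKGROUND, PERICARP, COTYLEDON, DIVIDER, MUMMIFICATION = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class SceneParams:
    """Geometry, reflectance and illumination of one synthetic scene.

    All level triplets are linear RGB reflectances in [0, 1].  The holder
    (``background_level``) doubles as the reference-patch material; the
    patch always occupies the ``patch_size`` x ``patch_size`` square at the
    image origin.  ``illumination_gain`` and ``colour_cast`` multiply the
    composed reflectance image before noise, emulating lamp drift and
    colour-temperature drift respectively.
    """

    image_width: int = 360
    image_height: int = 300
    patch_size: int = 100
    circle_centre: tuple[float, float] = (225.0, 165.0)
    circle_radius: float = 110.0
    background_level: Triplet = (0.520, 0.515, 0.500)
    cotyledon_level_healthy: Triplet = (0.440, 0.400, 0.200)
    pericarp_level: Triplet = (0.160, 0.100, 0.060)
    mummification_level: Triplet = (0.090, 0.080, 0.075)
    pericarp_thickness_frac: float = 0.12
    divider_width: float = 3.0
    divider_arc: bool = False
    mummification_fraction: float = 0.0
    illumination_gain: float = 1.0
    colour_cast: Triplet = (1.0, 1.0, 1.0)
    noise_sd: float = 0.003     # ~12 DN of a 4096-level 12-bit raw scale
    bit_depth: int = 12
    seed: int = 0

    def validate(self) -> None:
        cx, cy = self.circle_centre
        r = self.circle_radius
        if r <= 0:
            raise ConfigurationError("circle_radius must be positive")
        if not (cx - r >= 0 and cy - r >= 0 and cx + r < self.image_width
                and cy + r < self.image_height):
            raise ConfigurationError("circle must lie entirely inside the image")
        # nearest point of the patch square to the circle centre
        px = min(max(cx, 0.0), float(self.patch_size))
        py = min(max(cy, 0.0), float(self.patch_size))
        if np.hypot(cx - px, cy - py) <= r:
            raise ConfigurationError("circle overlaps the reference patch")
        if self.patch_size > min(self.image_width, self.image_height):
            raise ConfigurationError("reference patch does not fit in the image")
        for name in ("background_level", "cotyledon_level_healthy",
                     "pericarp_level", "mummification_level"):
            trip = getattr(self, name)
            if not all(0.0 <= v <= 1.0 for v in trip):
                raise ConfigurationError(f"{name} components must lie in [0, 1]")
        if self.illumination_gain <= 0:
            raise ConfigurationError("illumination_gain must be positive")
        if any(c <= 0 for c in self.colour_cast):
            raise ConfigurationError("colour_cast components must be positive")
        if not 0.0 <= self.mummification_fraction <= 1.0:
            raise ConfigurationError("mummification_fraction must lie in [0, 1]")
        if self.bit_depth not in (8, 12, 16):
            raise ConfigurationError("bit_depth must be 8, 12 or 16")


@dataclass(frozen=True)
class GroundTruth:
    """Label and applied parameters of one generated scene."""

    germinating: bool
    circle_centre: tuple[float, float]
    circle_radius: float
    mummification_fraction: float
    illumination_gain: float
    colour_cast: Triplet


@dataclass
class RawScene:
    """An acquired (or simulated) raster plus acquisition metadata.

    ``pixels`` is float64 RGB in [0, 1]; ``bit_depth`` records the storage
    quantisation (metadata only — all arithmetic is unit-range float).
    """

    pixels: np.ndarray
    bit_depth: int = 12
    patch_region: tuple[int, int, int, int] = (0, 0, 100, 100)
    sequence_id: int = 0

    def __post_init__(self) -> None:
        x, y, w, h = self.patch_region
        H, W = self.pixels.shape[:2]
        if not (0 <= x and 0 <= y and x + w <= W and y + h <= H and w > 0 and h > 0):
            raise ConfigurationError("patch_region must lie fully inside the raster")


def section_label_map(params: SceneParams) -> np.ndarray:
    """Deterministic composition map (codes above), before mummification.

    Exposed so the area-weighted expected colour of a section can be
    computed in closed form from the generator's own geometry.
    """
    params.validate()
    yy, xx = np.mgrid[0:params.image_height, 0:params.image_width]
    cx, cy = params.circle_centre
    r = params.circle_radius
    dist = np.hypot(xx - cx, yy - cy)
    labels = np.full(dist.shape, BACKGROUND, dtype=np.uint8)
    inner_r = r * (1.0 - params.pericarp_thickness_frac)
    labels[dist <= r] = PERICARP
    inner = dist <= inner_r
    labels[inner] = COTYLEDON
    if params.divider_arc:
        # size-asymmetric cotyledons: the separating edge bows into an arc
        arc_r = 1.6 * inner_r
        arc_cy = cy + arc_r - 0.35 * inner_r
        arc_dist = np.hypot(xx - cx, yy - arc_cy)
        edge = np.abs(arc_dist - arc_r) <= params.divider_width / 2.0
    else:
        edge = np.abs(yy - cy) <= params.divider_width / 2.0
    labels[inner & edge] = DIVIDER
    return labels


def _add_mummification(labels: np.ndarray, params: SceneParams,
                       rng: np.random.Generator) -> float:
    """Paint dark elliptical blobs on cotyledon tissue; returns achieved
    fraction of the full section area."""
    target = params.mummification_fraction
    if target <= 0:
        return 0.0
    cx, cy = params.circle_centre
    r = params.circle_radius
    section_area = int(np.count_nonzero(labels != BACKGROUND))
    inner_r = r * (1.0 - params.pericarp_thickness_frac)
    yy, xx = np.mgrid[0:labels.shape[0], 0:labels.shape[1]]
    inner = np.hypot(xx - cx, yy - cy) <= inner_r
    covered = np.zeros(labels.shape, dtype=bool)
    # blob area is capped at a quarter of the requested cover, so the
    # achieved fraction overshoots the target by at most that cap
    a_upper = r * np.sqrt(max(0.003, target / 4.0))
    # keep drawing seeded ellipses until the requested cover is reached
    for _ in range(400):
        if np.count_nonzero(covered) >= target * section_area:
            break
        rho = inner_r * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        bx, by = cx + rho * np.cos(phi), cy + rho * np.sin(phi)
        a = rng.uniform(0.55, 1.0) * a_upper
        b = rng.uniform(0.5, 1.0) * a
        theta = rng.uniform(0.0, np.pi)
        u = (xx - bx) * np.cos(theta) + (yy - by) * np.sin(theta)
        v = -(xx - bx) * np.sin(theta) + (yy - by) * np.cos(theta)
        blob = ((u / a) ** 2 + (v / b) ** 2 <= 1.0) & inner
        covered |= blob
    labels[covered] = MUMMIFICATION
    return np.count_nonzero(covered) / section_area


def generate_scene(params: SceneParams) -> tuple[RawScene, GroundTruth]:
    """Compose one scene and its ground truth.

    Composition order: background (and reference patch, same material) →
    pericarp ring → cotyledon disc with dark dividing edge → mummification
    blobs → per-channel multiply by colour_cast x illumination_gain →
    additive Gaussian noise → clip to [0, 1].  Deterministic for a fixed
    seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    labels = section_label_map(params)
    achieved_mum = _add_mummification(labels, params, rng)

    palette = np.array([
        params.background_level,
        params.pericarp_level,
        params.cotyledon_level_healthy,
        params.pericarp_level,       # the dividing edge shares pericarp colour
        params.mummification_level,
    ], dtype=np.float64)
    img = palette[labels]

    scale = np.asarray(params.colour_cast, dtype=np.float64) * params.illumination_gain
    img = img * scale
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    scene = RawScene(
        pixels=img,
        bit_depth=params.bit_depth,
        patch_region=(0, 0, params.patch_size, params.patch_size),
        sequence_id=0,
    )
    truth = GroundTruth(
        germinating=achieved_mum <= 0.05,
        circle_centre=params.circle_centre,
        circle_radius=params.circle_radius,
        mummification_fraction=achieved_mum,
        illumination_gain=params.illumination_gain,
        colour_cast=tuple(params.colour_cast),
    )
    return scene, truth


# ---------------------------------------------------------------------------
# illumination drift profiles (gain as a function of 1-based sequence index)

def constant_profile(gain: float = 1.0) -> Callable[[int], float]:
    return lambda i: gain


def step_profile(switch_index: int, before: float = 0.55,
                 after: float = 0.95) -> Callable[[int], float]:
    """Brightness jumps at ``switch_index`` — the corrective gain curve of a
    normaliser then shows a falling slope at that index."""
    return lambda i: before if i < switch_index else after


def ramp_profile(n: int, start: float = 0.5,
                 stop: float = 1.0) -> Callable[[int], float]:
    return lambda i: start + (stop - start) * (i - 1) / max(n - 1, 1)


DRIFT_PROFILES = {"constant": "constant", "step": "step", "ramp": "ramp"}


def named_profile(name: str, n: int) -> Callable[[int], float]:
    if name == "constant":
        return constant_profile()
    if name == "step":
        return step_profile(n // 2 + 1)
    if name == "ramp":
        return ramp_profile(n)
    raise ConfigurationError(f"unknown drift profile {name!r}")


@dataclass(frozen=True)
class DatasetParams:
    """Class-conditional ranges used when sampling a labelled sequence.

    Non-germinating seeds draw a mummified cover of at least
    ``mummification_floor`` of the section; germinating seeds at most
    ``mummification_ceiling`` (binary labels collapse partly-spoiled into
    non-germinating).  Geometry jitter keeps every circle inside the frame
    and clear of the reference patch.
    """

    mummification_floor: float = 0.30
    mummification_ceiling: float = 0.05
    cast_jitter: tuple[float, float] = (0.92, 1.08)
    centre_jitter_frac: float = 0.10     # +/- fraction of base radius
    radius_jitter: tuple[float, float] = (0.87, 1.07)
    arc_divider_prob: float = 0.15


def generate_dataset(
    n: int,
    fraction_germinating: float = 183.0 / 400.0,
    drift_profile: Callable[[int], float] | str = "step",
    seed: int = 0,
    base_params: SceneParams | None = None,
    dataset_params: DatasetParams | None = None,
) -> tuple[list[tuple[RawScene, GroundTruth]], pd.DataFrame]:
    """Generate a labelled acquisition sequence with illumination drift.

    Returns the scenes (sequence_ids 1..n) and a manifest table with one
    row per scene.  Class counts are ``round(n * fraction_germinating)``
    germinating, remainder non-germinating; class positions are a seeded
    permutation of the sequence.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not 0.0 <= fraction_germinating <= 1.0:
        raise ConfigurationError("fraction_germinating must lie in [0, 1]")
    base = base_params or SceneParams()
    dp = dataset_params or DatasetParams()
    profile = (named_profile(drift_profile, n)
               if isinstance(drift_profile, str) else drift_profile)

    rng = np.random.default_rng(seed)
    n_pos = int(round(n * fraction_germinating))
    flags = np.zeros(n, dtype=bool)
    flags[:n_pos] = True
    rng.shuffle(flags)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n)

    out: list[tuple[RawScene, GroundTruth]] = []
    rows = []
    for i in range(n):
        sid = i + 1
        germ = bool(flags[i])
        # the 0.8 margin absorbs blob-overshoot so achieved cover of a
        # germinating scene never crosses the healthy ceiling
        mum = (rng.uniform(0.0, 0.8 * dp.mummification_ceiling) if germ
               else rng.uniform(dp.mummification_floor, 0.60))
        cast = tuple(rng.uniform(*dp.cast_jitter, size=3))
        gain = float(profile(sid))
        jitter = dp.centre_jitter_frac * base.circle_radius
        params = replace(
            base,
            circle_centre=(base.circle_centre[0] + rng.uniform(-jitter, jitter),
                           base.circle_centre[1] + rng.uniform(-jitter, jitter)),
            circle_radius=base.circle_radius * rng.uniform(*dp.radius_jitter),
            divider_arc=bool(rng.uniform() < dp.arc_divider_prob),
            mummification_fraction=mum,
            colour_cast=cast,
            illumination_gain=gain,
            seed=int(scene_seeds[i]),
        )
        scene, truth = generate_scene(params)
        scene.sequence_id = sid
        out.append((scene, truth))
        rows.append({
            "sequence_id": sid,
            "filename": f"scene_{sid:04d}.tif" if base.bit_depth != 8 else f"scene_{sid:04d}.png",
            "germinating": int(truth.germinating),
            "circle_x": params.circle_centre[0],
            "circle_y": params.circle_centre[1],
            "radius": params.circle_radius,
            "gain": gain,
            "cast_r": cast[0],
            "cast_g": cast[1],
            "cast_b": cast[2],
            "mummification_fraction": truth.mummification_fraction,
        })
    manifest = pd.DataFrame(rows)
    return out, manifest


# ---------------------------------------------------------------------------
# storage

def _quantise(pixels: np.ndarray, bit_depth: int) -> np.ndarray:
    """Quantise unit-range floats to the integer raster actually stored.

    12-bit data is carried inside a 16-bit container (4096 levels), the
    raw-capture convention this generator emulates.
    """
    levels = 2**bit_depth - 1
    codes = np.rint(np.clip(pixels, 0.0, 1.0) * levels).astype(np.uint16)
    if bit_depth == 8:
        return codes.astype(np.uint8)
    return codes


def write_scene(scene: RawScene, path: str | Path) -> None:
    """Write a scene as 8-bit PNG/TIFF or 12/16-bit TIFF."""
    path = Path(path)
    codes = _quantise(scene.pixels, scene.bit_depth)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, codes)
    else:
        if scene.bit_depth != 8:
            raise ConfigurationError("12/16-bit scenes must be stored as TIFF")
        iio.imwrite(path, codes)


def read_scene(path: str | Path, bit_depth: int | None = None,
               patch_region: tuple[int, int, int, int] = (0, 0, 100, 100),
               sequence_id: int = 0) -> RawScene:
    """Read a stored raster back to a unit-range float scene.

    ``bit_depth`` defaults to the container depth (8 for uint8, 16 for
    uint16); pass 12 for rasters quantised to 4096 levels inside 16-bit
    TIFF.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        codes = tifffile.imread(path)
    else:
        codes = iio.imread(path)
    if bit_depth is None:
        bit_depth = 8 if codes.dtype == np.uint8 else 16
    pixels = codes.astype(np.float64) / (2**bit_depth - 1)
    return RawScene(pixels=np.clip(pixels, 0.0, 1.0), bit_depth=bit_depth,
                    patch_region=patch_region, sequence_id=sequence_id)


def write_dataset(scenes: Sequence[tuple[RawScene, GroundTruth]],
                  manifest: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write every scene plus ``manifest.csv`` to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (scene, _), fname in zip(scenes, manifest["filename"]):
        write_scene(scene, out_dir / fname)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
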