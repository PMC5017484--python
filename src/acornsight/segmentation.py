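"""Two-stage section segmentation.

Stage one finds a rectangular ROI: the grey image is thresholded
automatically (Otsu unless a fixed threshold is given), the largest dark
connected component — the acorn section on its bright holder — is taken,
and its bounding box is padded by a small margin.  Stage two runs an
edge-based circular Hough transform inside the ROI and keeps the
highest-vote circle; the resulting circular mask circumscribes the
cotyledons and the adjacent pericarp ring and its pixel count A_E is the
area used to normalise the colour averages downstream.

Detections can always be replaced by a manually supplied circle
(``override_circle``); provenance is recorded on the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.transform import hough_circle

from .errors import GeometryError, SegmentationError


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned crop window, 0-based, x rightward, y downward."""

    x: int
    y: int
    width: int
    height: int

    def validate(self, shape: tuple[int, int]) -> None:
        H, W = shape[:2]
        if self.width <= 0 or self.height <= 0:
            raise GeometryError("ROI must have positive area")
        if self.x < 0 or self.y < 0 or self.x + self.width > W or self.y + self.height > H:
            raise GeometryError("ROI must lie fully inside the image")

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.y:self.y + self.height, self.x:self.x + self.width]


@dataclass
class CircleMask:
    """Rasterised circular section mask with its pixel area A_E."""

    centre_x: float
    centre_y: float
    radius: float
    mask: np.ndarray
    area: int
    method: str = "auto"
    vote: float = float("nan")

    @classmethod
    def from_circle(cls, centre_x: float, centre_y: float, radius: float,
                    shape: tuple[int, int], method: str = "auto",
                    vote: float = float("nan")) -> "CircleMask":
        if radius <= 0:
            raise GeometryError("radius must be positive")
        H, W = shape[:2]
        if (centre_x - radius < 0 or centre_y - radius < 0
                or centre_x + radius >= W or centre_y + radius >= H):
            raise GeometryError("circle must lie inside the image")
        yy, xx = np.mgrid[0:H, 0:W]
        mask = np.hypot(xx - centre_x, yy - centre_y) <= radius
        return cls(centre_x=centre_x, centre_y=centre_y, radius=radius,
                   mask=mask, area=int(np.count_nonzero(mask)),
                   method=method, vote=vote)


def find_section_roi(grey: np.ndarray, threshold: float | None = None,
                     margin: float = 0.05) -> RectROI:
    """Bounding box (plus relative margin) of the largest dark blob.

    ``threshold`` overrides the automatic Otsu level.  Raises
    ``SegmentationError`` when no pixel falls below the threshold.
    """
    if threshold is None:
        try:
            threshold = threshold_otsu(grey)
        except ValueError as exc:          # constant image
            raise SegmentationError("no dark object: image is constant") from exc
    dark = grey < threshold
    if not dark.any():
        raise SegmentationError("no dark object below threshold")
    labels = cc_label(dark)
    regions = regionprops(labels)
    biggest = max(regions, key=lambda r: r.area)
    y0, x0, y1, x1 = biggest.bbox
    my = int(round(margin * (y1 - y0)))
    mx = int(round(margin * (x1 - x0)))
    H, W = grey.shape
    x0, y0 = max(0, x0 - mx), max(0, y0 - my)
    x1, y1 = min(W, x1 + mx), min(H, y1 + my)
    return RectROI(x=x0, y=y0, width=x1 - x0, height=y1 - y0)


def fit_circle(roi_image: np.ndarray, radius_range: tuple[int, int],
               vote_floor: float = 0.3, canny_sigma: float = 2.0,
               origin: tuple[int, int] = (0, 0),
               full_shape: tuple[int, int] | None = None) -> CircleMask:
    """Highest-vote circle from an edge-based circular Hough transform.

    Candidates must be supported by at least ``vote_floor`` of their
    perimeter (perimeter-normalised accumulator).  Among qualifying
    candidates the absolute edge support (perimeter-weighted vote) is
    maximised, so when both the outer pericarp boundary and the inner
    cotyledon ring are near-complete circles the outer one — the mask
    circumscribing cotyledons *and* adjacent pericarp — wins.  Ties are
    broken deterministically: larger radius, then smaller y, then smaller
    x.  ``origin`` maps the result back into full-image coordinates and
    ``full_shape`` (default: the ROI shape) sets the raster on which the
    mask is drawn.
    """
    rmin, rmax = radius_range
    if rmin <= 0 or rmin >= rmax:
        raise GeometryError("radius_range must be positive with min < max")
    edges = canny(roi_image, sigma=canny_sigma)
    radii = np.arange(int(rmin), int(rmax) + 1)
    acc = hough_circle(edges, radii, normalize=True)
    if float(acc.max(initial=0.0)) < vote_floor:
        raise SegmentationError(
            f"no circle with edge support >= {vote_floor:.2f} in radius range {radius_range}")
    weighted = np.where(acc >= vote_floor, acc * radii[:, None, None], -1.0)
    best = float(weighted.max())
    cand = np.argwhere(weighted == best)       # (radius_idx, y, x)
    order = np.lexsort((cand[:, 2], cand[:, 1], -cand[:, 0]))
    ri, cy, cx = cand[order[0]]
    shape = full_shape if full_shape is not None else roi_image.shape
    return CircleMask.from_circle(
        centre_x=float(cx + origin[0]), centre_y=float(cy + origin[1]),
        radius=float(radii[ri]), shape=shape, method="auto",
        vote=float(acc[ri, cy, cx]))


def detect_circle(grey: np.ndarray, radius_range: tuple[int, int],
                  threshold: float | None = None, margin: float = 0.05,
                  vote_floor: float = 0.3, canny_sigma: float = 2.0) -> CircleMask:
    """ROI clipping followed by Hough fitting, in image coordinates."""
    roi = find_section_roi(grey, threshold=threshold, margin=margin)
    return fit_circle(roi.crop(grey), radius_range, vote_floor=vote_floor,
                      canny_sigma=canny_sigma, origin=(roi.x, roi.y),
                      full_shape=grey.shape)


def override_circle(shape: tuple[int, int], centre: tuple[float, float],
                    radius: float) -> CircleMask:
    """Construct a mask from supplied parameters, bypassing detection."""
    return CircleMask.from_circle(centre_x=centre[0], centre_y=centre[1],
                                  radius=radius, shape=shape, method="manual")
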