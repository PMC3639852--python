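"""Initial brain contours and their slice-to-slice propagation.

The middle slice is initialized by a robust-threshold surrogate (Otsu floor,
largest component, hole filling, morphological closing, safety-margin
erosion) standing in for a full deformable-surface brain extractor; the
method is tolerant of crude initialization, so only the output contract
matters — a closed contour near/inside the brain. A circle variant with
0.83x the reference area is provided for robustness experiments.

Remaining slices are initialized from the adjacent slice's result,
contracted or expanded according to a simple discriminant: partition the
plane into R1 = {current slice brighter than next} and R2 = the rest; if
the current result covers R1 more than R2 the brain is receding, so the
contour is contracted, otherwise expanded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import InitializationError, EmptyContourSignal, ValidationError

_FULL_3X3 = np.ones((3, 3), dtype=bool)


def disk_structuring_element(radius: int) -> np.ndarray:
    """Euclidean disk footprint of the given pixel radius."""
    r = int(radius)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    return x**2 + y**2 <= r**2


@dataclass
class Contour:
    """A filled planar region with its pixel border.

    ``boundary`` holds the region's 8-connected border pixels (region
    pixels with at least one 8-neighbour outside the region). Ordered
    closed chains are available via :meth:`chains`.
    """

    region: np.ndarray
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=bool)
        if self.region.ndim != 2:
            raise ValidationError("contour region must be 2D")

    @property
    def boundary(self) -> np.ndarray:
        inner = ndimage.binary_erosion(self.region, structure=_FULL_3X3, border_value=1)
        return self.region & ~inner

    @property
    def area(self) -> int:
        return int(self.region.sum())

    def chains(self) -> list[np.ndarray]:
        """Ordered closed subpixel boundary chains (row, col)."""
        return measure.find_contours(self.region.astype(float), 0.5)

    def centroid(self) -> tuple[float, float]:
        idx = np.argwhere(self.region)
        if idx.size == 0:
            raise EmptyContourSignal("empty region has no centroid")
        return tuple(idx.mean(axis=0))


@dataclass
class PropagationDecision:
    """Outcome of the R1/R2 contract-or-expand discriminant."""

    direction: str  # 'contract' | 'expand'
    r1_cover: int
    r2_cover: int


def initial_contour_middle_slice(
    slice_img: np.ndarray,
    threshold_floor: float = 0.2,
    min_area: int = 50,
    close_radius: int = 2,
    margin: int = 1,
) -> Contour:
    """Estimate a closed contour near/inside the brain on one slice.

    Threshold at max(Otsu, floor), keep the largest connected component,
    fill holes, close, then erode by a small safety margin so the contour
    starts near or just inside the brain boundary.
    """
    slice_img = np.asarray(slice_img, dtype=float)
    if slice_img.ndim != 2:
        raise ValidationError("expected a 2D slice")
    try:
        thr = max(float(threshold_otsu(slice_img)), threshold_floor)
    except ValueError:  # constant image
        raise InitializationError("slice has no intensity contrast")
    fg = slice_img > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        raise InitializationError("no foreground above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        raise InitializationError(
            f"largest component has {int(sizes[best - 1])} px < min_area={min_area}"
        )
    region = labels == best
    region = ndimage.binary_fill_holes(region)
    region = ndimage.binary_closing(region, structure=disk_structuring_element(close_radius))
    region = ndimage.binary_fill_holes(region)
    if margin > 0:
        eroded = ndimage.binary_erosion(region, structure=disk_structuring_element(margin))
        if eroded.sum() >= min_area:
            region = eroded
    return Contour(region=region)


def circle_initial_contour(ref: Contour, area_ratio: float = 0.83) -> Contour:
    """A filled circle at the reference centroid with 0.83x its area.

    Used to probe sensitivity to the initial condition: the extraction
    should still succeed from this deliberately crude start.
    """
    if ref.area < 5:
        raise InitializationError(f"reference contour area {ref.area} too small")
    cy, cx = ref.centroid()
    target = area_ratio * ref.area
    radius = np.sqrt(target / np.pi)
    yy, xx = np.indices(ref.region.shape)
    region = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return Contour(region=region, slice_index=ref.slice_index)


def propagation_decision(
    current_slice: np.ndarray, next_slice: np.ndarray, resultant_mask: np.ndarray
) -> PropagationDecision:
    """Decide whether the brain shrinks or grows toward the next slice.

    R1 is the set of pixels where the current slice is strictly brighter
    than the next; the decision compares how much of the current result
    lies in R1 versus its complement. Depends only on the sign of
    ``current - next``, so it is invariant to global intensity offsets.
    Ties (including the all-empty case) break toward contraction, the
    safer error: the contour can re-expand within its neighborhood,
    whereas outward leakage is the failure mode the model exists to avoid.
    """
    current_slice = np.asarray(current_slice, dtype=float)
    next_slice = np.asarray(next_slice, dtype=float)
    mask = np.asarray(resultant_mask, dtype=bool)
    if not (current_slice.shape == next_slice.shape == mask.shape):
        raise ValidationError("slices and mask must share shape")
    r1 = current_slice > next_slice
    r1_cover = int(np.count_nonzero(mask & r1))
    r2_cover = int(np.count_nonzero(mask & ~r1))
    direction = "contract" if r1_cover >= r2_cover else "expand"
    return PropagationDecision(direction=direction, r1_cover=r1_cover, r2_cover=r2_cover)


def propagate_initial_contour(
    resultant: Contour, decision: PropagationDecision, r_prop: int = 2
) -> Contour:
    """Erode (contract) or dilate (expand) the result into the next slice's
    initial contour."""
    if r_prop < 1:
        raise ValidationError("r_prop must be >= 1")
    if resultant.area == 0:
        raise EmptyContourSignal("cannot propagate an empty contour")
    selem = disk_structuring_element(r_prop)
    if decision.direction == "contract":
        region = ndimage.binary_erosion(resultant.region, structure=selem)
    elif decision.direction == "expand":
        region = ndimage.binary_dilation(resultant.region, structure=selem)
    else:
        raise ValidationError(f"unknown direction {decision.direction!r}")
    if not region.any():
        raise EmptyContourSignal("contraction emptied the region")
    return Contour(region=region, slice_index=resultant.slice_index + 1)
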