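"""The active contour neighborhood (ACN) and its intensity statistics.

The ACN is the belt-shaped region obtained by dilating the current contour's
border with a Euclidean disk. All speed-function statistics are defined on
it: the belt mean mu and belt maximum I_m drive the data term, while the
per-pixel regional value I_r — built from windowed max/min/mean statistics —
drives the edge-stopping factor g in place of the image gradient, which is
unreliable across weak boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .initialization import Contour


@dataclass
class ACNBelt:
    """Belt mask around a contour plus its global intensity statistics."""

    belt: np.ndarray
    mu: float  # mean intensity over the belt
    i_m: float  # max intensity over the belt
    r_acn: int


@dataclass
class LocalStatsMap:
    """Windowed per-pixel statistics feeding the regional value.

    ``i_max`` is the max over an n1 x n1 window, ``i_min``/``i_mu`` the
    min/mean over an n2 x n2 window; windows are clipped at image borders.
    Even window sizes follow the scipy footprint convention
    [i - n//2, i + n//2 - 1].
    """

    i_max: np.ndarray
    i_min: np.ndarray
    i_mu: np.ndarray
    n1: int
    n2: int


def build_acn(contour: Contour, slice_img: np.ndarray, r_acn: int = 5) -> ACNBelt:
    """Dilate the contour's border pixels into a belt and take its stats.

    The dilation uses the exact Euclidean distance to the border, so every
    belt pixel is within ``r_acn`` of a boundary pixel.
    """
    if r_acn < 1:
        raise ValidationError("r_acn must be >= 1")
    boundary = contour.boundary
    if not boundary.any():
        raise ValidationError("cannot build an ACN around an empty contour")
    slice_img = np.asarray(slice_img, dtype=float)
    if slice_img.shape != boundary.shape:
        raise ValidationError("slice and contour shapes differ")
    dist = ndimage.distance_transform_edt(~boundary)
    belt = dist <= r_acn
    vals = slice_img[belt]
    return ACNBelt(belt=belt, mu=float(vals.mean()), i_m=float(vals.max()), r_acn=int(r_acn))


def local_stats(
    slice_img: np.ndarray, domain: np.ndarray | None = None, n1: int = 40, n2: int = 20
) -> LocalStatsMap:
    """Windowed max/min/mean maps over the slice.

    Statistics are computed from the full slice (tissue context beyond the
    belt matters) but are only meaningful where they will be consumed —
    normally the ACN belt passed as ``domain``. Border windows are clipped:
    the extrema use edge replication (equivalent for max/min) and the mean
    uses an exact sum/count ratio.
    """
    slice_img = np.asarray(slice_img, dtype=float)
    if not (n1 >= n2 >= 1):
        raise ValidationError(f"need n1 >= n2 >= 1, got ({n1}, {n2})")
    if domain is not None and not np.asarray(domain).any():
        raise ValidationError("empty domain")
    i_max = ndimage.maximum_filter(slice_img, size=n1, mode="nearest")
    i_min = ndimage.minimum_filter(slice_img, size=n2, mode="nearest")
    # exact clipped-window mean: windowed sum / windowed count
    s = ndimage.uniform_filter(slice_img, size=n2, mode="constant", cval=0.0)
    c = ndimage.uniform_filter(np.ones_like(slice_img), size=n2, mode="constant", cval=0.0)
    i_mu = s / c
    return LocalStatsMap(i_max=i_max, i_min=i_min, i_mu=i_mu, n1=int(n1), n2=int(n2))


def regional_value(
    i_max: np.ndarray, i_min: np.ndarray, i_mu: np.ndarray, i: np.ndarray
) -> np.ndarray:
    """Per-pixel boundary indicator I_r.

    Averages the local intensity range with the deviation from the local
    mean: zero in homogeneous regions, large near tissue boundaries. This
    replaces the gradient as the edge indicator, since weak brain/non-brain
    boundaries have little gradient while WM/GM interfaces can have a lot.
    """
    return 0.5 * ((np.asarray(i_max) - np.asarray(i_min)) + np.abs(np.asarray(i_mu) - np.asarray(i)))


def edge_stop(i_r: np.ndarray, sigma_g: float = 0.2) -> np.ndarray:
    """Edge-stopping factor g = 1 / (1 + (I_r / sigma_g)^2).

    Equals 1 in homogeneous regions and decays toward 0 where the regional
    value is large, slowing the contour at boundaries (the classical
    geodesic profile, applied to I_r rather than |grad I|).
    """
    if sigma_g <= 0:
        raise ValidationError("sigma_g must be > 0")
    x = np.asarray(i_r, dtype=float)
    return 1.0 / (1.0 + (x / sigma_g) ** 2)
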