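"""Segmentation overlap and surface-distance measures.

All measures take a predicted mask M and a ground-truth mask N of equal
shape: Dice 2|M&N|/(|M|+|N|), Jaccard |M&N|/|M|N|union, false-positive and
false-negative rates both normalized by |N| (so over-inclusion can push
FP_Rate past 1), and the directed Hausdorff distance between boundary
voxels. Counts are exact integers; only the final ratios are floats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ValidationError
from .volume_io import MaskVolume


@dataclass
class EvalReport:
    ds: float
    js: float
    fp_rate: float
    fn_rate: float
    hd: float  # directed Hausdorff M -> N, voxel units
    hd_mm: float | None = None

    def to_dict(self) -> dict:
        d = {
            "ds": self.ds,
            "js": self.js,
            "fp_rate_pct": 100.0 * self.fp_rate,
            "fn_rate_pct": 100.0 * self.fn_rate,
            "hd_vox": self.hd,
        }
        if self.hd_mm is not None:
            d["hd_mm"] = self.hd_mm
        return d


def _as_bool(m) -> np.ndarray:
    a = m.data if isinstance(m, MaskVolume) else np.asarray(m)
    return a.astype(bool)


def _check_pair(m, n):
    m, n = _as_bool(m), _as_bool(n)
    if m.shape != n.shape:
        raise ValidationError(f"shape mismatch: {m.shape} vs {n.shape}")
    return m, n


def dice(m, n) -> float:
    m, n = _check_pair(m, n)
    sm, sn = int(m.sum()), int(n.sum())
    if sm == 0 and sn == 0:
        raise ValidationError("Dice undefined for two empty masks")
    return 2.0 * int((m & n).sum()) / (sm + sn)


def jaccard(m, n) -> float:
    m, n = _check_pair(m, n)
    union = int((m | n).sum())
    if union == 0:
        raise ValidationError("Jaccard undefined for two empty masks")
    return int((m & n).sum()) / union


def fp_fn_rates(m, n) -> tuple[float, float]:
    """False positive and false negative rates, both relative to |N|."""
    m, n = _check_pair(m, n)
    sn = int(n.sum())
    if sn == 0:
        raise ValidationError("rates undefined for empty ground truth")
    inter = int((m & n).sum())
    fp = (int(m.sum()) - inter) / sn
    fn = (sn - inter) / sn
    return fp, fn


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one background face-neighbour (2D or 3D)."""
    mask = _as_bool(mask)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    inner = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~inner


def hausdorff_directed(m, n, spacing=None, boundary: bool = True) -> float:
    """Directed Hausdorff max_{a in M} min_{b in N} ||a - b||.

    Computed over boundary voxels by default, in voxel units; pass voxel
    ``spacing`` for millimetres. Asymmetric: HD(M, N) != HD(N, M) in
    general.
    """
    m, n = _check_pair(m, n)
    if not m.any() or not n.any():
        raise ValidationError("Hausdorff undefined for an empty mask")
    if boundary:
        m, n = boundary_voxels(m), boundary_voxels(n)
    pm = np.argwhere(m).astype(float)
    pn = np.argwhere(n).astype(float)
    if spacing is not None:
        s = np.asarray(spacing, dtype=float)
        pm = pm * s
        pn = pn * s
    tree = cKDTree(pn)
    dists, _ = tree.query(pm, k=1)
    return float(dists.max())


def hausdorff_symmetric(m, n, spacing=None, boundary: bool = True) -> float:
    return max(
        hausdorff_directed(m, n, spacing=spacing, boundary=boundary),
        hausdorff_directed(n, m, spacing=spacing, boundary=boundary),
    )


def evaluate(m, n, spacing=None) -> EvalReport:
    """All five measures for a predicted vs truth mask pair."""
    fp, fn = fp_fn_rates(m, n)
    hd = hausdorff_directed(m, n)
    hd_mm = hausdorff_directed(m, n, spacing=spacing) if spacing is not None else None
    return EvalReport(ds=dice(m, n), js=jaccard(m, n), fp_rate=fp, fn_rate=fn, hd=hd, hd_mm=hd_mm)
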