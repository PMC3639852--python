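"""Reading, writing and normalizing MRI volumes and binary masks.

Volumes are stored slice-axis first (slice index x rows x cols); voxel
spacing is carried in millimetres. NIfTI-1 (``.nii``/``.nii.gz``) and
Analyze 7.5 (``.hdr``/``.img``) are supported through nibabel. Working
intensities live on a robust [0, 1] scale produced by percentile rescaling,
which the speed-function statistics downstream assume.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import DegenerateInputError, DimensionalityError, FormatError, ValidationError

@dataclass
class Volume:
    """A 3D intensity grid with voxel spacing.

    Attributes
    ----------
    data : ndarray, shape (n_slices, n_rows, n_cols)
        Intensities; float for images, {0, 1} for masks.
    spacing : tuple of float
        Per-axis voxel size in mm, same axis order as ``data``.
    meta : dict
        Source-format descriptor (``format``, optionally ``path``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if any(d < 1 for d in self.data.shape):
            raise ValidationError(f"degenerate shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValidationError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class MaskVolume(Volume):
    """A binary (0/1) volume aligned with an intensity :class:`Volume`."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D mask, got {self.data.ndim} dimensions"
            )
        uniq = np.unique(self.data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValidationError(f"mask values must be 0/1, got {uniq[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")


def _format_of(path: str) -> str:
    low = path.lower()
    if low.endswith(".nii.gz") or low.endswith(".nii"):
        return "nifti1"
    if low.endswith(".hdr") or low.endswith(".img"):
        return "analyze"
    raise FormatError(f"unsupported extension on {path!r} (need .nii, .nii.gz or .hdr/.img)")


def read_volume(path: str, as_mask: bool = False) -> Volume:
    """Read a NIfTI-1 or Analyze 7.5 volume from *path*.

    Intensities are returned on their native scale. Set ``as_mask`` to get
    a :class:`MaskVolume` (values validated as 0/1).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _format_of(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error variety
        raise FormatError(f"could not parse {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise DimensionalityError(f"{path!r} is {data.ndim}-D after squeeze, expected 3-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = {"format": fmt, "path": path}
    cls = MaskVolume if as_mask else Volume
    return cls(data=data, spacing=spacing, meta=meta)


def write_volume(vol: Volume, path: str) -> None:
    """Write *vol* to *path*; the format follows the extension.

    Masks are written as unsigned 8-bit; intensity volumes keep their dtype
    (floats are written as float32).
    """
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    fmt = _format_of(path)
    data = vol.data
    if isinstance(vol, MaskVolume):
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    affine = np.diag(list(vol.spacing) + [1.0])
    if fmt == "nifti1":
        img = nib.Nifti1Image(data, affine)
    else:
        img = nib.AnalyzeImage(data, affine)
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, path)
    except (OSError, PermissionError) as exc:
        raise IOError(f"cannot write {path!r}: {exc}") from exc


def normalize_intensity(vol: Volume, p_low: float = 2.0, p_high: float = 98.0) -> Volume:
    """Rescale intensities robustly onto [0, 1].

    Intensities are clipped at the ``p_low``/``p_high`` percentiles and
    linearly mapped so the clip points land on 0 and 1. Rank order among
    non-clipped voxels is preserved, and the operation is idempotent up to
    clipping.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValidationError(f"need 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})")
    data = vol.data.astype(np.float64)
    lo = np.percentile(data, p_low, method="lower")
    hi = np.percentile(data, p_high, method="higher")
    if hi <= lo:
        # percentiles collapsed (e.g. constant or near-constant volume)
        lo, hi = float(data.min()), float(data.max())
        if hi <= lo:
            raise DegenerateInputError("constant-intensity volume cannot be normalized")
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return Volume(data=out, spacing=vol.spacing, meta={**vol.meta, "normalized": True})
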