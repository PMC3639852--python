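"""Whole-volume brain extraction: middle-slice start, bidirectional
slice-by-slice propagation, 3D mask assembly.

The middle slice is segmented from a fresh initial contour; every other
slice inherits its initial contour from the adjacent slice's result,
contracted or expanded by the R1/R2 discriminant. The two directions are
independent and each stops when the contour empties, the area falls below
``min_brain_area``, or the belt statistics degenerate (no brain left).
Slices are otherwise processed independently; no 3D regularization is
applied across slices.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field as dc_field

import numpy as np

from .errors import (
    DegenerateACNError,
    EmptyContourSignal,
    ExtractionError,
    InitializationError,
)
from .initialization import (
    Contour,
    circle_initial_contour,
    initial_contour_middle_slice,
    propagate_initial_contour,
    propagation_decision,
)
from .levelset_core import SpeedParams, run_acnm_slice
from .volume_io import MaskVolume, Volume, normalize_intensity


@dataclass
class RunConfig:
    """Complete effective configuration of an extraction run."""

    speed: SpeedParams = dc_field(default_factory=SpeedParams)
    r_acn: int = 5
    r_prop: int = 2
    n1: int = 40
    n2: int = 20
    sigma_g: float = 0.2
    initializer: str = "surrogate"  # 'surrogate' | 'circle'
    min_brain_area: int = 50
    p_low: float = 2.0
    p_high: float = 98.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        speed = d.pop("speed", {})
        if isinstance(speed, dict):
            speed = SpeedParams(**speed)
        return cls(speed=speed, **d)


@dataclass
class SliceLog:
    slice_index: int
    decision: str  # 'middle' | 'contract' | 'expand' | 'empty'
    r1_cover: int
    r2_cover: int
    outer_iterations: int
    area: int


@dataclass
class ExtractionRun:
    """Result bundle: configuration, per-slice log, assembled mask."""

    config: RunConfig
    mask: MaskVolume
    slice_logs: list = dc_field(default_factory=list)
    elapsed_s: float = 0.0


def _segment_slice(img2d, init, cfg: RunConfig) -> Contour:
    return run_acnm_slice(
        img2d,
        init,
        params=cfg.speed,
        r_acn=cfg.r_acn,
        n1=cfg.n1,
        n2=cfg.n2,
        sigma_g=cfg.sigma_g,
    )


def run_acnm_volume(vol: Volume, config: RunConfig | None = None) -> ExtractionRun:
    """Extract the brain from a whole volume.

    The input is normalized to [0, 1] if its intensities are not already in
    that range. Returns an :class:`ExtractionRun`; the binary mask is its
    ``mask`` attribute.
    """
    cfg = config or RunConfig()
    cfg.speed.validate()
    t0 = time.time()
    data = vol.data
    if data.min() < 0 or data.max() > 1:
        vol = normalize_intensity(vol, cfg.p_low, cfg.p_high)
        data = vol.data
    data = data.astype(float)
    nz = data.shape[0]
    mid = nz // 2

    try:
        seed_contour = initial_contour_middle_slice(data[mid])
        if cfg.initializer == "circle":
            seed_contour = circle_initial_contour(seed_contour)
        middle = _segment_slice(data[mid], seed_contour, cfg)
    except (InitializationError, EmptyContourSignal, DegenerateACNError) as exc:
        raise ExtractionError(f"middle-slice (index {mid}) initialization failed: {exc}") from exc

    mask = np.zeros(data.shape, dtype=np.uint8)
    mask[mid] = middle.region
    logs = {mid: SliceLog(mid, "middle", 0, 0, 0, middle.area)}

    for step in (+1, -1):  # ascending then descending, both from the middle
        prev = middle
        z = mid
        while 0 <= z + step < nz:
            z_next = z + step
            decision = propagation_decision(data[z], data[z_next], prev.region)
            try:
                init = propagate_initial_contour(prev, decision, r_prop=cfg.r_prop)
                result = _segment_slice(data[z_next], init, cfg)
            except (EmptyContourSignal, DegenerateACNError):
                break
            if result.area < cfg.min_brain_area:
                break
            mask[z_next] = result.region
            logs[z_next] = SliceLog(
                z_next, decision.direction, decision.r1_cover, decision.r2_cover, 0, result.area
            )
            prev = result
            z = z_next

    run = ExtractionRun(
        config=cfg,
        mask=MaskVolume(data=mask, spacing=vol.spacing, meta={"format": "mask"}),
        slice_logs=[logs[k] if k in logs else SliceLog(k, "empty", 0, 0, 0, 0) for k in range(nz)],
        elapsed_s=time.time() - t0,
    )
    return run


def extract_brain(vol: Volume, config: RunConfig | None = None) -> MaskVolume:
    """Convenience wrapper returning only the binary brain mask."""
    return run_acnm_volume(vol, config).mask


def summarize_run(run: ExtractionRun) -> dict:
    """Machine-readable summary: full configuration + per-slice log."""
    return {
        "config": run.config.to_dict(),
        "elapsed_s": run.elapsed_s,
        "n_slices": int(run.mask.data.shape[0]),
        "total_voxels": int(run.mask.data.sum()),
        "slices": [
            {
                "slice": log.slice_index,
                "decision": log.decision,
                "r1_cover": log.r1_cover,
                "r2_cover": log.r2_cover,
                "area": log.area,
            }
            for log in run.slice_logs
        ],
    }
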