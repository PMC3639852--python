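"""Synthetic T1-like head phantoms with voxel-exact ground truth.

The phantom mimics the contrast ordering of a T1-weighted head scan:
bright white matter, mid gray matter, dark CSF and background, a scalp
ring separated from the brain by a dark CSF/skull gap, and (optionally) a
bright eyeball connected to the brain through a low-contrast bridge — the
weak-boundary configuration through which intensity-driven contours leak.
Brain cross-sections are ellipses whose radius is modulated by a smooth
sinusoidal "gyri" perturbation and which shrink toward the first/last
slices, so per-slice truth areas are unimodal along the slice axis.

Not modeled: partial-volume effects, anatomically realistic tissue maps,
Rician noise. See the methods note for what this does and does not
exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .volume_io import MaskVolume, Volume

#: default tissue palette on the normalized [0, 1] scale (T1 ordering)
DEFAULT_INTENSITIES = {
    "background": 0.05,
    "csf": 0.15,
    "gm": 0.45,
    "wm": 0.75,
    "scalp": 0.55,
    "eye": 0.95,
    "gap": 0.40,  # weak-boundary bridge between brain and eye
}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head.

    ``gyri_amplitude`` is the fractional radius modulation of the brain
    boundary (``r(theta) = r0 * (1 + a * sin(k * theta))``); ``bias_amplitude``
    scales a separable low-order cosine field applied multiplicatively;
    ``noise_sd`` is the additive Gaussian sigma on the [0, 1] scale.
    """

    shape: tuple[int, int, int] = (96, 128, 128)
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    gyri_amplitude: float = 0.07
    gyri_frequency: int = 9
    eye: bool = True
    noise_sd: float = 0.02
    bias_amplitude: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(d < 32 for d in self.shape):
            raise ValidationError(f"each dimension must be >= 32, got {self.shape}")
        for name, v in self.intensities.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"intensity {name}={v} outside [0, 1]")
        it = self.intensities
        if it["eye"] <= it["wm"]:
            raise ValidationError("eye intensity must exceed white matter")
        if it["csf"] >= it["gm"]:
            raise ValidationError("CSF intensity must be below gray matter")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.gyri_amplitude < 0.5):
            raise ValidationError("gyri_amplitude must be in [0, 0.5)")


#: tissue label codes in :attr:`PhantomResult.labels`
LABELS = {
    "background": 0, "csf_gap": 1, "scalp": 2, "gm": 3, "wm": 4,
    "ventricle": 5, "eye": 6, "bridge": 7,
}


@dataclass
class PhantomResult:
    volume: Volume
    truth: MaskVolume
    slice_areas: np.ndarray  # per-slice truth voxel counts
    labels: np.ndarray | None = None  # per-voxel tissue code (see LABELS)


def _brain_semiaxis_profile(nz: int) -> tuple[np.ndarray, float]:
    """Relative in-plane brain scale per slice: elliptical along z."""
    zc = (nz - 1) / 2.0
    cz = 0.44 * nz
    z = np.arange(nz)
    f = 1.0 - ((z - zc) / cz) ** 2
    return np.sqrt(np.clip(f, 0.0, None)), zc


def generate_head_phantom(spec: PhantomSpec | None = None) -> PhantomResult:
    """Build the phantom volume, its ground-truth brain mask and areas.

    Deterministic given ``spec.seed``. The truth mask covers white matter,
    gray matter and interior CSF (ventricles); scalp, skull gap, eye,
    bridge and background are excluded.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    nz, nr, nc = spec.shape
    it = spec.intensities
    rng = np.random.default_rng(spec.seed)

    rc, cc = (nr - 1) / 2.0, (nc - 1) / 2.0
    ar0, ac0 = 0.33 * nr, 0.30 * nc  # base brain semi-axes (rows, cols)
    fz, zc = _brain_semiaxis_profile(nz)

    rows = np.arange(nr)[:, None] - rc
    cols = np.arange(nc)[None, :] - cc
    theta = np.arctan2(rows, cols + np.zeros_like(rows))
    gyri = 1.0 + spec.gyri_amplitude * np.sin(spec.gyri_frequency * theta)

    vol = np.full(spec.shape, it["background"], dtype=np.float64)
    truth = np.zeros(spec.shape, dtype=np.uint8)
    labels = np.zeros(spec.shape, dtype=np.uint8)

    # eye geometry (voxel units), placed off-middle on the shrinking side
    eye_r = 7.0
    bridge_len = 10.0
    z_eye = int(round(zc + 0.18 * nz))

    for z in range(nz):
        f = fz[z]
        if f <= 0.05:
            continue
        ar, ac = ar0 * f, ac0 * f
        rho = np.sqrt((rows / ar) ** 2 + (cols / ac) ** 2)
        rho_b = gyri  # perturbed brain boundary in normalized radius
        sl = np.full((nr, nc), it["background"])

        # dark CSF + skull-bone band (both dark on T1, ~7 mm together)
        # and the bright scalp ring outside it
        gap_w, scalp_w = 0.20, 0.12
        lab = np.zeros((nr, nc), dtype=np.uint8)
        in_gap = (rho >= rho_b) & (rho < rho_b + gap_w)
        in_scalp = (rho >= rho_b + gap_w) & (rho < rho_b + gap_w + scalp_w)
        sl[in_gap] = it["csf"]
        sl[in_scalp] = it["scalp"]
        lab[in_gap] = LABELS["csf_gap"]
        lab[in_scalp] = LABELS["scalp"]

        # eye + weak-boundary bridge (drawn before brain so brain wins ties);
        # the eye sits past the skull gap along +cols where the gyri term is 0
        if spec.eye and abs(z - z_eye) <= eye_r:
            rb_pix = ac0 * fz[z_eye]  # brain boundary at theta=0 on the eye slice
            ez_r = np.sqrt(max(eye_r**2 - (z - z_eye) ** 2, 0.0))
            eye_col = rb_pix + bridge_len + eye_r  # offset from plane center
            de = np.sqrt(rows**2 + (cols - eye_col) ** 2)
            if abs(z - z_eye) <= 2:
                bridge = (
                    (np.abs(rows[:, 0]) <= 1.5)[:, None]
                    & (cols[0] >= rb_pix - 1.0)[None, :]
                    & (cols[0] <= eye_col)[None, :]
                )
                sl[bridge] = it["gap"]
                lab[bridge] = LABELS["bridge"]
            sl[de <= ez_r] = it["eye"]
            lab[de <= ez_r] = LABELS["eye"]

        # brain: thick cortical GM rim (standing in for folded cortex plus
        # sulcal CSF), WM core, ventricular CSF — all inside the truth mask
        brain = rho < rho_b
        gm_rim = brain & (rho >= 0.74 * rho_b)
        wm_core = brain & (rho < 0.74 * rho_b)
        sl[gm_rim] = it["gm"]
        sl[wm_core] = it["wm"]
        lab[gm_rim] = LABELS["gm"]
        lab[wm_core] = LABELS["wm"]
        if f > 0.55:
            vent = ((rows + 0.12 * ar) / (0.16 * ar)) ** 2 + (cols / (0.10 * ac)) ** 2 < 1.0
            sl[brain & vent] = it["csf"]
            lab[brain & vent] = LABELS["ventricle"]

        vol[z] = sl
        truth[z] = brain.astype(np.uint8)
        labels[z] = lab

    if spec.bias_amplitude > 0:
        zz = np.cos(np.pi * np.arange(nz) / max(nz - 1, 1))
        rr = np.cos(np.pi * np.arange(nr) / max(nr - 1, 1))
        ccs = np.cos(np.pi * np.arange(nc) / max(nc - 1, 1))
        bias = 1.0 + spec.bias_amplitude * (
            zz[:, None, None] * rr[None, :, None] * ccs[None, None, :]
        )
        vol *= bias
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    np.clip(vol, 0.0, 1.0, out=vol)

    areas = truth.reshape(nz, -1).sum(axis=1).astype(np.int64)
    volume = Volume(data=vol, spacing=(1.5, 1.0, 1.0), meta={"format": "phantom"})
    mask = MaskVolume(data=truth, spacing=volume.spacing, meta={"format": "phantom"})
    return PhantomResult(volume=volume, truth=mask, slice_areas=areas, labels=labels)


@dataclass
class SlicePair:
    """Two adjacent slices plus the current slice's resultant mask."""

    current: np.ndarray
    next: np.ndarray
    resultant_mask: np.ndarray
    current_area: int
    next_area: int


def slice_pair_fixture(kind: str, seed: int = 0) -> SlicePair:
    """Adjacent phantom slices where the brain strictly shrinks or grows.

    ``kind='shrinking'`` returns a pair where the next slice's brain area is
    strictly smaller than the current one's; ``'growing'`` the reverse. The
    resultant mask is the current slice's truth, playing the role of a
    completed segmentation.
    """
    if kind not in ("shrinking", "growing"):
        raise ValidationError(f"kind must be 'shrinking' or 'growing', got {kind!r}")
    spec = PhantomSpec(shape=(64, 96, 96), eye=False, seed=seed)
    res = generate_head_phantom(spec)
    nz = spec.shape[0]
    z0 = int(round((nz - 1) / 2 + 0.28 * nz))  # steep part of the area profile
    if kind == "shrinking":
        cur, nxt = z0, z0 + 1
    else:
        cur, nxt = z0 + 1, z0
    return SlicePair(
        current=res.volume.data[cur],
        next=res.volume.data[nxt],
        resultant_mask=res.truth.data[cur].astype(bool),
        current_area=int(res.slice_areas[cur]),
        next_area=int(res.slice_areas[nxt]),
    )
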