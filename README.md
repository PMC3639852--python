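# acnm — brain extraction with a hybrid level set active contour neighborhood model

`acnm` segments brain tissue (skull stripping) from 3D T1-weighted MRI
volumes. It is aimed at neuroimaging researchers who need an automatic,
parameter-light brain extraction step and at methods developers who want a
compact, fully tested reference implementation of belt-confined level-set
segmentation.

## The method

The brain boundary on each slice is the zero set of a level-set field
φ (positive inside) evolved under a speed law with a data term and an
edge-stopped smoothing term:

    φ_t = D(I) |∇φ| + β div( g(I_r) ∇φ / |∇φ| ) |∇φ|

Evolution is confined to the **active contour neighborhood (ACN)** — the
belt obtained by dilating the current contour — and the contour and belt
are replaced iteratively until they agree. The belt supplies two global
statistics, its mean μ and maximum I_m, that shape the nonlinear
piecewise data term (r = |I−μ| / ((I_m−μ) t)):

    D(I) = −exp(−r)                                          if I < μ
    D(I) =  exp(−r) − exp(−(2(I_m−μ) − |I−μ|)/((I_m−μ) t))   if I ≥ μ

so the contour expands over intensities in (μ, I_m) and contracts over
darker tissue and — crucially — over anything *brighter than the belt
maximum*, such as an eyeball across a weak boundary; D(I_m) = 0 exactly.
The speed parameter t trades contraction speed against expansion speed.
The smoothing term is stopped not by the image gradient but by the
**regional value** I_r, a windowed boundary indicator
(I_r = ((I_max − I_min) + |I_μ − I|)/2 over N₁=40 / N₂=20 windows),
which stays large at weak, low-gradient boundaries.

A whole volume is segmented slice by slice from the middle outward: each
slice's initial contour is the previous slice's result, contracted or
expanded according to a simple discriminant (does the result cover more of
the region where the current slice is brighter than the next, or less?).
The fixed-parameter protocol is β = 1.2, t = 6.

The package ships a synthetic T1-like head phantom (tissue palette,
gyri-perturbed boundary, bias field, noise, optional weak-boundary
eyeball) with voxel-exact ground truth, plus the standard evaluation
metrics (Dice, Jaccard, FP/FN rates, directed Hausdorff).

## Worked example

```python
from acnm import PhantomSpec, generate_head_phantom, run_acnm_volume, evaluate

phantom = generate_head_phantom(PhantomSpec(seed=0))      # 96x128x128 T1-like head
run = run_acnm_volume(phantom.volume)                     # beta=1.2, t=6 defaults
report = evaluate(run.mask, phantom.truth, spacing=phantom.volume.spacing)
for k, v in report.to_dict().items():
    print(f"{k:16s} {v:.4f}")
```

prints

```
ds               0.9983
js               0.9967
fp_rate_pct      0.0160
fn_rate_pct      0.3177
hd_vox           4.5826
hd_mm            4.7170
```

i.e. the extracted mask overlaps the phantom's ground truth at Dice 0.998,
adds 0.016 % spurious voxels, misses 0.32 % of brain voxels, and its
farthest boundary voxel lies 4.6 voxels (4.7 mm) from the true surface.

The same pipeline is available from a shell:

```sh
acnm phantom --size 96 128 128 --seed 0 -o head        # writes head_t1.nii.gz + head_truth.nii.gz
acnm strip head_t1.nii.gz -o head_mask.nii.gz          # extraction + head_mask_summary.json
acnm eval head_mask.nii.gz head_truth.nii.gz --mm      # JSON metric report
```

`strip` accepts `--beta`, `--t`, `--r-acn`, `--initializer surrogate|circle`
and a YAML config; every run writes a summary JSON with the complete
effective configuration and a per-slice decision log.

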