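# Methods

## Model

Brain extraction is posed as a per-slice active contour problem. The
contour is the zero set of a scalar field φ, **positive inside** the brain
region, evolved by

    φ_t = D(I) |∇φ| + β ( g κ |∇φ| + ∇g · ∇φ )

where κ is the contour curvature and the right-hand bracket is the
geodesic expansion of div(g ∇φ/|∇φ|)·|∇φ|. The multiplication of the
data term by |∇φ| is exact under the signed-distance assumption |∇φ| = 1
and keeps the update well-scaled when the field drifts from it between
reinitializations.

Evolution is confined to the **active contour neighborhood (ACN)**: the
belt obtained by dilating the current contour's 8-connected border with a
Euclidean disk of radius `r_acn`. Each outer iteration (i) rebuilds the
belt around the current contour, (ii) recomputes the belt statistics
μ = mean, I_m = max and the per-pixel edge map, (iii) evolves φ inside the
belt until the front stalls, and (iv) extracts the new contour
(φ ≥ 0, components ≥ `min_area` kept, holes filled). Outer iterations
stop when successive contours agree to Dice ≥ `converge_tol` (0.999) or
after `outer_max` (10) rounds. μ and I_m are deliberately recomputed every
outer iteration — they are belt statistics and the belt moves.

### Data terms

The nonlinear piecewise speed expands over (μ, I_m) and contracts outside,
with the analytically forced zero D(I_m) = 0; intensities above the belt
maximum (eyeball, bright artifacts across weak boundaries) therefore
drive contraction, which is the model's leakage-elimination mechanism.
The function is discontinuous at I = μ (left limit −1, right limit
1 − e^(−2/t)); the discontinuity is preserved as designed, not smoothed.
The speed parameter t (default 6) monotonically speeds contraction and
slows expansion; β (default 1.2) weights the smoothing term. These two
are the only parameters a user normally touches.

A linear window baseline D(I) = ε − |I − T| (defaults T = 0.6, ε = 0.4,
weighted by α = 0.75 with (1−α) curvature smoothing) is retained solely
as the comparison arm for the leakage experiments.

### Regional value and edge stop

I_r = ((I_max − I_min) + |I_μ − I|)/2, with I_max over an N₁×N₁ = 40×40
window and I_min, I_μ over N₂×N₂ = 20×20 windows, clipped at image
borders (extrema via edge replication, mean as an exact sum/count ratio;
even window sizes follow the scipy footprint convention
[i − n/2, i + n/2 − 1]). I_r is zero in homogeneous tissue and large near
boundaries regardless of gradient, so g(I_r) = 1/(1 + (I_r/σ_g)²) slows
the front at weak boundaries where |∇I| would not. σ_g defaults to 0.2,
placing g at roughly 0.2–0.4 for boundary-typical I_r ≈ 0.3–0.45 and near
1 inside homogeneous tissue; a much smaller σ_g suppresses the smoothing
term everywhere in the belt and with it the weak-boundary protection.

### 3D propagation

The middle slice (⌊n/2⌋) is initialized by a robust-threshold surrogate:
Otsu threshold floored at 0.2, largest connected component (≥ 50 px),
hole filling, morphological closing (disk radius 2), then a 1 px
safety-margin erosion so the contour starts near or just inside the
brain. A circle variant (same centroid, 0.83× the area) is provided to
probe initialization sensitivity. Every other slice inherits its initial
contour from the adjacent result, eroded or dilated by a disk of radius
`r_prop` = 2 according to the discriminant: with R1 = {current slice
brighter than next}, contract iff the result covers at least as much of
R1 as of its complement (ties contract — the contour can re-expand within
its belt, while outward leakage is the failure mode the model exists to
avoid). The two directions run independently from the middle result; a
direction stops when the contour empties, falls below `min_brain_area`
(50 px), or its belt intensity range degenerates. Slices are segmented
independently after initialization; no 3D regularization is applied.

## Numerics

- **Advection** uses first-order Godunov upwinding. With φ positive
  inside, the upwind selection must be the mirror of the textbook
  (inside-negative) formulas: for D > 0,
  |∇φ|² = min(D⁻ˣ,0)² + max(D⁺ˣ,0)² + (same in y), and vice versa for
  D < 0. The mirrored choice is monotone (discrete maximum principle);
  the unmirrored one amplifies single-pixel spikes exponentially.
- **Curvature** by central differences, clipped at the grid-resolvable
  bound |κ| ≤ 1; ∇g·∇φ by central differences.
- **Time step**: dt = 0.45 / (max|D| + 4 β max g) over the belt,
  recomputed each step, unless fixed explicitly.
- **Narrow-band clamp**: |φ| ≤ 6 inside the belt. Off-belt pixels are
  frozen, so gradients would otherwise pile up against the belt edge and
  the advection magnitude (∝|∇φ|) with them.
- **Signed distance** from a binary region via two exact Euclidean
  distance transforms, offset by 0.5 so the zero crossing sits on the
  half-pixel ring. Discrete EDT fields carry O(1) slope kinks at
  rasterization corners; band-gradient assertions are therefore stated on
  medians/quantiles for raw EDT fields and pointwise only for smooth
  fields.
- **Reinitialization** every 20 iterations by the relaxation flow
  φ_τ = S(φ₀)(1 − |∇φ|) with a smoothed sign and Godunov differencing,
  plus a subcell anchor: cells with a sign change to a 4-neighbour relax
  toward d = φ₀/max(|∇φ₀|, 0.5) instead. Without the anchor each call
  displaces the zero set a fraction of a pixel; iterated inside the ACN
  loop this produced a period-20 breathing cycle and a systematic ~1 px
  inward bite.
- **Inner stall test**: mean front displacement, estimated as boundary
  sign flips per boundary pixel, summed over a trailing 5-iteration
  window, below 0.05 px — checked only after 25 iterations, since a slow
  front needs ~25 steps before its first pixel flip. A second test stops
  equilibrium dither (period-2 flip patterns with no net motion):
  net flips against the front 20 iterations back below 0.1 px.
- Degenerate belts (I_m ≤ μ + 1e−6, e.g. a contour deep inside uniform
  tissue) raise an error rather than divide by ~0.

## Synthetic head phantom

The generator emulates the contrast structure a T1 head scan presents to
this method, not anatomy: per-slice elliptical brain cross-sections
(semi-axes 0.33/0.30 of the grid) scaled by an elliptical through-slice
profile so truth areas are unimodal; a multiplicative separable cosine
bias field (±`bias_amplitude`); additive Gaussian noise; and a palette on
[0, 1] — background 0.05, CSF 0.15, GM 0.45, scalp 0.55, WM 0.75, eye
0.95, weak-boundary bridge 0.40 — chosen to mimic T1 ordering and force
the eye above any brain intensity. The boundary is modulated by
r(θ) = r₀(1 + a sin kθ) with k = 9, a = 0.07, giving a convoluted border
the smoothing term must not erase. Two geometric choices matter to the
belt statistics and were set for fidelity to real tissue composition:
the dark CSF + skull-bone band is 0.20 of the brain radius (~7 mm; bone
is dark on T1), and the cortical GM rim is 0.26 of the brain radius — it
stands in for folded cortex plus sulcal CSF, so that a belt reaching
~7 px inward from the boundary sees mostly GM rather than pure WM, as it
would in a real head. The optional eyeball (radius 7 px) sits 10 px past
the brain boundary behind a 3 px-wide bridge of intensity 0.40 — a
corridor above typical belt means, i.e. a genuine leakage path for
intensity-window models.

Ground truth is the filled brain ellipse per slice (WM + GM +
ventricular CSF); scalp, skull gap, bridge, eye and background are
excluded, and a voxel label map records every tissue.

What passing on the phantom does *not* show: robustness to partial-volume
mixing, Rician noise statistics, anatomical asymmetry, or real
skull-base/neck structure. The phantom's contrasts are cleaner than real
scanner data, so phantom metrics overstate absolute real-data accuracy; they are
meant to verify the mechanisms (belt statistics, weak-boundary exclusion,
slice propagation), not to forecast clinical Dice. The parameters
(r_acn = 5, r_prop = 2, N₁ = 40, N₂ = 20) are in pixels and target
128–256 px slices; heads drawn on much smaller grids fall outside the
design regime (the 64×64 phantom is the smallest used in tests).

## Problem sizes used in tests

The acceptance-style end-to-end check runs the full 96×128×128 phantom
(~0.29 M truth voxels, ~30 s); module tests use 64×96×96 heads and
small synthetic fields. Metric implementations are validated against
exhaustive brute-force enumeration on random ≤ 20×20×5 masks, and the
windowed statistics against window-by-window scans on ≤ 9×9 images.

## Known limitations

- The Dice outer-convergence test can terminate at a dithering
  equilibrium, leaving the reported boundary dependent on iteration
  parity at a handful of pixels (observed effect ≲ 0.1 % of area).
- The data term's hard jump at I = μ makes behavior sensitive to where
  the belt mean lands relative to the GM intensity mode; initializations
  biased several pixels inward can place μ inside the GM noise cloud and
  under-segment. The surrogate initializer's 1 px margin and the
  r_prop = 2 propagation keep the belt roughly centered in practice.
- Directed Hausdorff is reported in voxel units by default; with
  anisotropic spacing the mm option uses physical coordinates for both
  point sets but the boundary-voxel extraction itself is lattice-based.
- No inter-slice regularization: small slice-to-slice artifacts in the
  assembled 3D mask are expected and left as is.
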