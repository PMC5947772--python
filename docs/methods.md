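# Methods

This note records the models implemented in `sweepint`, the conventions and
tunable parameters, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Geometry and conventions

* Laboratory frame: right-handed Cartesian, millimetres, sample at the
  origin.  The beam direction points source → sample; the incident wave
  vector is `s0 = ŝ0/λ` in Å⁻¹ and elastic scattering fixes `|s1| = 1/λ`.
* Pixels are 0-based with the centre of pixel `(i, j)` at continuous
  coordinate `(i+0.5, j+0.5)`; bounding boxes are half-open; image `z`
  covers rotation `[φ0 + (z−z0)Δφ, φ0 + (z−z0+1)Δφ)`.
* Rotation by φ about the goniometer axis `m̂` is right-handed; an observed
  `s1 − s0` is rotated back to the φ = 0 crystal setting with `R(−φ)`.  The
  handedness is a convention the data format does not pin down; it is fixed
  here and used consistently by prediction and mapping, so round trips are
  exact by construction.
* The B matrix uses the standard orthogonalization with the real-space
  **a** axis along lab x (via gemmi); columns of `UB = U·B` are the
  reciprocal basis vectors a*, b*, c* in Å⁻¹.
* Prediction solves `|R(φ)·UB·h + s0| = 1/λ` as `A + B cosφ + C sinφ = 0`
  per reflection — at most two crossings per 360° — and intersects the
  diffracted ray with the first panel hit (multi-panel overlap is not
  supported).  Reflections whose reciprocal-lattice point is parallel to the
  rotation axis (`|B|² + |C|² → 0`) are the blind region and are excluded.

## Synthetic rotation series

The generator renders each predicted reflection as a separable 3D Gaussian:

* detector widths: the angular width σ_D (degrees, per axis) is converted to
  pixels by the local pixel subtense, `σ_px = σ_D[rad]·r/(p·cosα)` with `r`
  the sample–pixel distance, `p` the pixel pitch and `α` the ray–normal
  incidence angle.  This treats the footprint as isotropic; the true oblique
  footprint is slightly anisotropic (≤ ~4 % at the panel edge for the
  default geometry), which the tests tolerate.
* rotation width: the rocking curve has standard deviation σ_M/|ζ| in φ
  (ζ = m̂·e₁), matching the Lorentz-factor geometry that integration assumes.
* the Gaussian is truncated at ±4σ and renormalized, so the *recorded*
  expectation of a reflection sums exactly to its true intensity; per-pixel
  values are single Poisson draws of the accumulated expectation plus a flat
  background `b` — photon statistics are exact, and output is bit-identical
  under a fixed seed.

Default study conditions: 30 Å cubic cell missettled 25° about a skew axis,
λ = 1 Å, 450×450 pixels of 0.15 mm at 120 mm, 90 images of 1°, background
1 count/pixel, log-uniform intensities over [10, 10⁵] (3–4 decades of
dynamic range, as in a typical single sweep), σ_D = 0.05°, σ_M = 0.1°.

The generator only emits *measurable* reflections: |ζ| ≥ 0.15 (outside the
blind region, where the rocking curve would smear without bound), impacts
≥ 8 px from the panel edge, and rocking curves entirely inside the scan.
Reflections failing these cuts are unintegrable for geometric reasons, so
including them would contaminate recovery statistics with failures unrelated
to the algorithms under test.

Not modelled: beam profile and divergence structure, air scatter, detector
point spread and charge sharing, per-module gaps, sample absorption, or
scan-varying crystal models.  Passing tests therefore demonstrate
correctness of the inference chain under ideal Poisson imaging, not
robustness to those instrument effects.

Artifacts available on top: single-pixel zingers (Poisson rate per image)
and azimuthally uniform powder ("ice") rings at chosen d-spacings.

## Spot finding

Three sequential tests on each valid pixel `c` with local window mean μ and
unbiased variance s² (box-filter accumulation; cost independent of kernel
size; the window includes the central pixel — excluding it shifts the
χ² threshold negligibly at N = 49):

1. `c > T` (global threshold, default 0; "discard below" is implemented as
   strictly greater);
2. `s²/μ > G·(1 + σ_b·√(2/(N−1)))` — the index-of-dispersion test, from
   `D(N−1) ~ χ²_{N−1}` whose variance is `2(N−1)`;
3. `c > μ + σ_s·√(G·μ)`.

Defaults: 7×7 window, G = 1, T = 0, σ_b = 6, σ_s = 3 — appropriate for
photon-counting detectors.  The calibration test uses a flat field at
3 counts/pixel, a representative background level; the χ² form of the null
is a large-mean result, and at very low counts the discreteness of the
Poisson distribution slightly distorts the D(N−1) distribution even though
its mean stays at G.

Strong pixels are linked by 6-connectivity in 3D (26 optional) in scan
order; spots are summarized by intensity-weighted centroids with variances
`Var_w(x)/Σc` floored at the single-pixel uniform variance 1/12 px² (and
(Δφ)²/12 in rotation).  Spots touching the panel border are rejected by
default.

## Indexing

Direction search: 16 384 golden-spiral hemisphere directions; projections of
the reciprocal-lattice points are histogrammed on a 256-point grid and a
real-space periodicity `d` appears as a power-spectrum peak at frequency
`d = k/L`.  The top local maxima per direction are pooled, duplicates merged
(< 2° as lines, |Δd|/d < 1 %), and peak frequencies refined by centre of
mass.  The hemisphere density and grid size are open choices; the defaults
resolve macromolecular cells up to ~200 Å and are CLI-overridable.

Basis selection scores candidate triples by the fraction of points indexed
within tolerance 0.3 (ties broken by smaller cell volume), requiring
pairwise angles in [20°, 160°] and a genuinely non-coplanar triple (unit
scalar triple product ≥ 0.1 — the pairwise-angle test alone cannot exclude
three coplanar lattice vectors, which index everything).  The winner is made
right-handed, Niggli-reduced (gemmi, with tracked change of basis), and the
final UB is re-fitted to the indexed points by linear least squares, with
one reassignment cycle.  Full geometric refinement then happens downstream
in a triclinic cell.

## Refinement

Residuals are observed-minus-predicted centroids (Δx, Δy in mm, Δφ in deg),
weighted by inverse centroid variances, central impacts only — no profile
information is used at this stage.  Parameters are perturbations of a
reference model: beam tilts (2), crystal orientation (3, rotation vector),
cell (6), detector shift (3) + rotation about the panel centre (3); single
rotation-vector composition makes perturbations exactly invertible.

The minimizer is a compact Levenberg–Marquardt with a central
finite-difference Jacobian (step 10⁻⁶ of each parameter's scale —
correctness over speed at this problem size), damping factor adaptation
(÷3 on acceptance, ×10 on rejection), convergence at relative cost change
< 10⁻⁶ or 50 iterations, and an accepted-step cost history so the
monotonicity of the weighted target is observable.  Zero-diagonal normal
matrix entries are reported by parameter name as null-space directions.
Between macro-cycles (up to 2) reflections with any residual beyond 4·RMSD
per component are rejected; the 4·RMSD rule is a local design choice, not a
published one.

Post-integration cell refinement fits the six cell parameters to observed
2θ angles (orientation-free: `2θ = 2 asin(λ|B·h|/2)`), with e.s.d.s from
the inverse normal matrix scaled by the residual variance and singular
directions flagged.

## Background estimation

The default estimator is a robust Poisson regression for a constant level.
A plain Huber-weighted IRLS on Pearson residuals is *not* Fisher-consistent
for Poisson data at low means (its fixed point at a true level of 0.5 is
≈ 0.42), so the score includes the consistency-correction expectation term:

    (1/n)·Σ ψ_c((c_i − μ)/√μ) − E_μ[ψ_c] = 0,   ψ_c = Huber, c = 1.345,

solved by bracketed root finding from a median start (floored at a small
positive value), ≤ 50 evaluations, tolerance 10⁻⁶, median fallback on
failure.  Because any monotone bounded score still leaves a bias
proportional to the contamination fraction (ε·c·√μ per unit score slope),
pixels more than 30 Poisson σ from the median — zinger scale, never genuine
background — are excluded outright, making the effective influence function
redescending at gross outliers.  Variance of the level: μ̂/n.

Alternatives for pedestal-subtracted CCD-like data: iterated ±3σ-rejection
mean, and an inclined-plane least-squares fit with the same rejection (both
treat a numerically constant residual as converged).

## Integration

* Profile parameters (σ_D, σ_M) are estimated from indexed strong spots:
  per-axis intensity-weighted variance of pixel-ray angular offsets about
  the centroid ray (the isotropic 2D variance halved), and of the
  ζ-scaled rotation offsets, ζ applied per spot; both averaged over spots.
  Because the threshold footprint truncates profile tails, the pixel block
  is expanded (4 px, 2 frames) beyond the strong-pixel bounding box with a
  local background subtracted and sub-noise pixels zero-weighted, and
  Sheppard's correction (pixel/frame subtense² / 12) removes the
  quantization inflation.
* Shoeboxes span ±nσ·σ_D (plus a 1-pixel margin) and ±nσ·σ_M/|ζ| in
  rotation; nσ = 3 and the 9×9×9 grid are fixed desk-scale choices.  A
  frame belongs to the foreground when its rotation *interval* overlaps the
  ±nσ·σ_M window — a centre-distance test would wrongly drop frames holding
  most of a finely peaked rocking curve.  Foreground voxels claimed by two
  predictions are masked out of both.
* Summation: `I = Σ_fg (c_i − b_i)`; variance `Σ_fg c_i + (m²/n)·b̄`
  (equivalently `I + m·b̄·(1+m/n)`, the Poisson error model of Leslie 1999);
  per-frame partial sums are retained.
* Grid transform: each foreground pixel's four corners are mapped to
  (ε₁, ε₂) and its counts distributed over grid cells in proportion to
  Sutherland–Hodgman overlap areas; the ε₃ axis uses the analytic Gaussian
  mass fraction of each frame in each grid slab (polygon clipping is a
  detector-plane construct; the rotation axis is already continuous).
  Counts are conserved exactly up to the reported mass clipped outside the
  grid; degenerate pixel polygons fall back to the nearest cell.
* Reference profiles: 3×3 positions per panel per half-overlapping image
  block (blocks start at the centre of their predecessor).  Each strong
  profile (summation I/σ ≥ 10) contributes to the references of its block
  with weight `exp(−d²/2σ_w²)`, `σ_w = Δ/(2√(2 ln 2))`, so a spot halfway
  between two references contributes exactly half its on-site weight to
  each; accumulated profiles are normalized to unit sum, and empty reference
  positions fall back to the block's mean profile.
* Profile fitting iterates `I ← Σ p(d−b)/v ÷ Σ p²/v` with Poisson variances
  `v = b + I·p` (≤ 10 iterations, ΔI/I < 10⁻⁴), variance `1/Σ p²/v`, and
  reports the Pearson correlation between `d−b` and `I·p`.  In the
  constant-variance limit this reduces to the plain least-squares ratio.

## Corrections

* Lorentz: `L = 1/|m̂·(ŝ1×ŝ0)|`; reflections with that factor below 10⁻⁶
  are flagged too close to the rotation axis to integrate.
* Polarization (Kahn convention):
  `P = [1 + cos²2θ − p′·cos2ψ·sin²2θ]/2`, `p′ = 2f−1`, with ψ the azimuth
  of ŝ1 about ŝ0 measured from `t̂ = ŝ0×n̂` — the dominant electric-vector
  direction — and `f` the fraction of intensity with E along t̂ (i.e. in the
  plane perpendicular to the polarization normal n̂, the synchrotron
  convention).  With ψ measured from n̂ instead, the sign of the p′ term
  flips; the implementation is verified against a direct two-component
  dipole-emission sum.
* Sensor absorption: `p = 1 − exp(−μ(E)·t/cosθ)`, correction `1/p`.  The
  packaged silicon table holds NIST (Hubbell & Seltzer/XCOM) total mass
  attenuation including coherent scattering, 4–30 keV, converted to linear
  attenuation at ρ = 2.33 g/cm³, interpolated log–log.  Note that p
  *increases* with obliquity (longer path), so the correction decreases.
  Corrections are stored as table columns and applied only on request,
  since downstream scaling may absorb them.

## Diagnostics

Spot counts per image (a spot counts on every frame its bounding box
touches) with qualitative flags made quantitative by local convention:
"decaying" when a least-squares linear trend falls by > 50 % start-to-end
with the slope negative at > 3σ; "blank" for runs of ≥ 5 images below 10 %
of the series median.  Both thresholds are configurable.  Reports are
deterministic given their inputs; timestamps live only in metadata.

## Problem sizes

The test suite and benchmarks run on: 500 simulated reflections for
spot-finder/indexing recovery (450² px × 90 images), 1000 reflections at
100 mm for integration fidelity, 2000 single-reflection replicates for the
weak-data comparison (I = 3 on b = 1), 200 seeds × 2000 pixels for
background bias, and 10⁵ windows for the dispersion-null calibration —
sizes chosen so the full chain demonstrates its statistical claims in a few
minutes on one core.

## Known limitations

* Single panel in practice (the detector is a list, but ray intersection
  stops at the first hit and the simulator renders panel 0 only).
* Static crystal model: no scan-varying orientation/cell, no
  post-refinement of partiality, no multi-sweep joint refinement.
* One lattice: no multi-crystal deconvolution; Bravais-lattice ranking and
  symmetry analysis are out of scope (the cell stays triclinic/Niggli).
* No parallax or thickness-dependent pixel mapping; the oblique-incidence
  correction treats the sensor as a simple absorber.
* The Huber tuning constant, outlier-rejection multipliers, grid size and
  nσ are fixed defaults, not fitted to any instrument.
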