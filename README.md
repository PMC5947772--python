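# sweepint

Desk-scale processing of rotation-method X-ray diffraction data: from raw
detector frames to background-subtracted, profile-fitted reflection
intensities, together with a synthetic image simulator that provides exact
ground truth for every stage.

## What it does, and for whom

A rotation ("sweep") diffraction experiment records a stack of area-detector
images while the crystal turns about a goniometer axis.  Turning those images
into integrated intensities `I(hkl)` requires a chain of inferences:

1. **Spot finding** — strong pixels are those incompatible with a locally
   flat Poisson background, found by thresholding the local index of
   dispersion `D = s²/μ` (for Poisson counts with detector gain `G`,
   `D ≃ G`, and `D(N−1)` is approximately `χ²` with `N−1` degrees of freedom
   for an `N`-pixel window); strong pixels are linked into 3D connected
   regions and summarized by intensity-weighted centroids.
2. **Indexing** — centroids are mapped to reciprocal space,
   `r = R(−φ)(s₁ − s₀)`, and a 1D-FFT search over hemisphere directions finds
   real-space lattice vectors as periodicities of the projected points; the
   best non-coplanar triple is Niggli-reduced into a primitive triclinic
   cell, giving the orientation matrix **UB** and Miller indices.
3. **Refinement** — a single static model (beam direction, crystal cell and
   orientation, detector position and orientation) is refined against all
   observed centroids at once by Levenberg–Marquardt minimization of the
   inverse-variance-weighted residuals in `x`, `y` (mm) and `φ` (deg).
4. **Integration** — each predicted reflection is modelled as a 3D Gaussian
   with angular widths `σ_D` (detector face) and `σ_M` (rotation) in a local
   reciprocal frame `e₁ = s₁×s₀`, `e₂ = s₁×e₁`, `e₃ = s₁+s₀` with
   `ε₃ = ζ(φ−φ_c)`, `ζ = m·e₁`.  The background under the peak is estimated
   by a robust Poisson regression that stays unbiased below one count per
   pixel; intensities come from summation (`I = Σ(c_i − b_i)`, variance after
   Leslie's Poisson error model) and from fitting each reflection's
   grid-transformed profile against empirical reference profiles
   (polygon-clipping resampling onto the `(ε₁, ε₂, ε₃)` grid), which is the
   better estimator for weak reflections.
5. **Corrections and diagnostics** — Lorentz, polarization (Kahn convention)
   and sensor-absorption (`p = 1 − exp(−μt/cosθ)`, oblique-incidence `1/p`)
   factors; spot-count-per-image crystal-health series; JSON/HTML processing
   reports.

It is aimed at people studying or prototyping integration algorithms:
everything runs in minutes on a laptop against simulated data with known
truth, and every stage is an importable, individually testable function.

## Worked example

Simulate a 60-image, 1°-per-image sweep of a 30 Å cubic crystal (180
reflections, Poisson background of 1 count/pixel), then run the full chain:

```bash
sweepint simulate  --seed 7 --output-dir sim  n_images=60 image_size=300,300 \
                   n_spots=180 intensity_min=500
sweepint find_spots sim/experiment.json sim/image_meta.json --output-dir proc
sweepint index      sim/experiment.json proc/strong.csv     --output-dir proc
sweepint refine     proc/experiment_indexed.json proc/indexed.csv --output-dir proc
sweepint integrate  proc/experiment_refined.json sim/image_meta.json \
                    proc/indexed.csv --output-dir proc dmin=4.5
sweepint report     proc/experiment_refined.json proc/integrated.csv --output-dir proc
```

which prints

```
simulate: 180 reflections on 60 images
find_spots: 180 strong spots -> proc/strong.csv
index: cell 29.993 30.000 30.004 89.998 90.000 90.009, 180/180 indexed
refine: RMSD x 0.00597 mm, y 0.00593 mm, phi 0.15935 deg over 180 reflections
integrate: 331 reflections -> proc/integrated.csv
report: 2 sections written
```

Reading the numbers: every simulated spot was found; the autoindexer
recovered the 30 Å cubic cell to ~0.02 % from the spot centroids alone and
assigned indices to all 180; after refinement the centroid residuals are
~6 µm on the detector (≪ one 150 µm pixel) and ~0.16° in φ (the quantization
floor for 1° images); integration then measures every reflection predicted
to diffract in the sweep — `proc/integrated.csv` carries `intensity_sum`,
`intensity_prf`, their variances, the profile correlation and the
Lorentz-polarization / sensor-absorption correction columns.

The stages are equally usable as a library; see
`sweepint.simulate.simulate_rotation_series`, `sweepint.spotfind.find_spots`,
`sweepint.index.index_reflections`, `sweepint.refine.refine_geometry` and
`sweepint.integrate.integrate_reflections`.

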