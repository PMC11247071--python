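# Methods

## Scope and model

The package studies how the bias and precision of SPECT-based ¹⁷⁷Lu
activity-concentration estimates depend on the number of projection angles,
the total acquisition time, and the OS-EM subset/iteration settings. All
data are synthetic: phantoms, projections and noise realizations are
generated by the package itself, which makes every number in the output
reproducible from a single seed.

### Projection formation

The forward model is a rotation-based parallel-beam projector. For each
angle the volume is rotated about the z axis into the detector frame by a
sparse bilinear-interpolation matrix, each voxel is weighted by its
attenuation survival factor `exp(−∫ μ dl)` along the ray to the detector
(ray integral discretized per voxel column with a half-voxel convention),
each constant-depth plane is blurred with a Gaussian of width
`σ(d) = sqrt(σ₀² + (b·d)²)` for source-to-collimator distance `d`, and
planes are summed and scaled by sensitivity × voxel volume. Every factor is
linear with an exact transpose, so the back projector is the exact matrix
adjoint of the forward projector; the tests verify this against a dense
matrix built column by column. Columns of the rotation matrix are
normalized to unit sum for interior voxels so that rotation conserves total
counts (plain bilinear gather loses a few percent at special angles through
lattice aliasing).

Scatter is an additive effective component: the primary projections
convolved with a broad 2-D Gaussian and scaled by `sf/(1−sf)`, so the
scatter-to-total ratio of a uniform field equals the configured scatter
fraction `sf`. The same term serves, by default, as the scatter estimate in
reconstruction (a matched, model-based compensation). This is an effective
stand-in for full model-based scatter estimation; it reproduces the
broad-and-smooth character of ¹⁷⁷Lu photopeak scatter, not its
object-specific shape.

Defaults (all configurable on `SystemModel`): pixel size 4.42 mm, orbit
radius 250 mm, σ₀ = 1.7 mm, slope b = 0.043 (≈11 mm FWHM at 100 mm —
representative of a medium-energy collimator at 208 keV), scatter fraction
0.2 with a 40 mm kernel, attenuation 0.136 cm⁻¹ (water, narrow-beam,
208 keV) inside the body support. The camera sensitivity is not given an
absolute value; a helper rescales it so that the six-sphere phantom yields a
chosen aggregate count rate (700 counts/s by default), anchoring the noise
level of all simulations.

### Phantoms

* Sphere phantom: six spheres of 0.52, 1.15, 2.72, 5.61, 11.7 and 26.9 mL
  at 5.80 MBq/mL on a 57.2 mm-radius ring inside a cold elliptical-cylinder
  body (semi-axes 135 × 98 mm, length 180 mm).
* Calibration cylinders: uniform fill (22.8 kBq/mL by default); the
  simulated geometry is radius 108 mm, length 186 mm.
* Anthropomorphic stand-in: an ellipsoidal body with ellipsoidal liver,
  spleen and kidneys and three spherical tumours (2.8, 8.9, 40.0 mL) at
  fixed, documented positions. Concentrations follow ¹⁷⁷Lu-DOTA-TATE
  values at 24 h (tumours 1.9; liver 0.14, spleen 0.51, kidneys 0.34/0.45
  MBq/mL) and 168 h (tumours 0.75; 0.040/0.12/0.051/0.068 MBq/mL). Organ
  shapes, positions and volumes are stylized choices — the study geometry
  behind those concentrations is not reproduced — and the remainder-body
  background defaults to zero with a config option for a uniform level.

Regions are voxelized volume-preservingly: voxels are ranked by fractional
overlap with the analytic shape (4× subvoxel sampling per axis) and included
greedily until adding the next voxel would overshoot the target volume by
more than the current undershoot; the mask volume is always within one voxel
of the target. Evaluation VOIs use the same rule, so phantom regions and
VOIs are consistent by construction.

### Noise realizations

Two routes produce noise realizations of shorter acquisitions:

* Time-binned bootstrap (sphere arm): the base acquisition (120 projections
  × 180 s) is simulated as independent Poisson 1-s bins per angle and pixel.
  A realization of an `N`-projection, `T`-minute acquisition keeps every
  `120/N`-th angle and, per pixel independently, sums `k = 60T/N` bins drawn
  uniformly with replacement. Bins are floats and summed without rounding.
  Pixels and angles are treated as statistically independent; `k` beyond
  twice the acquired bins triggers a warning.
* Direct Poisson sampling (anthropomorphic arm): noise-free projections are
  scaled to the acquisition time and Poisson noise is drawn per realization.

All acquisition times are virtual single-head times.

### Reconstruction

OS-EM with the classic multiplicative update per angular subset, using the
same projector (attenuation + depth-dependent blur) and the additive scatter
estimate in the denominator. Choices where the algorithm is underdetermined:

* Counts are divided by the time per projection before reconstruction, so
  images are in count-rate concentration units; this leaves the EM update
  invariant (numerator and denominator scale together).
* Initial estimate: 1 inside the attenuation support, 0 outside (uniform
  everywhere when no attenuation map is given).
* Subsets are interleaved (`i, i+S, i+2S, …`) and processed in natural
  order 0..S−1 — not bit-reversed; vendor orderings differ and the
  sensitivity of Pareto conclusions to ordering is untested.
* Denominator guard: projected values are clamped at 1e-12 of their mean;
  voxels with zero subset sensitivity are left unchanged.
* Snapshots are stored after each full iteration only.
* All-zero projection data returns a zero image with a warning rather than
  failing, mirroring how degenerate noise realizations are handled
  downstream (the CV is then undefined and the setting flagged invalid).

A single-subset scheme (plain ML-EM) is allowed as a special case for
likelihood-monotonicity checks; the scheme enumeration itself only emits
even subset counts with ≥2 angles per subset and iterations × projections
≤ 2400.

### Calibration

Noise-free cylinder projections are reconstructed with every scheme under
study and the factor `C_ref / mean VOI signal` tabulated per
(projections, subsets, iterations). The VOI is a coaxial cylinder of the
protocol volume (375 mL for the sphere arm, 1953 mL for the anthropomorphic
arm); only the volume is protocol-specified, the shape is fixed here at 60 %
of the phantom radius with the length set by the volume. Using noise-free
data mirrors a long calibration acquisition.

### Statistics

Per setting and VOI, the per-realization VOI means give
`C̄_est`, the sample SD `s` (n−1 denominator — a documented choice),
`CV = s/C̄_est` and `|C̄_est/C_ref − 1|`. Settings with `C̄_est = 0` have
undefined CV and are flagged invalid and excluded. Estimates deviating more
than 50 % from the median (or a zero median) are flagged as outliers but
retained in the summaries. Pareto fronts minimize (error, CV) jointly per
VOI and acquisition time, with non-strict domination and ties kept on the
front; the sweep-based implementation is property-tested against an O(n²)
pairwise-domination oracle. Plot inclusion requires ≥2 iterations and ≥16
updates and validity.

With 32 realizations the relative standard error of a sample SD under
normality is `1/√(2·31) = 12.7 %`, so CV values carry non-negligible
vertical uncertainty in the Pareto plots — reproduced here both in closed
form and by simulation.

## Problem sizes

The default grid is 64 × 64 × 48 voxels at 4.42 mm — the package's chosen
desk-scale working size; phantom geometry is defined in millimetres and is
grid-independent. Full protocol sweeps (all six projection counts, three
times, 32 realizations, all 1900 settings) are supported behind an explicit
`--full` flag and take hours; tests and the acceptance script run reduced
sweeps (one or two projection counts, ≤16 realizations, capped iterations)
that exercise every code path. The acceptance pipeline uses 16 realizations
of a 60-projection, 10-minute acquisition reconstructed with 2 subsets × 8
iterations.

## What passing tests do and do not show

The simulator and the reconstruction share the projection model (matched
attenuation, resolution and scatter). Results therefore isolate the
statistical behaviour of the settings — convergence bias, noise
propagation, subset effects — without model mismatch. Real acquisitions add
septal penetration, imperfect scatter models, dead time, non-circular
orbits and detector nonuniformity; a config switch can perturb the
simulation-side PSF/scatter to emulate mismatch, but the defaults do not.
Bootstrap realizations resample simulated Poisson bins, so they validate the
resampling machinery, not the non-Poisson character of corrected list-mode
data. Absolute bias values at low update numbers are dominated by
under-convergence and partial-volume effects and depend on the stylized
geometry; the qualitative trends (CV rises as time falls; few subsets favour
precision at matched updates; more updates trade bias for noise) are the
transferable results.

## Known limitations

Parallel-beam geometry with a fixed circular orbit; no septal penetration or
energy-window modelling; scatter is an effective convolution, not a physical
transport estimate; organ geometry is stylized; no partial-volume
correction, segmentation, or time-integrated activity — the endpoints are
single-time-point concentration estimates in physically sized VOIs.
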