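# Methods

This note documents the statistical model the package implements, the
defaults and why they are what they are, what the synthetic-data generator
does and does not emulate, and the numerical choices that make results
reproducible bit-for-bit.

## Design and data model

One *session* is a 4D BOLD series `(x, y, z, t)` acquired continuously at a
fixed repetition time. Acquisition indices are 1-based in every public
interface (baseline = acquisitions 1–50); ranges are half-open. The default
window scheme compares the baseline to minutes 15–25, 25–35 and 35–45
(acquisitions [150, 250), [250, 350), [350, 450) at TR 6 s). The printed
minute ranges share endpoints, so windows are taken half-open to keep the
three 100-acquisition samples disjoint — a requirement for treating the
window tests independently.

The *atlas* is a 3D integer label grid (0 = background, which doubles as
the brain mask), a region table, and named circuits as region-id sets.
Circuits may overlap, since anatomical systems share structures; region ids
are arbitrary positive integers so a subset of a larger parcellation needs
no renumbering.

## Drift model

Slow scanner drift over a ~50 min session is modelled as a single linear
trend of the whole-brain mean signal, fitted by ordinary least squares over
time in minutes (t_k = (k−1)·TR/60). The slope is expressed as percent of
the fitted intercept per minute — percent needs a reference level, and the
signal at t = 0 is the natural one. Correction happens only when
|slope| > 0.015 %/min, and is **multiplicative**: every voxel is divided by
`1 + slope·t/100`. Division, not subtraction, because the downstream
quantities are percent changes, and dividing out a gain leaves the percent
change of a superposed response exactly intact. Correction precedes
smoothing (it is defined on the raw global mean); the ordering is an
assumption — the emulated workflow does not state one. Re-estimating the
slope on a corrected session returns ~0, so the operation is idempotent.

A deliberate limitation inherited from the global strategy: when a large
region responds strongly, the global mean absorbs part of the response and
the slope estimate is biased by it. Voxel-wise detrending would avoid that
bias but absorb activation itself; the global trade-off is the one the
analysis design makes.

## Smoothing

Volume-wise 3D Gaussian smoothing, parameterised by FWHM in mm
(σ = FWHM / (2√(2 ln 2)), converted to voxel units per axis; default
0.8 mm). Boundaries are reflective so the brain rim is not darkened against
the zero background; the choice is pinned because it changes boundary
voxels and tests assert bit-stable output.

## Voxel-wise statistics

Per voxel and window: percent change of the window mean about the baseline
mean; Welch's two-sample t-test of the window acquisitions against the
baseline acquisitions (unequal variances, Welch–Satterthwaite df,
two-tailed). Voxels with zero baseline mean are undefined and excluded from
the testing family. Degenerate noiseless voxels are given the limiting
values (equal constants → t = 0, p = 1; different constants → p = 0), which
keeps fully synthetic noise-free sessions analysable.

Multiplicity is controlled per subject with the Benjamini–Hochberg step-up
procedure at q = 0.05, applied across the subject's brain voxels separately
per window. Whether the family should instead pool the three windows is
not determinable from the emulated design; per-window is implemented and
is the conservative reading for window-level independence. A voxel is
*activated* iff its adjusted p ≤ q **and** |percent change| ≥ 2 %. The
amplitude filter is applied to the magnitude so negative (deactivation)
responses are retained with their sign; reported tables use the positive
sign. The threshold, not the t-test, gates small responses: a noiseless
+1.5 % step is maximally significant yet produces zero activated voxels.

## Region and group statistics

The volume of activation (VOA) of a region is its activated-voxel count of
a given sign. Group tables compare each treatment arm to vehicle per region
and window with the tie-corrected Kruskal–Wallis test on per-subject
counts; counts are heavily tied at zero, which midranks with the standard
tie correction handle. With every observation identical the statistic is
defined as H = 0, p = 1. The p-value is taken from the chi-square reference
distribution with (groups − 1) df; this is asymptotic, and at very small
samples it deviates from the exact permutation distribution by a few
hundredths — an inherent property of the reference, documented by a test.

A published-style table prints one representative count per arm but can
only have tested per-subject distributions; the package resolves this by
printing the count from the arm's *composite map* (voxel-wise mean percent
change across subjects, retaining voxels activated in ≥ 50 % of subjects)
while the p-value always comes from the per-subject counts. Both the
retention frequency and this split are configurable. No correction across
regions is applied by default (matching the emulated tables, which apply
none); Benjamini–Hochberg across regions is available by flag.

## Circuit time courses

A circuit's series is the mean, over all voxels of its member regions, of
each voxel's percent change about its own baseline mean — so regions weigh
by voxel count, and the series of a union of disjoint regions is exactly
the voxel-weighted mean of the per-region series. Window means of these
series enter a two-way mixed-design ANOVA (treatment between-subject,
window within-subject), computed from the sums-of-squares decomposition;
the group × window interaction F uses the subject × window residual as its
error term, with df (g−1)(w−1) and (N−g)(w−1). No sphericity correction is
applied by default (three within levels); the implementation is verified
against an independent mixed-ANOVA implementation. Dunnett's many-to-one
procedure compares each treatment to vehicle within a window: with one
treatment the procedure *is* the pooled-variance two-sample t-test and is
computed in closed form; with several, the multivariate-t tail probability
of the maximum contrast statistic is evaluated numerically with a fixed
quadrature seed (the evaluation is accurate to ~1e-4, which is why the
single-contrast case is special-cased rather than integrated).

## The simulator

`generate_session` produces
`v(t) = baseline·(1 + response(t)/100 + ε(t)/100)·(1 + drift(t)/100)` on
in-brain voxels and exact zeros outside (mimicking brain-extracted data).
The drift gain is linear in minutes and multiplicative — scanner drift
scales the measured signal, and this composition is exactly what
division-based correction removes. Responses are ramp-to-plateau kernels
per (treatment, region): onset acquisition (> 50, i.e. post-baseline), ramp
duration, plateau amplitude in percent (negative allowed). A ramp rather
than a haemodynamic basis function because the analysis consumes only
window means, which the ramp parameterises transparently. Noise is
independent Gaussian per voxel and acquisition in percent units — the
simplest model consistent with the Welch assumptions.

Defaults are the emulated study conditions: 500 acquisitions at TR 6.0 s
(50 baseline), four arms of 9/10/8/9 subjects, baseline level 1000 (a.u.),
noise 1 %, drift 0. The default grid is a reduced 24×24×12 volume with
1 mm isotropic voxels for desk-scale work; `SessionConfig.paper_scale()`
gives the full 96×96×22 geometry at 0.3125×0.3125×1.0 mm. Cohort subject
seeds derive deterministically from one master seed via spawned seed
sequences, so cohorts are bit-reproducible.

Not modelled: head motion, slice-timing offsets, susceptibility distortion,
physiological (cardiac/respiratory) noise, temporal autocorrelation, and
partial-volume effects at region boundaries. Passing recovery tests
therefore demonstrate the pipeline's statistical logic under its own
assumptions, not robustness to awake-animal confounds; registration is
likewise reduced to applying a user-supplied affine (estimation is
interactive in the emulated workflow and out of scope).

## Validation studies

`phmri.validation` measures operating characteristics by simulation; the
problem sizes are the package's chosen desk-scale conditions:

- FDR calibration: 200 null subjects × 500 voxels (50 baseline + 100
  window Gaussian samples each); mean realised false discovery proportion
  (V/max(R,1)) must not exceed q + 0.02.
- Mixed-ANOVA and Dunnett type-I error: 1000 null simulations each with the
  cohort's group sizes; rejection/family-wise error at α = 0.05 expected in
  [0.03, 0.07].
- Ground-truth recovery: 20 cohorts, 9 subjects per arm, two regions at
  +4 % with 1 % noise and 0.02 %/min drift on the 24×24×12 grid, full
  per-subject pipeline, Kruskal–Wallis vs vehicle in the 25–35 min window;
  responsive regions must be flagged in ≥ 90 % of cohorts and null regions
  in ≤ 10 %.
- Threshold gating and drift recovery as described above.

## Numerical conventions

- Voxel indexing is 0-based half-open internally; acquisition indices are
  1-based at the API boundary.
- Affine resampling: rotations compose x → y → z, right-handed, about the
  volume centre; functional data default to nearest-neighbour interpolation
  (trilinear by flag) so intensities are preserved exactly; inversion
  round-off below 1e-9 is snapped so voxel-aligned transforms are exact.
- The identity transform, a zero-FWHM smoother, and a below-limit drift
  estimate all return their input unchanged, bit-exactly.
- All randomness flows from explicit integer seeds; reruns of
  simulate + analyze are byte-identical.
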