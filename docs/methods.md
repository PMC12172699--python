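# Methods

This package implements an MRI-less ("non-standard") Centiloid pipeline
for amyloid PET: spatial normalization of a PET volume to an adaptive PET
template driven by normalized mutual information (NMI), SUVr quantification
from cortical and whole-cerebellar volumes of interest (VOIs), and the full
Centiloid calibration algebra for PiB and four ^18F-labeled tracers
(florbetapir/FBP, flutemetamol/FMM, florbetaben/FBB, NAV4694/NAV).  The
whole pipeline is testable end-to-end on synthetic phantoms with known
ground truth; no clinical data ships with the package.

## The Centiloid scale and its calibration algebra

The Centiloid (CL) scale anchors PiB SUVr linearly at two cohort means:
the young-control anchor S_YC0 = 1.014 maps to 0 and the typical-AD anchor
S_AD100 = 2.088 maps to 100:

    CL = 100 (S - S_YC0) / (S_AD100 - S_YC0).

A tracer (or an alternative pipeline) is calibrated by ordinary least
squares of its SUVr against standard-pipeline PiB SUVr,
S_tracer = m·S_PiB + b; the inverse map (S_tracer − b)/m is the
PiB-equivalent SUVr, which feeds the anchor equation.  Composing the two
steps gives the direct form CL = 100 (S − offset)/divisor with
offset = b + m·S_YC0 and divisor = m·(S_AD100 − S_YC0).

The bundled registry stores the published slope/intercept pairs at their
printed 3-decimal precision.  Composing those printed inputs reproduces
most published direct-equation constants exactly at 3 decimals; six
constants (for example the PiB non-standard divisor, 0.924 × 1.074 =
0.992 vs the printed 0.993) differ by one unit in the last printed digit
because the published table was evidently computed from unrounded inputs.
The tests assert exact 3-dp agreement where it holds and ±0.001 for the
six known one-ulp cases; both values are deliberately surfaced rather than
forced.

Level-1 quality control follows the published replication ranges: a
regression of locally computed Centiloid values on the published values
must have slope in [0.98, 1.02] (inclusive), intercept in [−2, 2]
(inclusive), and R² strictly greater than 0.98.

## MRI-less spatial normalization

The normalization registers PET directly to an adaptive PET template

    A(w) = w·Aneg + (1 − w)·Apos,

a voxelwise mixture of an amyloid-negative and an amyloid-positive
template built by averaging spatially aligned scans.  The stages are:

1. **Affine (12-DOF) registration** of the subject PET to the mixed
   template A(0.5), maximizing NMI with a derivative-free direction-set
   (Powell) search over a 3-level Gaussian image pyramid (×4, ×2, ×1
   downsampling).  Parameters are translation (mm), Euler angles, log
   scales and shears, composed about the template centre; the rigid
   variant uses the first six.  The full-resolution level subsamples the
   metric with stride 2 (about 25k voxels on the test grid), which left
   recovery accuracy unchanged in ground-truth experiments (translation
   ≤0.2 mm, rotation ≤0.15°, scale ≤0.005) while cutting cost several-fold.
2. **Adaptive-weight optimization**: w maximizing NMI(target, A(w)) on
   [0, 1], initialized at 0.5.  In one dimension Powell's method reduces
   to a single line search; it is implemented as a coarse Δw = 0.01
   bracketing scan followed by bounded golden-section/parabolic refinement
   to a tolerance of 10⁻³.  The histogram's template-intensity range is
   held fixed across w (the min/max over both pure templates); with a
   per-evaluation range the objective acquires spurious wiggles as bin
   edges shift with w, which can trap a pure local search far from the
   optimum.  The weight is optimized once, after the affine stage and
   before the nonlinear stage, and is clamped to [0, 1]: the endpoints are
   the pure templates, and extrapolation would create negative template
   intensities.  If the reported optimum were ever worse than the w = 0.5
   start, the start is returned, so the achieved NMI never falls below its
   initialization.  NMI for the weight search uses the full volume (no
   head mask).
3. **Cubic-B-spline free-form deformation (FFD)** to A(w*), default 20-mm
   control-point spacing, maximizing a Parzen-window NMI minus a
   bending-energy penalty.  SUVr is then measured on the normalized image
   with template-space VOIs.

### NMI

The reported similarity is Studholme's normalized mutual information,
NMI = (H(F) + H(M))/H(F, M), from a joint histogram over the voxel
overlap; it is 1 for independent images and 2 for identical ones.  The
public `nmi()` operation uses hard binning with 64 bins over each image's
intensity range and includes zero-intensity background voxels.

### FFD details and numerical choices

The control lattice covers the fixed grid's world bounding box plus a
cubic-spline support margin; a lattice of zeros is exactly the identity.
Displacements are evaluated by treating the lattice values as B-spline
coefficients (`map_coordinates(..., order=3, prefilter=False)`), which is
the textbook FFD definition.

The FFD objective makes the moving-intensity histogram differentiable with
a cubic-B-spline Parzen window (32 bins; the moving-bin range is frozen
from the initial warp with 5% padding), and the analytic gradient is
chained through the warp to the control points with exact separable
tensor contractions.  Optimization is L-BFGS with that gradient, at most
100 iterations per stage; a result is never accepted if it scores below
the stage's starting point.

Three choices matter and were fixed by ground-truth warp-recovery
experiments on phantoms (4-mm-amplitude smooth warps on the
64×64×48 @ 3 mm grid):

- **Control-grid multi-resolution.**  The spacing is refined 4× → 2× → 1×
  the requested value (80 → 40 → 20 mm by default) alongside the image
  pyramid.  Optimizing the fine lattice directly lets the NMI ascent chase
  histogram-sharpening and smooth-drift artifacts instead of alignment;
  coarse lattices capture the bulk of the warp first.  Each finer lattice
  is initialized by ridge-regularized separable least squares on the
  coarser stage's displacement field — the ridge keeps border control
  points with little sample support near zero (a plain pseudo-inverse
  amplifies them catastrophically).
- **Bending energy normalization.**  The penalty is the *mean* squared
  second difference of the control lattice (mm² per entry), weight 0.01 by
  default.  Normalizing per entry keeps the weight meaningful across
  lattice resolutions and comparable to the O(1) NMI value; with a raw sum
  the penalty at a genuinely smooth 4-mm warp exceeds the achievable NMI
  gain and forbids the true solution.  Weight 0.01 balances warp recovery
  (0.64 mm mean residual), identity drift (0.1 voxel) and post-affine
  translation residual (0.43 mm).
- **Metric sampling.**  The full-resolution stage subsamples with stride 2,
  as in the affine stage.

Convergence criteria throughout: metric improvement below 10⁻⁵ or 100
iterations per level; non-convergence is flagged in the transform's
metadata, never silenced.  All optimizers are deterministic — identical
inputs and options give bit-identical transforms.

## VOIs and SUVr

SUVr is the weighted mean over the cortical target mask divided by the
weighted mean over the whole-cerebellum reference mask.  Mask values act
as weights, so binary masks reduce to plain means and probabilistic masks
are supported unchanged.  Voxels that fell outside the source image during
resampling are tracked in a validity mask and excluded from VOI means.
Masks are resampled with nearest-neighbour interpolation by default so
binary masks stay binary; trilinear is available for probabilistic masks.

## Synthetic phantoms

The generator emulates the statistical structure the pipeline assumes,
not PET physics.  Anatomy is a deterministic set of nested ellipsoids:
head envelope with non-brain soft tissue (intensity 0.25), cortical ribbon
(the inner 12% shell of the cerebrum, ~30% of brain volume), white-matter
core, a disjoint cerebellar blob (the reference region, intensity 1), and
an optional skull/scalp shell (intensity 1.5) that emulates the
high-skull-uptake failure mode seen with some ^18F tracers.  Cortical
intensity interpolates linearly between the anchors:
S = 1.014 + burden·(2.088 − 1.014).  White matter is 1.6 for the
high-nonspecific-binding tracer class (FBP/FMM/FBB) and 1.1 for the
PiB/NAV class; these are configuration values, not scientific claims.
Rendering applies, in order: the ground-truth deformation (affine, B-spline
FFD, or a seeded random smooth FFD with border taper), a Gaussian PSF of
8 mm FWHM by default (a typical PET resolution), and voxelwise Gaussian
noise from `numpy.random.default_rng(seed)` (PCG64).  The recorded
`true_suvr` is the analytic pre-blur compartment ratio.

Cohorts draw pre-blur PiB SUVr from Normal(1.014, 0.047²) for the negative
class and Normal(2.088, 0.209²) for the positive class.  Because the
negative distribution straddles the zero-burden point, cohort rendering
sets the cortical intensity from the sampled SUVr directly (floored at
0.1) rather than clamping the burden parameter, which would bias the
cohort mean.  For ^18F tracers the rendered SUVr follows the published
calibration line plus Normal(0, 0.06²) residuals.  Everything is a pure
function of the arguments: the same seed reproduces volumes bit-exactly.

The default grid is 64×64×48 voxels of 3 mm (a down-scaled stand-in for
the 160×160×96 @ 1.5 mm template grid, which is available as an option);
templates in the tests average 10–34 phantoms per class.  These sizes keep
the full suite and the acceptance script within a few minutes on one CPU
while leaving registration accuracy comfortably inside its tolerances.

What passing phantom tests do *not* show: robustness to real anatomy
(gyral structure, ventricles, atrophy), scanner and reconstruction
differences, motion, or attenuation/scatter effects.  The phantoms have
piecewise-constant compartments, which is in fact an adversarially
texture-poor case for NMI-driven registration; real cortical uptake
patterns give the metric more structure, not less.

## Validation statistics

Pipeline agreement uses OLS R², the regression slope (bias expressed as
(slope − 1)·100%), and the intraclass correlation ICC(A,1) — two-way
model, absolute agreement, single rater — computed from the ANOVA mean
squares (MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)) with k = 2
pipelines.  "Relative variance" summaries are ratios of Centiloid standard
deviations against the standard-pipeline PiB SD; SD ratios (not variance
ratios) are what reproduce every published table value, and the naming
discrepancy is kept visible in the documentation.  One published value
(FBP non-standard, printed 4.61) disagrees with its own printed SDs
(12.00/2.60 = 4.615 → 4.62 at 2 dp), evidently computed from unrounded
SDs; both numbers are surfaced.

## Known limitations

- Templates are PiB-derived for all tracers (tracer-specific templates are
  out of scope), matching the published pipeline's own first limitation.
- No diffeomorphism guarantee: large FFDs can fold; the bending penalty
  discourages but does not prevent this.
- The standard (MRI-based) pipeline exists here only through its published
  calibration coefficients; no MRI segmentation or normalization is
  implemented.
- Reference-region alternatives (pons, cerebellar cortex), partial-volume
  correction and longitudinal change are out of scope.
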