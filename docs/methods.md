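# Methods

This note documents the models, defaults and numerical choices behind
`orseg`, and what validation on the synthetic phantoms does and does not
establish.

## pRF model and fitting

Each cortical site is a single isotropic 2-D Gaussian receptive field in
visual-field coordinates (degrees): center (x₀, y₀), spread σ > 0.  The
neural drive is the inner product of the binary stimulus aperture with
the Gaussian on a square raster spanning [−R, +R]² (R = 10.40°, default
101 pixels per side; predictions change by < 1% RMS when the raster is
doubled, which the suite asserts).  The BOLD prediction convolves the
drive with a double-gamma HRF sampled at the TR and z-scores the result;
amplitude is recovered post hoc by least squares, so fitting reduces to
maximizing Pearson correlation.

The HRF is a difference of gamma densities with peak delay, undershoot
delay and peak:undershoot ratio free (defaults 6 s, 16 s, 6) and both
dispersions fixed at 1 s.  Fixing the dispersions keeps the sparse-burst
fit well-posed: the event-locked average of a 150-volume burst run
constrains three timing/amplitude parameters comfortably but six poorly.
A fit whose r² falls below 0.2 is flagged degenerate rather than raised,
since downstream code may still prefer the default HRF.

Fitting is two-stage. The lattice stage evaluates a polar grid of
centers (12 angles × 8 log-spaced eccentricities ≤ R) crossed with 6
log-spaced σ values in [0.2°, 5°], on data smoothed across the sheet
(FWHM 8.3 mm); ties break toward the lowest lattice index so the search
is deterministic.  The refinement stage runs Nelder–Mead on
(x₀, y₀, log σ) against the unsmoothed series, with an explicit initial
simplex (edges 0.5° in position, 0.25 in log σ) because the default
per-coordinate perturbation collapses when a coordinate starts at zero
(e.g. a lattice point on a meridian).  Because the coarse lattice can
seed the simplex in the wrong basin — typically a small-σ optimum at a
neighboring lattice angle — `fit_vertex` restarts refinement from the
top-3 lattice candidates and keeps the best, stopping early once
r ≥ 0.999.  `refine_fit` itself never returns a correlation below its
init's.  Vertices whose best r falls below 0.1 are excluded from
delineation.

## Delineation

Delineation automates what is usually drawn by hand: boundaries are
local extrema (mirror reversals) of the polar-angle profile along the
sheet axis orthogonal to iso-eccentricity lines.  The implementation
requires the regular grid sheets produced by the phantom generator —
a deliberate simplification of a folded cortical surface, validated
against synthetic ground truth only.  The polar input is the signed
hemifield elevation (0 at the horizontal meridian, ±90° at the vertical
meridians, lower field negative).  The band whose profile spans both
signs is V1; bands are labeled V2, V3 outward on both sides, V3A beyond
dorsal V3, and each extremum row is assigned to the band farther from
V1.  V1 splits into dorsal/ventral at the sign of the vertical
visual-field coordinate.  A constant map has no reversals and raises a
delineation error.  With 5° polar noise on the phantom, mislabeled
vertices stay within two rows of a true boundary (asserted).

## Diffusion and tracking

The tensor is fitted per voxel by weighted log-linear least squares with
squared-signal weights (the first-order propagation of log-domain
noise); voxels with any non-positive signal get a zero tensor.  FA of
the zero tensor is defined as 0.  The white-matter skeleton thresholds
FA at 0.7 and erodes with a 6-connected structuring element.

Tracking is bidirectional from uniformly sampled seed-ROI points in
fixed 0.2 mm steps.  The per-step direction is sampled from an axially
symmetric dispersion about the voxel's principal eigenvector:
d = normalize(κ·v + η) with η ~ N(0, I₃) and κ = κ₀ · FA, sign-aligned
with the previous step.  This projected-normal form was chosen over
rejection-sampled alternatives because it consumes a fixed three normal
draws per streamline per step, which lets all 10,000 streamlines advance
in lockstep from a single seeded generator — tractograms are
bit-identical given (seed, n_streamlines).  The trade-off is that a
run with fewer streamlines is not a prefix of a larger run.

Propagation terminates when FA at the next point falls below 0.1 (that
terminal point is kept, so streamlines genuinely end inside low-FA
cortical targets), when the point leaves the volume, when the turning
angle exceeds the curvature constraint, or at the length cap (default
200 mm, applied per directed half).  The curvature constraint is a
minimum radius of curvature of 1 mm, i.e. a maximum turning angle of
2·asin(step/2r) ≈ 11.5° per 0.2 mm step.  κ₀ defaults to 40: the sampled
per-step wander must sit well inside the curvature limit, otherwise the
curvature test terminates a constant fraction of propagations per step
and streamlines cannot traverse a bundle; at κ₀ = 40 and FA ≈ 0.85 the
probability of a sampled turn exceeding the limit is ~10⁻⁵ per step.
As κ₀ → ∞ the tracker reduces to deterministic eigenvector tracking
(asserted on a uniform field).

Coordinates are world RAS mm.  The affine maps a voxel index to the
voxel's minimum corner, so the containing voxel of a point is the floor
of its continuous index; NIfTI I/O applies the half-voxel shift to and
from the center convention.

## Rejection rules and segmentation

The four anatomical rejection heuristics are geometric predicates with
package-chosen thresholds: initial segment 5 mm, elevation 45°, wall
proximity 1 voxel with tangent within 20° of the wall plane for ≥ 50% of
points, endpoint label radius r_assign = 2 mm.  Precedence is a > b > c
> d, first match wins.  These rules replace a manual viewer-based
procedure, so they are validated only against constructed ground truth
(the labeled tractogram generator plants violations of each rule).
Termination labels are the area labels within r_assign of the cortical
endpoint (the end farther from the LGN); both Boolean schemes are pure
set predicates on those labels, and mixed terminations are excluded.

## Statistics

Visitation maps count each streamline at most once per voxel; a voxel is
visited if any point falls inside it, which with a 0.2 mm step far below
the 1 mm voxel size approximates exact segment–voxel intersection.
Segment FA/MD are unweighted means over the support.  The
repeated-measures ANOVA partitions sums of squares explicitly (subject
as blocking factor) and tests each within-subject effect against its own
effect-by-subject stratum; no sphericity correction is applied — a known
limitation.  The suite checks the partition against a brute-force loop
oracle, against statsmodels' AnovaRM, and calibrates the null factor's
type-I error at ≈ 5% over 500 simulations.  The between-subject
covariate model is out of scope.

## Phantoms: what they emulate and what they do not

The retinotopic sheet is a flat 60 × 40-vertex grid (1 mm spacing) with
the band stack V3v, V2v, V1, V2d, V3d, V3A (9/9/16/9/9/8 rows);
eccentricity runs 0.5–10° along the columns, σ = 0.25° + 0.15·ecc, and
BOLD noise defaults to sd 0.5 of the unit signal.  It emulates
mirror-reversed polar progression and the eccentricity axis, but not
cortical folding, vascular or physiological noise structure, or
volume-to-surface sampling — so passing tests show the estimator is
correct under its own forward model, not that it is robust to real fMRI
artifacts.

The OR phantom is a 40 × 50 × 40-voxel, 1 mm tensor volume (right
hemisphere, all x > 0).  Six prolate bundles (eigenvalues 1.7/0.2/0.2
× 10⁻³ mm²/s, FA ≈ 0.87) run from an LGN-analogue sphere (radius 6 mm)
to posterior cortical blocks, nested medio-laterally (V1 medial, V3
lateral) with dorsal/ventral C-shaped bows (±4 mm).  The V1 tube is
wider (radius 2.0 mm vs 1.4 mm), so V1 receives the majority of
streamlines, while the V1 target block is also the largest, so
area-normalized counts invert the ordering — both properties the
pipeline must reproduce.  Background (0.8/0.7/0.7 × 10⁻³) and
gray-matter targets (0.9/0.8/0.8 × 10⁻³) sit below the FA 0.1 stopping
threshold; the CSF ventricle analogue (3.0 × 10⁻³ isotropic) lies along
the ventral route and is partial-volume blended (weight 0.35 within
2 mm) into adjacent ventral-bundle voxels, which both elevates the
ventral segment's mean MD and leaves those voxels trackable
(FA ≈ 0.36).  No bundle reaches the V3A block, making it a true
negative control.  Typical runs retain ~6% of 10,000 seeds (seeds
landing outside tubes die immediately; edge-seeded propagations may
wander out mid-course) — stricter than the in-vivo attrition but
immaterial, since all count measures condition on retained streamlines.
Bundles are straight-ish tubes without crossing, kissing or fanning
fibers, so tracking results here say nothing about crossing-fiber
robustness.

Problem sizes used by the default suite and the acceptance script —
200 fitted vertices for noisy pRF recovery, 10,000 streamlines per
tracking run, 5–10 seeded phantom repetitions, 500 ANOVA calibration
simulations — were chosen as the smallest sizes at which the measured
quantities are stable across seeds.

## Degenerate inputs and tie-breaks

Zero-variance series, empty visitation supports, zero-area targets,
all-excluded segmentations and incomplete ANOVA designs raise typed
errors rather than returning NaNs.  Lattice ties break to the lowest
index; eigenvector signs are canonicalized (largest-magnitude component
positive) before the direction of travel disambiguates them.
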