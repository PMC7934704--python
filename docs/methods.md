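# Methods

`perfrad` implements an analysis pipeline for a chemoselection question in
advanced laryngeal/hypopharyngeal cancer: do pre-to-post induction-chemotherapy
changes in CT-derived tumor features (radiomics and CT-perfusion parameters)
predict which patients will fail to achieve one-year disease-free survival
(DFS)?  The patient images that motivated the design cannot be shared, so the
package pairs every analysis component with a synthetic generator that
reproduces the *statistical structure* the analysis assumes; every accuracy
claim in the test suite is therefore a claim about the method on that
structure, not about real tumors.

## Image model and grids

Volumes are Hounsfield-unit grids with axis order (z, y, x), physical spacing
in mm, 0-based half-open index ranges.  Two grids matter: a thin-slice
"conventional" grid (default 1.25 mm slices) on which tumors are segmented,
and a thick-slice perfusion grid (default 5 mm slices, one slice the
composite of four thin slices).  Masks move between grids by exact
footprint-coverage resampling: a target voxel becomes tumor iff at least 50%
of its physical volume is covered by source tumor voxels.  The 50% threshold
is this package's convention; it is volume-unbiased under symmetric partial
coverage.  For axis-aligned grids the coverage factorises per axis, so it is
computed exactly as a separable tensor contraction (no sampling error).

## Segmentation

Three deterministic stages, from an approximate bounding box:

1. **Preprocessing.** Gaussian smoothing (sigma 1 mm), gradient-modulated
   anisotropic diffusion (5 iterations, conductance 2 HU, time step 0.06 —
   SimpleITK's gradient filter), central-difference gradient magnitude in
   HU/mm, and a rank transform of the gradient magnitude to [0, 1] with
   average ranks for ties.  The rank transform makes every later stage
   exactly invariant to monotone intensity remappings.
2. **Initial segmentation.** The central third of the bounding box per axis
   is taken as a statistical sample of the lesion; voxels inside the box are
   kept when their raw HU lies in `[max(mu - 3*sigma, -400), mu + 3*sigma]`.
   The -400 HU floor excludes air/fat.  The sample statistics use the raw
   voxels deliberately: after smoothing the sample SD collapses and the
   interval would exclude the lesion's boundary ramp.  Dilation with a
   one-voxel-radius physical ball, hole filling, retention of the connected
   component containing the box centre, and erosion produce the initial mask.
3. **Level-set refinement.** The initial mask seeds a signed-distance
   function evolved under a geodesic active-contour flow
   `phi_t = a g kappa |grad phi| + b grad g . grad phi + c g |grad phi|`
   with edge-stopping function `g = 1 - rank-transformed gradient`
   (defaults a = 1, b = 2, c = 0, cap 300 iterations, convergence when under
   0.1% of voxels change sign per iteration).  Curvature uses
   `laplacian(phi) - (grad phi . H . grad phi)/|grad phi|^2`; advection is
   upwinded; the time step obeys the combined parabolic/advective CFL bound.
   phi is re-anchored to a signed distance every 25 iterations, but only
   after the interface has actually moved — re-anchoring an unmoved sign
   pattern would silently erase sub-voxel progress.  Because curvature flow
   moves the interface O(h^2) per step, convergence may not be declared
   before a longer quiet window (80 iterations) if no voxel has flipped yet,
   versus 30 afterwards.  A per-slice 2D pass (20 iterations) smooths the
   final contour.  Note a geometric consequence of the geodesic weighting:
   surface roughness *on* a strong image edge is preserved (g ~ 0 freezes
   the flow there); only roughness away from edges is smoothed.

## Radiomic features

Exactly 26 features, fixed and ordered (see `perfrad.features.FEATURE_NAMES`):
10 volume/size, 8 shape, 8 gray-level.  The surface is defined as the
0.5-level marching-cubes mesh of the mask mollified by a 1-voxel Gaussian;
the raw staircase mesh of a voxelised smooth body over-measures area by ~8%
at any resolution, whereas the mollified surface converges, which keeps
sphericity of fine spheres near 1 (it is capped at 1.0, its theoretical
supremum, because mollification can under-measure a perfect sphere by ~1%).
Masks too small to reach the 0.5 level (e.g. one voxel) have no surface and
all surface-dependent features are NaN.  Principal-axis lengths are
`4*sqrt(eigenvalue)` of the voxel-centre coordinate covariance.  Histogram
features (entropy in bits, energy) use fixed 25-HU bins over [-200, 300] with
clipping.  Margin gradients use only in-mask neighbours (one-sided at the
border), so all intensity features are exactly invariant to voxel edits
outside the mask.  Every feature is verified against an independently coded
brute-force implementation to 1e-9 relative.

Change features: percent change for volume (the clinical response scale),
absolute and percent change for everything else, percent being the default
classifier input.  A patient is a *responder* iff percent volume change
<= -50 (boundary inclusive).

## Perfusion features

The five deconvolution-derived maps (PS, BF, BV, MTT, Tmax) are consumed as
inputs, never computed from cine data.  Each feature is the map's mean over
the tumor ROI on the perfusion grid, missing voxels excluded, ROI voxel
counts recorded.

## Combined response index (two-loop leave-one-out + LDA)

The decision variable is a Fisher discriminant `w = S_w^{-1}(m1 - m0)` with
the intercept at the midpoint of the projected class means and a ridge
`1e-6 * trace/p` added when the pooled covariance's condition number exceeds
1e8.  Evaluation is nested: the outer loop leaves one case out; greedy
forward selection — scored by inner-leave-one-out AUC of the LDA index, ties
broken by feature name, default cap of two features — and the final fit use
only the remaining n-1 cases.  The held-out index for each case thus comes
from a model that never saw it.

Each outer fold's index is expressed in pooled within-class SD units before
pooling across folds.  This is a positive affine map per fold (fold-internal
ROC unchanged) and is necessary: pooling raw fold indices mixes fold-specific
scales, which biased the pooled held-out AUC to ~0.46 under a pure-noise
null; with the standardisation the null mean is ~0.48, and resubstitution
AUC stays far above it — the selection-bias control the nesting exists for.
"Training AUC" is reported both as resubstitution on per-case mean training
indices (default) and as the mean over folds of fold-internal resubstitution
AUC; the two are labelled in the prediction trace.

Missing feature values are never imputed; a feature with missing values is
excluded from the affected fold with a logged warning.  Meaningful operation
needs at least 4 cases in the rarer class (the nesting removes up to two).

## ROC, ICC, kappa

The binormal ROC model puts negatives at N(0,1) and positives at
N(a/b, 1/b^2) on an unobserved monotone transform of the score axis, so
TPF = Phi(a + b z_FPF) and AUC = Phi(a / sqrt(1 + b^2)).  The fit is an
ordinal-category maximum-likelihood fit: scores are reduced to categories by
truth-state run collapsing; if more than 40 categories remain (continuous
scores), the scores are re-binned at pooled-sample quantiles.  The quantile
edges are blind to class labels; binning at run boundaries (which are
label-informative locations) was measured to bias (a, b) low by ~0.2 SE.
Cutpoints are parameterised by log-increments for ordering; L-BFGS-B with
tight tolerances; standard errors from the inverse observed information
(central-difference Hessian), AUC CI by the delta method (a percentile
bootstrap is available as an option).  Perfect separation is flagged
degenerate rather than fitted.  Parameter recovery on binormal-simulated data
(n = 2000/2000) is unbiased with joint 2-SE coverage around 90%.

ICC is fixed to ICC(2,1) — two-way random effects, absolute agreement,
single measure — computed from the ANOVA mean squares and labelled as such in
every output (cross-checked against pingouin's ICC(A,1)).  Cohen's kappa uses
marginal-product chance agreement; the paired t-test is the textbook
two-sided statistic with n-1 df.  The motivating analysis also compared
*pairs of ICCs* by a paired t-test; how exactly such a comparison is
constructed is not derivable from its description, so this package provides
the t-test primitive and leaves that construction to the user.

## Synthetic data

Phantoms are ellipsoids with a linear HU ramp (default width 1 mm, measured
by signed Euclidean distance to the discretised surface) between tumor
(default 80 HU) and background (default -100 HU) plus additive Gaussian noise
(default SD 8 HU), on the thin-slice grid; the ground-truth mask is the
noiseless >=50%-occupancy discretisation (5^3 subvoxel sampling).  Paired
cases scale the post radii by `shrink^(1/3)` so the true volume ratio is
exact.  Perfusion maps put the case's true parameter values inside the
down-sampled tumor region over a muscle-like background with proportional
noise; no cine time-series or arterial input function is simulated.

Feature-level cohorts draw change features from a multivariate normal with
exact group counts (default 36 cases, 10 without one-year DFS, responder
fraction 0.75).  The two informative features carry standardised group
differences d = 0.661 (blood-flow change) and d = 0.507 (percent volume
change), chosen so the per-feature population AUCs Phi(d/sqrt 2) are 0.68 and
0.64 — the performance scale the analysis is designed for.  This is a
calibration of the generator, not a reproduction of any clinical result.
The remaining 20 radiomic-change columns are uninformative by default.

Simulated radiologists read volumes with multiplicative lognormal noise.
With case log volume-ratio SD `s` and per-scan rater log-SD `sigma_r`, the
population ICC of percent change between two raters has the closed form

    ICC = (1 - e^{-s^2}) / ((1 - e^{-s^2}) + (e^{2 sigma_r^2} - 1)),

derived from the lognormal moments of `pc = 100 (e^{L + delta} - 1)` with
`L ~ N(mu, s^2)` and `delta ~ N(0, 2 sigma_r^2)`.  The default `sigma_r`
solves this for a target ICC of 0.75 (the simulated laryngoscopic reading
uses the same machinery with target 0.55, making it a much weaker rater).
At n = 36 the sample ICC estimator is slightly attenuated (mean ~0.74 over
100 cohorts), within the calibration tolerance.

What the generator does *not* emulate: anatomical shape irregularity,
necrosis, contrast-enhancement texture, scanner drift, registration error
between timepoints, correlated radiomic noise.  Passing tests therefore
demonstrate correctness of the pipeline's mathematics and its behaviour
under the assumed statistical structure — not clinical performance.

## Orchestration and reproducibility

One global seed; each stage derives an independent substream by hashing
(seed, stage name), so adding a stage never perturbs another's draws.  The
pipeline writes everything under one run directory, records a manifest of
SHA-256 digests per stage, supports resuming from intact stages, and is
bit-reproducible: identical config + seed gives identical digests for the
cohort, masks, scores and report (images are written as uncompressed NIfTI so
digests depend only on the data).  Default problem sizes (36-case cohort on
48x64x64-voxel phantoms; 200-seed null simulations; 2000/2000 ROC samples)
were chosen so a complete run and the full test suite execute comfortably on
a single CPU.

## Known limitations

- The level-set functional is a standard geodesic active-contour formulation;
  the in-house tool that inspired the three-stage design is not published, so
  no numerical equivalence with it is claimed, and the same holds for the
  identity of the original 26-feature list.
- The binormal CI is a Wald interval on the delta-method SE; near AUC 1 it is
  crude (the bootstrap option is better there).
- Phantom segmentation accuracy (Dice ~1.0) reflects the phantoms' clean
  geometry; real lesions with low-contrast margins will do worse.
- ICC comparisons between correlated pairs of raters (beyond the primitive
  paired t-test) are out of scope.
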