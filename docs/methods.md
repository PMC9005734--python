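# Methods

This note documents the models, conventions, parameter choices and known
limitations of the `svoct` pipeline.

## Coordinate and sampling conventions

Arrays are indexed `(z, x, y)`: depth (index 0 at the glass/tissue
interface, increasing downward), fast lateral axis within a B-scan, and
slow lateral axis (one index per B-scan position). Physical positions
are voxel centers, `(i + 0.5)·spacing`. The nominal acquisition grid is
anisotropic (≈8 μm axial × 15 μm lateral); all distance metrics are
computed after resampling the *binarized* mask to an isotropic
(2.5 μm)³ grid (binarize first, then resample, with nearest-neighbour
interpolation so the mask stays boolean). Distance-histogram bins are
2.5 μm wide, half-open `[lo, hi)`, starting at 0.

## Speckle-variance angiography

For M repeated same-position B-scans the angiographic contrast is the
per-pixel population variance, `sv = (1/M) Σ (Ī − I_t)²`. The 1/M
normalization (not 1/(M−1)) is deliberate and tested: on i.i.d.
unit-variance frames the mean response is (M−1)/M = 7/8 at M = 8.
Intensities are taken as linear by default; the scale choice is recorded
in the volume metadata. No interframe registration is applied — bulk
motion artifacts are handled downstream by morphological filtering.

## Segmentation pipeline

Stage order is fixed (each stage bypassable, with identity configs):
denoise → depth-decaying threshold → step-down shadow filter → Frangi
vesselness → binarize → VOI mask → isotropic resample.

- **Denoise.** Grayscale opening then closing with ellipsoidal
  structuring elements of physical radius (converted to voxels per
  axis), then a median filter. Defaults: no open/close, median 3 — on
  speckle data the median filter alone removes salt-and-pepper noise
  without the strong speckle-mean compression grayscale opening causes.
- **Depth-decaying threshold.** `T(z) = T0·exp(−μz)` matches
  Beer–Lambert signal decay so true-vessel survival is depth
  independent. Because sv is an intensity-squared quantity, its decay
  rate is twice the tissue attenuation coefficient; the default
  μ = 0.006 μm⁻¹ corresponds to tissue attenuation of 0.003 μm⁻¹.
  T0 defaults to the median of the positive voxels.
- **Step-down shadow filter.** Moving blood decorrelates the speckle of
  everything it shadows, leaving bright sv tails below vessels. Below
  each contiguous run of voxels above the volume-wide trigger quantile,
  values a distance Δz below the run are multiplied by
  `1 − exp(−Δz/L)` (L = 50 μm default); factors from stacked runs
  compound, implemented exactly as a causal convolution along depth in
  log space. The trigger quantile (default 0.98) should sit near one
  minus the expected vascular volume fraction: a lower quantile lets the
  bright tops of the shadow tails join the trigger runs and escape
  suppression. On matched-decay simulations the default removes >50% of
  sub-vessel false positives while keeping >95% of true vessel voxels.
- **Frangi vesselness.** Hand-rolled multiscale implementation because
  the analysis scale must be isotropic in μm on anisotropic grids:
  Gaussian-derivative Hessians use per-axis sigmas `scale/spacing_i`,
  second derivatives are divided by the axis spacings, and responses are
  γ = 2 scale-normalized. Eigenvalues are |λ1| ≤ |λ2| ≤ |λ3|; the
  standard tube response with α = β = 0.5 and c defaulting to half the
  maximum Hessian Frobenius norm per scale. Default scales
  {4, 7, 10, 14, 18} μm: the response for a tube of radius r peaks near
  σ ≈ r/√2, so this ladder covers radii ≈6–25 μm, the capillary-to-
  dilated-tumour-vessel range. Scales larger than the largest vessel
  radius measurably dilate the segmentation.
- **Binarize.** Otsu on the *log* of the positive vesselness values
  (vesselness distributions are heavy tailed; linear-domain Otsu lands
  far up the tail and erodes vessels to centerlines), then removal of
  connected components below 27 voxels — the programmatic counterpart of
  visually guided artifact removal. A fixed threshold is available.
- **VOI.** Default tumour VOI is a depth slab from the glass interface
  down ~1 mm, optionally intersected with a 2D lateral contour. Air
  gaps below the glass are not excluded. Metrics always receive the VOI
  (resampled to the isotropic grid) so out-of-VOI voxels never count as
  tissue.

On simulated cylinder phantoms (r_c = 20 μm, VVD 1–3%, anisotropic
(4, 5, 5) μm grid) the default pipeline reaches Dice ≈ 0.92 against
ground truth and recovers VVD within ~10–15%.

## DNV metrics

The DNV map is the exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt` with physical sampling),
verified voxel-for-voxel against a brute-force nearest-vessel search on
random masks. Tissue voxels are the non-vessel voxels inside the VOI;
vessel voxels (δ = 0) are excluded from n(δ) — their zero-distance mass
would be meaningless in the log–log fit. DLF_Λ sums bins with lower
edge ≥ Λ; off-grid Λ snaps to the nearest edge with a warning. An empty
vessel mask yields DLF = 1 with a warning (all tissue diffusion
limited) while λ is undefined and raises.

The convexity index is an unweighted OLS slope of log n(δ) vs log δ
over non-empty bins with centers in (0, 60 μm]; the standard error and
R² are reported so fit quality is visible. The fixed 60 μm cutoff is
the default; the adaptive δ_max/3 variant is available
(`fit_max=None`) but unvalidated. Planted power laws δ^λ* with
λ* ∈ {0, 0.5, 1, 2} are recovered to |error| < 0.001; a voxelized
single-cylinder phantom (shell density ∝ δ + r_c, r_c = 2.5 μm) gives
λ = 0.93, the residual from the finite radius and the first bin.

The Poisson cylinder null model is implemented twice, deliberately: the
small-radius proportionality `ln DLF_Λ = −(Λ/r_c)²·VVD` and the exact
form `−ρπ(Λ+r_c)²` with ρ recovered from VVD. At r_c = 15 μm and
VVD = 0.01 the two differ appreciably (0.296 vs 0.368 for DLF_150), so
conflating them would bias any architecture inference.

The symbol M is used in the field both for the repeated-B-scan count
and for the metabolism rate; the code names them `n_frames` and
`metabolism_rate` to avoid the collision.

## Synthetic data

The cylinder generator draws axis positions as a 2D Poisson process in
the cross-section perpendicular to the (axis-aligned) cylinder
direction, extended by a margin (default Λ + r_c = 165 μm) so interior
statistics match the unbounded process; the realized axes are returned
as ground truth. For this process DLF has the closed form
`exp(−ρπ(Λ+r_c)²)`; conditioning on the evaluation point being tissue
divides by `exp(−ρπr_c²)`, a correction of order VVD. The tree
generator grows a binary branching structure of tapering capsules (root
radius 20 μm, taper 0.75, ~35° branch angles) — a heterogeneous
geometry with a centerline-graph ground truth but no closed form; its
radius distribution is a package choice, not constrained by any
measured tumour data.

The speckle simulator models fully developed speckle: unit-mean
exponential intensities, with each voxel mixing a frozen field and
per-frame redraws, `I_t = (1−d)F + dR_t`. Decorrelation fractions
default to 1.0 in vessels and 0.05 in tissue (residual physiological
motion); d² sets the sv scale, so the vessel/tissue sv contrast is
large (≈100× in practice, safely above the 5× the segmentation needs).
Depth attenuation is Beer–Lambert (default 0.003 μm⁻¹, giving ~3
e-folds over the 1 mm imaging depth); below each vessel an excess
decorrelation tail `0.5·exp(−Δz/50 μm)` produces the shadow artifacts
the step-down filter targets; an additive exponential noise floor
(mean 0.05) bounds the tissue variance from below. The simulator is a
statistical forward model, not wave optics: no coherent PSF speckle
correlations, no flow-speed dependence, no bulk-motion artifacts, no
multiple scattering. Passing tests therefore demonstrate correctness of
the processing chain under the stated contrast mechanism, not
performance on real acquisitions with motion and depth-dependent
speckle statistics.

## Longitudinal statistics

Tidy tables (subject_id, dose_Gy, day, metric, value) with dose cohorts
{0, 10, 20, 30} Gy. DLF_150 is normalized per subject as the ratio to
its day-0 baseline; λ as the difference from baseline. Visits follow
unsynchronized every-few-days schedules, so cohort comparisons match
each subject's nearest stored visit within ±2 days (configurable) and
error otherwise; missing timepoints are dropped, not imputed. The
comparison is one-way ANOVA across all cohorts followed by per-dose
two-sample t-tests against control; Welch (unequal-variance) is the
default since cohort variances cannot be assumed equal at n = 3–6, with
a flag for the pooled variant. All p-values are returned regardless of
the ANOVA outcome, and no multiple-testing correction is applied (noted
in output metadata). Simulation checks: null ANOVA p-values are
uniform (KS test over 200 replicates), and a planted 3σ shift at n = 6
is detected at p < 0.05 in ≥95% of replicates. Time-to-peak is the
arg-extremum of a response series (direction per metric), ties broken
to the earliest visit.

## Problem sizes and tolerances

The Monte-Carlo validation phantoms are sized for single-CPU runs: the
Poisson-recovery fields use a 3 × 3 mm cross-section at 2.5 μm (with the
axis direction thin, since DNV statistics are translation invariant
along the cylinders), 10 seeds for DLF recovery (tolerance 15%
relative, comfortably above the ~4% Monte-Carlo error of the seed mean)
and 5 densities × 2 independent seeds for the ln DLF-vs-VVD slope
(tolerance 20% of −((Λ+r_c)/r_c)² = −121). End-to-end segmentation uses
a 0.4 × 1.0 × 0.5 mm phantom on the anisotropic grid. Brute-force
distance-transform checks run on ≥100 random masks up to 20³ voxels,
where exact equality is required.

## Known limitations

- Cylinder directions must be axis aligned (the closed-form oracle and
  the fast voxelization rely on it); oblique fields are out of scope.
- The shadow simulator and filter both use a nearest-run approximation
  in depth; densely stacked vasculature (VVD ≫ 5%) is outside the
  validated regime.
- The λ fit is sensitive to the first occupied bins; segmentation
  artifacts at short distances propagate into λ far more than into
  DLF_150, so λ should always be read together with its reported
  standard error and R².
- Real-tumour VOIs require supplied lateral contours; only slab VOIs
  are generated programmatically.
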