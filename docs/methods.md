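# Methods notes

This note documents the models, conventions and numerical choices behind
`osteomap`, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Thin-plate splines (3-D)

The interpolant from control points X (N×3) to targets Y is
f(p) = c + Ap + Σᵢ wᵢ U(‖p − xᵢ‖) with the 3-D fundamental kernel. The map
is identical whether the kernel is written U(r) = r or U(r) = −r (the
weights flip sign); internally the negative sign is used so that the
bending energy J = Σ_d w_dᵀ K w_d is non-negative on the side-condition
subspace (−r is conditionally positive definite of order 1). Properties
relied on throughout: exact interpolation at control points; J = 0 exactly
for affine targets; J invariant under rigid motion of both configurations
and under translation of either. `bending_energy_matrix` returns the N×N
matrix B (upper-left block of the inverse bordered system) with
J(Y) = tr(YᵀBY); B annihilates affine functions of the control points.
Systems are solved by LU with an explicit condition-number guard
(cond > 10¹² ⇒ degenerate-configuration error), so coincident or coplanar
control points fail loudly rather than silently.

Missing landmarks are estimated by mapping the reference's missing
positions through the TPS fitted on the shared landmarks
(reference → specimen). Because TPS reproduces affine maps exactly, any
specimen that is an affine image of the reference is restored exactly; the
pipeline's reference is the per-landmark mean over the specimens measured
at that landmark. Estimation precedes sliding, and estimated points are
allowed to slide.

## Semilandmark sliding

Curve semilandmarks may move only along local tangents (central differences
of ordered curve neighbours, one-sided at the fixed anchors); surface
semilandmarks move in the tangent plane spanned by two orthonormal vectors
derived from the surface normal (analytic normals of the synthetic patch,
or nearest-face normals of a supplied mesh). For one specimen all tangent
parameters are solved in a single linear system — the exact minimizer of
the quadratic bending-energy objective tr(YᵀBY), not a per-point greedy
pass. Fixed landmarks never move.

The sliding reference is the Procrustes consensus superimposed into each
specimen's own frame (rotation + scale + translation) once per call;
iterations (default 3) re-linearize the tangent directions at the slid
positions. Holding the reference fixed within a call makes the recorded
per-specimen energy trace provably non-increasing, since the zero
displacement is always feasible at each re-linearization; this is the
package default. The fully recursive scheme — consensus recomputed from the
slid data every iteration — is available via `update_reference=True`; its
energy trace is only approximately monotone because the minimization target
moves between iterations (observed wobble ~10⁻³ relative on noisy data).
Optional re-projection returns curve points to the specimen's *original*
digitized polylines (and surface points to the original mesh), preserving
the measured geometry at the cost of strict monotonicity.

## GPA, shape and form space

Partial Procrustes superposition: centring, scaling to unit centroid size,
and rotation-only alignment (reflections excluded — mirrored specimens are
not valid superpositions of same-side anatomy) to the iteratively updated,
renormalized consensus, until the consensus root-mean-square change falls
below 10⁻¹⁰. Centroid sizes are recorded before scaling. Form space appends
ln CS as one extra unweighted column to the flattened aligned coordinates —
the standard Procrustes form-space construction. PCA is computed by SVD of
the column-centred data; eigenvalues use the n−1 divisor, and each
component's sign is fixed so its largest-magnitude loading is positive,
making results independent of specimen order.

## Shape-change heatmaps

Meshes are warped by TPS from the template landmarks to group mean shapes
(connectivity unchanged; embedded landmarks land on targets). The signed
distance from the younger mean surface to the older is measured along the
younger mesh's outward vertex normals (nearest intersection in either
direction, cutoff 5 mean edge lengths, Möller–Trumbore against all faces),
falling back per-vertex to the nearest surface point; a pure nearest-point
mode is available (`method="nearest"`). Positive = older surface outside
the younger, i.e. forward growth displacement. The rendering scale is
symmetric about zero and covers the 2nd–98th percentile of the distances —
metadata only, per-species, so maps with different dynamic ranges stay
readable. Standard pairs are AG1→AG3 and AG3→AG5, with AG2→AG3 substituted
when the sample lacks AG1. Triangle-mesh proximity and ray queries are
implemented in numpy (brute force over faces), which is exact and fast at
the mesh sizes used (≤ a few thousand faces).

## Bone-modelling maps

Raw grids (default square size 2.5 mm; row 1 = superior, column 1 =
anterior) are standardized to 8×8 by treating the source as
piecewise-constant over its valid squares, stretching it to the target
extent and averaging with exact interval-overlap area weights. A target
square is masked when valid source coverage is below 50% of its area
(configurable); on fully valid grids the valid-area-weighted mean is
conserved to float precision, and an already-8×8 fully valid grid passes
through unchanged. Mean maps average per square over the specimens valid
there (square reported valid when ≥50% of the cell's specimens contribute);
total %BR is the bone-area-weighted mean of an individual's valid squares,
with per-square areas defaulting to the square size squared when measured
areas are absent. The per-square profile enumerates the common mask
(squares valid in >50% of all specimens) row-major from the
superior-anterior corner. Per-square comparisons use unweighted per-square
values; within-square area weighting enters only the total %BR.

## Statistics

Pairwise tests on PC scores use the Euclidean distance between group mean
score vectors (a pooled-variance T²-type statistic is available via
`statistic="pooled_t2"`), with labels reshuffled within the pair and the
conservative estimator p = (b+1)/(m+1), so p ≥ 1/(n_perm+1) and is never
zero; an exhaustive-enumeration mode computes exact p-values on small
groups. Bonferroni adjustment multiplies by the number of pairs, capped at
1. PERMANOVA uses squared Euclidean distances, SS_total = Σd²/(2N) with the
within-group analogue, pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)), and full label
reshuffles; the SS decomposition is exact and the statistic reduces to the
one-way ANOVA F in the univariate case. The size regression fits each %BR
column on ln CS by least squares, reports R² = 1 − tr(E)/tr(T), and
permutes sizes across specimens for significance. Permutations are full
label reshuffles (simple exchangeability), not residual permutations.

**Missing-square imputation.** Before PCA/PERMANOVA, squares masked in an
individual but inside the common mask are imputed with the *across-specimen*
(grand) mean at that square. Imputing with the species × age-group cell mean
— superficially more faithful — makes rows of the same group artificially
similar and was measured here to inflate the PERMANOVA type-I error from
~0.05 to ~0.5 on null data; it remains available (`impute="cell_mean"`), as
does restriction to squares valid in every specimen (`impute="restrict"`).
Label-blind grand-mean imputation keeps rows exchangeable under the null
(measured size ≈ 0.04–0.05 at α = 0.05) and is the default.

## Synthetic data generator

The generator emulates the study design, not maxillary biomechanics:

- **Template geometry**: the 249-point scheme realized on a smooth open
  quadric patch (40 × 35 mm footprint, 10 mm relief), curves as parametric
  paths between fixed anchors, surface points by deterministic stratified
  parametric sampling. Normals and tangents are everywhere defined.
- **Landmarks**: specimen = template + species offset + (AG−1) × trajectory,
  all scaled by the allometric factor 1 + 0.15(AG−1), plus isotropic
  Gaussian noise (default sd 0.5 mm). Species offsets and trajectories are
  random unit fields scaled to configured magnitudes (defaults 4 mm and
  2 mm/step), drawn deterministically from the global seed. Missing
  landmarks are Bernoulli over semilandmarks only (default rate 0.02) —
  fixed landmarks anchor curves and are never dropped — and are encoded as
  NaN plus a mask, never sentinels.
- **Maps**: per-square %BR = regional mean for the species × AG plus
  Gaussian noise (default 5 pp), clipped to [0, 100]. The default regional
  patterns encode the qualitative interspecific design (humans: high canine
  resorption from birth, childhood peak; chimpanzees/gorillas: premaxillary
  peaks at AG2/AG3; orangutans flat; gibbons low with zygomatico-maxillary
  and post-canine resorption). Validity masks come from thresholding a
  smooth random field biased toward the grid centre, giving a contiguous
  off-bone margin; grid dimensions are drawn uniformly from configured
  ranges (default 6–10).
- **Seeding**: one global seed; per-specimen streams via
  `SeedSequence([seed, species_index, age_group, replicate])`, so any
  specimen can be regenerated in isolation and whole datasets are bitwise
  reproducible.
- **Null mode** zeroes species offsets, shares one trajectory and pools the
  resorption patterns across species, so group labels carry no signal —
  the configuration used for type-I-error calibration.

Default cell size is 8 specimens per species × age group (a factorial
version of a real cross-sectional sample of ~170–180 individuals over ~23
occupied cells); within-group shape variance is a free parameter of the
generator, documented here, and not a claim about any real sample. What
passing tests show is that the *pipeline* recovers known truth under these
conditions; they do not certify biological realism of the patch geometry,
the white-noise shape covariance, or the independence of squares within a
map — real resorption fields are spatially autocorrelated, real landmark
noise is anisotropic, and real samples are unbalanced.

## Numerical conventions and degenerate inputs

GPA convergence 10⁻¹⁰ (RMS consensus change), sliding trace tolerance
10⁻⁹ relative, TPS condition bound 10¹²; PCA sign convention as above;
permutation p-values never zero by construction. Degenerate inputs raise
typed errors naming the offender: coincident/coplanar TPS control points,
duplicate curve neighbours (undefined tangent), all-coincident
configurations in GPA, all-masked grids, empty species × AG cells (the
error lists the available cells), groups of size <2 in any permutation
procedure, constant centroid size in the regression. The CLI maps these to
distinct exit codes (2 configuration, 3 format, 4 numerical).

## Problem sizes used in the shipped experiments

The acceptance computations run the full pipeline at 5 × 5 × 8 = 200
synthetic specimens; the PERMANOVA size calibration uses 500 null datasets
of n = 30 (3 species × 10) with 199 permutations each; the canine-offset
experiment uses 200 replicates of 2 species × 10 specimens on fixed 8×8
grids with a +20 pp regional offset and 5 pp square noise. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands
(e.g. ±0.01 on a 0.05 rejection rate at 500 replicates).

## Known limitations

No 2-D TPS; no geodesic or minimum-Procrustes-distance sliding; no
phylogenetically corrected PCA or GLS models; heatmaps do not reproduce any
particular commercial projection workflow; formation intensity is not
graded (0% resorption simply means formation/quiescence); computing %BR
from microscope imagery is upstream of this package.
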