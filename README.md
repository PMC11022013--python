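# osteomap

Joint macroscopic/microscopic analysis of primate midfacial growth:
sliding-semilandmark **geometric morphometrics** of the maxilla across
ontogeny, coupled with standardized **bone-modelling (BM) resorption maps**
of its periosteal surface, and the group-comparison statistics used to
contrast species and dental age groups.

The package is written for evolutionary developmental morphologists working
with cross-sectional growth series (here: gibbons, orangutans, gorillas,
chimpanzees, humans; dental age groups AG 1–5 from "no teeth erupted" to
"M3 erupted"). It covers the full analysis chain from per-specimen raw data
— a 249-point 3-D landmark configuration (9 fixed landmarks, 40 curve
semilandmarks on 8 curves, 200 surface semilandmarks) and a lattice of
2.5 × 2.5 mm squares each scoring percent bone resorption (%BR, 0 =
formation) — to publication-level tables, maps and tests. A first-class
synthetic-data generator reproduces the study design (species mean shapes,
ontogenetic trajectories, allometric size growth, regional resorption
patterns, masked off-bone squares, missing landmarks), so every stage is
testable end to end without access to the original specimens.

## Methods at a glance

**Geometric morphometrics.** Missing landmarks are estimated by 3-D
thin-plate spline (TPS) interpolation from a complete reference; the TPS
uses the 3-D kernel U(r) = r and exposes its bending energy, the quadratic
form wᵀKw of the non-affine weights (zero iff the map is affine).
Semilandmarks slide to minimize that bending energy — curve points along
finite-difference tangents, surface points in tangent planes — solved
jointly per specimen as one linear least-squares problem, so each iteration
is the exact minimizer and the per-specimen energy trace is non-increasing.
Generalized Procrustes analysis (GPA) then standardizes position,
orientation and scale to unit centroid size CS = √Σᵢ‖xᵢ − x̄‖², and PCA is
run in shape space (aligned coordinates) and Procrustes form space (aligned
coordinates plus ln CS). Shape change between subsequent age-group means is
rendered as signed-distance heatmaps on TPS-warped surface meshes (positive
= outward displacement from younger to older).

**Bone-modelling maps.** Raw grids of any size are standardized to a common
8 × 8 lattice by area-weighted piecewise-constant resampling (valid-area-
weighted mean conserved; squares with <50% valid coverage masked), averaged
into species × age-group mean maps, summarized as a total
%BR = Σᵢvᵢaᵢ / Σᵢaᵢ per individual, and tabulated square-by-square over the
common mask.

**Statistics.** Pairwise permutation tests on PC scores (Euclidean distance
between group mean score vectors; Bonferroni correction over pairs;
p = (b+1)/(m+1)), distance-based PERMANOVA with
F = (SS_A/(a−1)) / (SS_W/(N−a)) on Euclidean %BR distances, and a multiple
multivariate regression of %BR on ln CS with R² = 1 − tr(E)/tr(T) and a
permutation p-value. All permutation procedures are seeded and
reproducible.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```sh
$ python examples/02_morphometrics.py
sliding: total bending energy dropped by 10.988 over 3 iterations
GPA converged in 4 iterations; centroid sizes 228-371 mm
shape space: PC1 19.4%, PC2 8.6% of total variance
 form space: PC1 93.1%, PC2 1.4% of total variance
```

The sliding line reports the bending-energy reduction achieved by the
semilandmark relaxation; the form-space PC1 is dominated by the common
allometric growth axis (ln CS spans the five age groups), while shape-space
PCs separate species and trajectory directions.

```sh
$ python examples/03_bm_maps.py
...
total %BR by species (mean over all age groups):
      gibbon:   5.3%
   orangutan:   9.5%
     gorilla:   8.9%
  chimpanzee:   9.2%
       human:  15.0%
```

Total %BR is each individual's resorbed surface fraction corrected by bone
area; under the default synthetic study conditions humans resorb the most
and gibbons the least, mirroring the qualitative interspecific design the
generator emulates.

The whole chain — simulation, landmark completion, sliding, GPA, PCAs,
heatmaps, maps, profiles, statistics, and a content-hashed run manifest —
runs as one call (`examples/06_full_pipeline.py`) or from the shell:

```sh
osteomap run --seed 42 --out scratch/run
osteomap simulate --out scratch/data --seed 1   # write CSV inputs only
```

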