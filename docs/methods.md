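# Methods

## Pipeline overview

Each case enters as a labeled segmentation volume (integer grid, label 0 =
background, labels ≥ 1 = fracture fragments; voxel spacing in mm, NIfTI
carrier). The stages are:

1. **Fragment morphometry.** Fragments are taken from the input labels or, on
   request, re-derived as connected components of the bone mask
   (26-connectivity by default so thin oblique fragments stay connected;
   6-connectivity available). A fragment's volume is voxel count × voxel volume
   / 1000 cm³, exactly. Fragments strictly below 1 cm³ are comminution — the
   comparison is strict, so a fragment of exactly 1 cm³ is not comminuted.
   Specks below a 0.01 cm³ noise floor are discarded and the removed mass
   logged. The per-case mean comminuted volume averages comminuted fragments
   only; cases without comminution enter cohort summaries as zeros.
2. **Reduction and registration.** Right-sided cases are mirrored about the
   template's mid-sagittal plane (face winding flipped to keep normals
   outward). The case's reconstructed surface — the marching-cubes isosurface
   of its bone mask — is registered to the template by ICP and gated on the
   maximum surface distance: ≤ 5 mm, read inclusively. Failing cases are
   excluded from the maps and listed in the QC table.
3. **Mapping.** Fracture interfaces are the face-adjacent (6-connectivity)
   voxel pairs with differing fragment labels; 26-adjacency would inflate
   interfaces at corners. Where an interface voxel also touches background it
   lies on the outer cortex and contributes a fracture-line point. Comminution
   footprints are the outer-surface voxels of comminuted fragments. Both point
   sets are mapped through the case-to-template transform to nearest template
   vertices; points farther than a 5 mm cutoff (matching the gate) are
   discarded and counted. Per-case vertex sets are dilated 2 mm along the
   surface (hand-traced curves have width; the radius is configurable and
   recorded in output metadata) and accumulated binarily: frequency =
   100 × count / n. Color scales are normalized to each map's own maximum,
   since the conventions being followed describe relative gradients; zero is
   exactly the cool/light endpoint (dark blue for lines, white for
   comminution).
4. **Zone extents.** Heat-zone extents are signed distances along the superior
   axis from the joint-line plane (z = 0 at the distal condylar tangent) to the
   lowest and highest supra-threshold vertex, optionally restricted to a
   verbal sector ("medial", "anterolateral", ...) realized as half-space or
   quadrant proxies about the template axes.
5. **Cohort statistics.** See below.

## Registration

Point-to-point ICP with nearest-neighbor correspondences, Kabsch/SVD update,
termination on RMS change < 1e-4 mm or 200 iterations. Two refinements matter
in practice:

* **Tangent-plane correspondences.** When the target is a mesh with vertex
  normals, each nearest-vertex match is replaced by its foot point on the
  tangent plane at that vertex. Raw nearest-vertex ICP against a sampled
  surface has local minima about one vertex spacing from the optimum
  (tangential quantization) and a convergence basin of only ~1°; the projected
  correspondences recover planted rigid transforms of up to 30° to < 0.01° and
  < 0.001 mm on the phantom. The per-iteration RMS remains non-increasing.
* **Initialization.** Candidates are the identity plus the four proper
  sign-combinations of principal-axis alignment (centroids matched), ranked by
  initial nearest-neighbor RMS; ICP runs from the best candidate and restarts
  from the runners-up if the distance gate fails. The identity candidate is
  essential for partial fragments: PCA centroid matching would drag a shaft
  fragment to the whole-template centroid.

`virtual_reduce` registers the largest fragment against the whole template
first, then each remaining fragment against the template region near its
initial guess (the main transform applied to the fragment centroid), and raises
an error listing every fragment that misses the gate. The gate is enforced per
fragment and for the assembled model — the stricter of the two readings.

Distances in `spacing_check` are point-to-nearest-vertex (the template is
sampled at roughly one vertex per mm²), model → template. The check is
directional by construction: a partial model can sit on the template while the
template is far from the model.

## Statistics

Quantitative two-group comparisons: Shapiro–Wilk on each group (normal iff both
p > α, α = 0.05 — the gate level equals the significance level, a convention
choice); if normal, Levene's test with mean-centering (the classic form) picks
pooled (p > α) versus Welch t; otherwise Mann–Whitney U, exact when both n ≤ 10
and tie-free, else the normal approximation with tie and continuity correction.
A constant sample has no defined Shapiro statistic and routes to Mann–Whitney
with a trace note. Every branch decision is recorded in a selection trace.

Categorical tables: expected frequencies from the margins; if more than 20 % of
cells have expected < 5, a two-sided Fisher exact test by full enumeration of
the conditional (fixed-margin) distribution — two-sided p is the sum of
probabilities of tables no more probable than the observed, the standard
convention, which reduces to the classic 2×2 definition. Otherwise Pearson
chi-square **without** continuity correction: the uncorrected statistic
reproduces the published 2×2 p-values from the published counts, the
Yates-corrected one does not, so the uncorrected form is the inferred
convention of the source analysis.

`t_from_summary` recomputes two-sample t-tests from printed mean/SD/n rows
(pooled df = n₁+n₂−2; Welch–Satterthwaite df for the Welch variant). The
published comminuted-zone fragment-count row (0.92 ± 1.94 vs 3.33 ± 4.67,
p = 0.008) is not reproducible from its summaries by either t variant and is
presumably a rank test on raw data; it is excluded from the reproduction set.

Summaries follow the same normality gate: mean ± SD when Shapiro passes,
median (IQR) otherwise, with linear-interpolation quantiles. No
multiple-testing correction is applied, matching the source convention.

## The synthetic phantom and what it does (not) emulate

The phantom is stylized, not anatomical: a cylindrical shaft (radius 16 mm)
flaring through a cone into two superellipsoid condyles (exponent 2.5) with an
intercondylar notch wedge subtracted; the medial condyle is 10–12 % larger, as
in anatomy, which also makes laterality geometrically meaningful. Default
dimensions are 439 mm total length and 82 mm condylar width, matching the
reference template bone; the joint-line plane is the distal condylar tangent
(z = 0), superior is +z, anterior +y, medial +x on a left femur. Voxel spacing
defaults to 1 mm isotropic so sub-cm³ fragments contain hundreds of voxels;
tests use a shortened 180 mm phantom at 1.5 mm for speed (the distal geometry,
where everything happens, is unchanged).

Fractures are planted as cut surfaces — planes with 1 mm sinusoidal roughness
so interfaces are not axis-aligned artifacts — whose sign pattern partitions the
bone voxels (a label partition: fragment volumes sum to the intact volume
exactly). Intercondylar splits are near-sagittal cuts active only below the
supracondylar cut height, producing the "Y" articular pattern. Comminution is
carved inside a per-case region by capacity-constrained nearest-seed assignment
with farthest-point seeding: each planted fragment hits its volume target to
within voxel rounding (well inside 10 %). Plain Voronoi cells cannot control
volumes, which is why the capacity-constrained variant is used. Class-conditional
defaults (cut heights 45–75 mm above the joint line, obliquity
medial-superior→lateral-inferior 15–35° for the extra-articular class and the
opposite, shallower, for the articular class; comminution prevalence 33/53 vs
8/21; comminuted volumes 0.05–0.40 vs 0.35–0.95 cm³) were chosen once to
emulate the published fracture characteristics and are exposed as config, not
revisited. Demographics (bimodal age, class-conditional sex/side/mechanism
probabilities, BMI) likewise emulate the published cohort table.

Cases are generated in the reduced (anatomic) pose: the clinical workflow
reduces fragments before tracing, so the generator emulates the post-reduction
state. Displaced-mode transforms are supported (voxel resampling on a padded
grid, planted transforms recorded) and are exercised by the registration tests
through per-fragment rigid displacements of cortical surface points; the
displacement magnitude distribution (≤ 30° / ≤ 10 mm in tests) is a free
modeling choice, since no clinical distribution is stated for it.

What passing tests show: the geometry engine (partition, interface extraction,
projection, accumulation) is exact or voxel-accurate, registration recovers
planted poses far inside the 5 mm gate, and the statistics reproduce every
published value recomputable from printed tables. What they do not show:
behavior on real segmentations with CT noise, partial volume effects,
osteoporotic cortices, or anatomically variable femora — the phantom has none
of these, and a single template ignores inter-individual shape variation by
design.

## Numerical choices and degenerate inputs

* Thresholds: comminution strict <1 cm³; gate and projection cutoff inclusive
  ≤ 5 mm; all exposed in `PipelineConfig` and hashed into output metadata.
* Surface dilation uses Euclidean vertex balls (2 mm default); geodesic
  distances are unnecessary at this radius.
* Heat scales are per-map relative; an absolute scale is a config choice away
  (pass an explicit scheme/normalization downstream of `FrequencyMap`).
* Empty inputs fail loudly: all-background volumes, single-label interfaces
  (warning + empty result), empty cohorts, single-class cohorts, zero-margin
  tables, empty heat zones.
* Determinism: every random draw flows from a single seed; NIfTI/CSV/PLY/JSON
  writers use stable ordering and fixed float formatting, so reruns are
  byte-identical.
* Problem sizes: the test suite runs the shortened phantom (180 mm, 1.5 mm
  voxels) and cohorts of 5–40 cases; the acceptance script runs the full-size
  phantom at the study's 53 + 21 cohort. These sizes are the package's chosen
  operating points for routine verification.

## Known limitations

* The registration source is the whole-bone surface; in displaced mode the
  fracture interfaces (which have no template counterpart) would bias a naive
  whole-fragment registration, so fragment-level registration uses cortical
  points. Real pipelines would need interface/cortex discrimination from
  image intensity.
* Sector definitions for zone extents are half-space/quadrant proxies for
  verbal anatomical terms.
* Fisher's exact enumeration is exponential in table size; it is intended for
  the small contingency tables of cohort demographics (fine up to roughly r×c
  tables with n of a few hundred), not for large tables.
* The per-vertex count rule is binary per case per vertex; a case touching a
  vertex with both a line and a dilated neighbor still counts once. The rule
  is recorded in map metadata.
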