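# Methods

This note documents the models, numerical choices, and limitations behind
`dentomorph`. It is the package's own account of its procedures; every
number quoted here is computed by the test suite or `scripts/acceptance.py`.

## Landmark templates and storage order

Each tooth class and feature set has a frozen template:

| tooth | feature set | anatomical | curve sLM | outline | total |
|-------|-------------------|-----------:|----------:|--------:|------:|
| ldm2  | dentinal_crown    | 8 | 23 | 24 | 55 |
| udm2  | dentinal_crown    | 7 | 47 | 24 | 78 |
| ldm2  | edj_only          | 8 | 23 | 0  | 31 |
| udm2  | edj_only          | 7 | 47 | 0  | 54 |
| both  | cervical/crown outline | 0 | 0 | 24 | 24 |

Within a template the storage order is: anatomical block, then curve
semilandmarks (mesio-buccal first, clockwise in occlusal view), then the
24 outline pseudo-landmarks starting at the mesial reference ray. No
community convention fixes this order, so it is a package convention and
is enforced at I/O time. The ldm2 anatomical block holds the five dentine
horn tips and three marginal grooves; the udm2 block holds four horn tips,
the central fovea and distal fossa (interior points), and the deepest
point of the hypocone's lingual marginal ridge. The EDJ marginal edge is
modeled as a closed loop through the on-loop anatomical anchors with the
semilandmarks distributed along the gaps (ldm2: gaps of 3,3,3,3,3,3,3,2;
udm2: 10,10,9,9,9 with the two interior points off-loop).

Coordinates are treated as millimetres in a right-handed frame with +x
mesial, +y buccal and +z occlusal; no unit conversion is performed.

## Outline resampling

Closed 3D contours are projected orthogonally onto the cervical plane and
expressed in an orthonormal in-plane basis. The resampling centre is the
centroid of the outline *area* (shoelace-weighted), which is invariant to
vertex density; the vertex mean is available as a configurable fallback
because the phrase "centroid of the outline" is ambiguous in common usage.
Rays at angles 2πj/k (k = 24, j = 0 from the mesial +x direction) are
intersected with the polygon boundary; edges are half-open along the
boundary orientation so a ray through a vertex yields exactly one
intersection, and for non-star-shaped (hourglass) outlines the
intersection farthest from the centre is kept so pseudo-landmarks stay on
the outer silhouette.

## Superimposition

`generalized_procrustes` centres each configuration, scales it to unit
centroid size, and iteratively rotates it to the running consensus
(orthogonal Procrustes restricted to det = +1; reflections are never
implicit — anatomical mirroring is the explicit `mirror_to_left`
operation, which negates the bucco-lingual axis). The consensus is the
renormalized mean of the aligned shapes; iteration stops when its change
drops below `tol` (default 1e-10, max 100 iterations; non-convergence
returns a flagged result with a warning). The consensus is initialized
from the preshape mean, so re-running GPA on an already-aligned dataset
converges in one iteration.

Two fitting variants exist because "GPA" is ambiguous among them:

- **partial fitting** (default): every specimen stays at unit centroid
  size. This is the variant used throughout the pipeline.
- **full fitting** (`scale_refine=True`): each specimen is additionally
  scaled optimally toward the consensus during the consensus update. Its
  fixed point is the full Procrustes mean — for planar shapes, the leading
  eigenvector of the sum of complex preshape outer products — which the
  test suite verifies against that closed form to 1e-8. The partial-fitting
  consensus genuinely differs from the eigenvector mean (by ~5e-2 on
  random triangles), which is why the oracle comparison runs with
  `scale_refine=True`.

Note that superimposing planar data embedded in 3D allows a proper 3D
rotation to act as a 2D reflection; planar comparisons against
rotation-only oracles must therefore be run with 2D input, which the
code supports.

Outline feature sets are digitized in a common cervical frame, so they are
normalized with `mode="scale_only"` (centering and scaling, no rotation);
the pipeline enforces this automatically.

Tangent coordinates are the orthogonal projection of the aligned unit-size
shapes onto the linear tangent space at the consensus (not stereographic):
t = x − (x·μ)μ with μ the flattened consensus. The consensus maps to zero
and, after convergence, the tangent coordinates are mean-centred to the
GPA tolerance. For perturbations of the order present in these data the
tangent distance tracks the Procrustes distance to well under 1 %.

`procrustes_distance` is the root-sum-of-squares between unit-size,
centred, optimally rotated configurations (proper rotations only).

## Thin-plate splines and sliding

The TPS kernel is U(r) = r² log r in 2D and U(r) = r in 3D; the dimension
dependence is stated explicitly because "thin-plate spline" alone does not
determine it. The bending-energy matrix is the landmark block of the
inverse of the bordered kernel system; with the 3D kernel that block is
negative semi-definite, so it is sign-normalized to make the quadratic
form PSD in both dimensions, with all affine displacement fields in its
null space (verified to 1e-9).

Curve semilandmarks slide to minimize the total bending energy of the
consensus-to-specimen deformation. Per outer iteration and specimen, a
single joint linear solve finds the tangential displacement of all
slidable points (tangents by central differences along the curve,
one-sided at open ends and when neighbours coincide); the slid points are
then re-projected onto the specimen's digitized polyline, which also means
a point's total excursion is clamped to the curve. A backtracking step
(damping 1, 1/2, …, 1/16, else reject) guarantees that re-projection never
raises a specimen's energy.

The sliding target (consensus and bending form) is estimated once from
the input dataset and **held fixed across outer iterations** by default.
With a fixed target and the per-specimen guard, the reported energy
sequence is provably non-increasing — the property the validation suite
checks. `update_reference=True` selects the classical alternating scheme
(re-estimate the consensus each iteration); it usually ends at a slightly
lower energy but offers no monotonicity guarantee, because the quadratic
form itself changes between iterations. Iteration stops early when the
largest displacement falls below 1e-6 consensus units (default 3 outer
iterations otherwise). Re-projection polylines default to the input
configuration's own curve but can be passed explicitly (`polylines=`),
which is what makes repeated sliding idempotent: a converged dataset slid
again against the same curves and consensus moves by less than 1e-6.

## Shape statistics

All covariances use the n−1 divisor. PCA eigenvectors and PLS singular
vectors are sign-fixed so the largest-magnitude loading is positive; for
PLS the flip is applied to each X/Y vector *pair* jointly, because
flipping one side alone would negate the score covariance and hence the
sign of r_i. With this convention the paired score covariances d_i are
non-negative.

- **PCA** decomposes the specimen covariance of tangent coordinates;
  variance fractions are percentages of total variance. Warping endpoints
  at ±s along a component are consensus + s·eigenvector mapped back to a
  (k, 3) configuration, with a fitted TPS model for rendering; a guard
  rejects |s| beyond 3× the observed score range unless disabled.
- **2B-PLS** is the SVD of the between-block cross-covariance of
  separately superimposed, paired blocks. The per-pair share is of total
  *squared* covariance, 100·d_i²/Σd_j² (some tools report unsquared
  shares; the squared convention is stated to avoid ambiguity). r_i is the
  Pearson correlation of paired scores; the optional permutation test
  permutes the specimen pairing and uses the first singular value as the
  statistic. At small n relative to the coordinate dimension, the first
  singular warp overfits and r1 is biased upward — visible in the worked
  examples and inherent to the method, not a defect.
- **RV** = tr(Sxy Syx)/√(tr(Sxx²)tr(Syy²)); invariant to orthogonal
  transforms and scaling of either block.
- **Size-shape regression** regresses every tangent coordinate on lnCS;
  %-explained is Goodall-style, pooled over coordinates: 100·SS_pred/SS_tot.
- **Group Procrustes variance** is the sum of squared tangent distances to
  the group mean over n−1; singleton groups are excluded with a warning.

## Inference

The mean-shape permutation test uses the distance between group mean
tangent vectors, relabelling with group sizes fixed, and the
(1+exceedances)/(1+n_perm) p-value convention so p is never zero (at
n_perm = 10 000 this differs from the plain proportion by at most 1e-4).
Mann-Whitney U uses midranks, tie-corrected variance, a 0.5 continuity
correction and the two-sided normal approximation; the exact-enumeration
oracle lives in the tests. The reported Z is the absolute standardized
statistic (sidedness of the raw sign is a display convention).
Kruskal-Wallis (tie-corrected, χ² upper tail) and the Pearson Chi-square
of independence come from scipy; the Chi-square deliberately applies **no**
continuity correction — with Yates' correction the reconstructed hypocone
table [[1, 22], [17, 20]] would not reproduce the value 11.7 that the
bundled data imply. Two-sided p-values are used throughout.

## Traits

Dichotomization thresholds (first moderate/heavy grade): hypocone 4 of
0–6, Carabelli 5 of 0–7, entoconulid 3 of 0–5, metaconulid 2 of the
ordinal scale 0, 1, 1A, 2, 3, 4 (1A strictly between 1 and 2). Display
percentages use largest-remainder integer rounding (ties to the larger
quota), so each trait-population pair sums to 100; Chi-square always
consumes raw counts. The bundled grade fixture encodes, per specimen,
grades whose dichotomized counts match the reference prevalence table;
because that table collapses grades within a class, the within-class
values are a deterministic convention (none/light: hypocone grade 3,
others grade 0; moderate/heavy: the lowest grade of the class) and only
the dichotomized classes are data-faithful. One known discrepancy: the
Egypt metaconulid cell prints 71/29 here, because 5 of 7 specimens is
71.4 % — no integer count reproduces a 72/28 split at n = 7.

The bundled sample manifest reproduces the reference sample's margins
(39 Baka individuals contributing 23 udm2 and 32 ldm2; all per-population
udm2/ldm2 counts). Row-level upper/lower assignment of single-tooth
specimens is only partly recoverable from the available table, so dual
specimens are those with two wear scores and the remaining 23 Baka rows
are split 7 upper / 16 lower by a fixed convention; wear ranges such as
3–4 are stored as their lower bound.

## Synthetic cohorts

The generator is the package's own generative contract (the analyses
assume no particular model). A specimen is template + group offset + sex
effect + allometric term + isotropic Gaussian noise, built at unit
centroid size so `noise_sd` is in consensus units, then scaled by
exp(lnCS ~ N(μ_g, σ_g)) and randomly rotated and translated. Planted
effect axes are drawn orthogonal to the similarity subspace (translations,
infinitesimal rotations, scaling) so superimposition cannot absorb them.
Defaults: `noise_sd` 0.02 (≈2 % of configuration size, a plausible
digitization-noise scale), group sizes and lnCS ordering as in the
reference design (South American ≥ Baka > Southeast Asian > Egyptian >
European ≈ Bedouin; lnCS means 2.96–3.08, sd 0.05), sex labels for the
Baka only, sex effect 0 (the null the data suggest).

Dyads share a latent scalar u ~ N(0,1) driving one axis per block with
loading a = σ√(ρ/(1−ρ)), so the theoretical first-singular-warp score
correlation is ρ; at ρ = 1 the residual is removed entirely (deterministic
coupling, r1 = 1 to machine precision). The planted %-explained of the
allometric term is a²σ_g²/(a²σ_g² + Dσ²) with D = 3k−7 effective tangent
dimensions.

What the generator does *not* emulate: anatomically structured (low-rank,
spatially correlated) within-group covariance, wear, asymmetry, or
measurement error that varies along the curve. Passing tests therefore
demonstrate the correctness and calibration of the machinery, not that
real dm2 data would show any particular effect size; in particular the
diffuse PC spectra of synthetic cohorts (PC1 ≈ 5 %) differ from real
crowns, where a few anatomical factors dominate.

## Problem sizes and determinism

The validation suite uses n = 200 cohorts for recovery checks (r1 within
±0.1 of a planted 0.8 averaged over five replicates; allometry within ±5
percentage points), 100 replicate null datasets at n = 50 (n_perm = 499)
for PLS calibration, and 200 replicates at n = 15+15 (n_perm = 999) for
the permutation test's type-I error, using the 24-point outline feature
set where the check does not depend on template size. All stochastic
stages take explicit seeds and are bit-reproducible; the pipeline stamps
every output with the seed and a configuration hash.

## Known limitations

- Sliding is restricted to curve semilandmarks (one tangential degree of
  freedom); surface semilandmarks are out of scope.
- Missing landmarks are not estimated; configurations must be complete.
- The TPS system is solved densely (fine for ≤ ~100 landmarks).
- `mirror_to_left` assumes the tooth frame's bucco-lingual axis is y;
  arbitrarily oriented raw scans must be reoriented upstream.
- The permutation test compares exactly two groups; multi-group shape
  comparisons (e.g. permutational MANOVA) are not implemented.
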