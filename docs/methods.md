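# Methods

This note records the models, estimators, parameter choices and known
limitations behind `spineshape`, at the level of detail a user needs to
judge what a passing test suite does and does not establish.

## Canonical orientation

Real (tesseral) spherical harmonics are not rotation-invariant, so spines
are compared in a canonical pose fixed by two constraints applied in order:

1. the least-squares plane through the junction-region vertices (the rim
   where the spine meets its dendrite) is rotated so its normal lies along
   +y, with the sign chosen so the spine body sits at positive y;
2. the remaining free rotation about y is fixed by aligning the direction
   of largest vertex variance in the xz-projection with +z, with the sign
   chosen so the third central moment of z is non-negative.

The vertex centroid is moved to the origin, making the pose a pure function
of shape. For exactly axisymmetric solids the second constraint is
degenerate and resolved by numerical tie-breaking; the synthetic generator
therefore bends its spines slightly (see below), which both looks more
biological and makes the pose well-determined. A PCA-only fallback exists
for meshes without a junction region and is flagged with a warning.

## Internal center and radial tabulation

The spherical-coordinate origin is the *internal center*: the point of the
voxel skeleton nearest the volumetric centroid. The solid is rasterized by
vertical-column crossing parity (exact for watertight meshes up to the
grid), thinned with 3D morphological thinning, and the candidate nearest
the centroid that passes a ray-parity inside test is returned. The default
voxel pitch is the bounding-box diagonal / 64; halve it for very thin
structures (a `ResolutionError` tells you when).

Radii are tabulated by casting rays from the internal center along
Monte-Carlo directions (normalized 3D standard-normal draws). Spines are
not perfectly star-shaped: rays that cross the surface several times take
the **farthest** intersection by default (outer envelope — it preserves the
head outline, which dominates morphology; `multi_hit="first"` is available)
and the fraction of multi-hit rays is reported as a quality diagnostic.
Rays that miss entirely are dropped and counted; more than 50% misses marks
the spine "decomposition not possible".

## Harmonic encoding

The descriptor solves, in the least-squares sense,

    f(θ_i, φ_i) ≈ Σ_{l<L, |m|≤l} a_lm Y_lm(θ_i, φ_i),  i = 1..N

over the sampled directions. This is the projection onto the basis
normalized by the empirical Gram matrix; it converges as soon as N exceeds
the L² unknowns by a modest factor, which is why the defaults L=10, N=140
(N ≈ 1.4·L²) produce usable reconstructions. The raw quadrature sum
a_lm = (4π/|S|) Σ f·Y_lm is available as `method="mc"`; it is unbiased but
its coefficient noise decays only as 1/√N, requiring N in the 10⁵–10⁶ range
for comparable quality, so it serves as a cross-check rather than the
working estimator.

Numerical safeguards, all chosen a priori:

* **Truncated SVD (`rcond=0.05`).** At N ≈ 1.4·L² a random direction design
  occasionally has singular values far below the Marchenko–Pastur edge
  (≈ 8% of the leading one at this aspect ratio); such directions are not
  identifiable from the sample and would amplify aliased high-frequency
  content. They are dropped. Dense designs have a flat spectrum and are
  unaffected, so exactness on band-limited inputs is preserved.
* **Radius normalization.** Radii are divided by their maximum before
  encoding; the factor is kept in `scale`. Coefficient vectors are thereby
  size-free and comparable across spines (volume is re-introduced as an
  explicit feature where size matters). The physical mean-radius term is
  `a00 * scale`.
* **Reconstruction clamping.** Truncated expansions of thin spines can ring
  below zero; reconstructed radii are clamped at 1e-6·scale and the count
  reported, rather than failing.
* **Convention.** Real orthonormal tesseral harmonics without the
  Condon–Shortley phase; coefficients packed (l, m)-lexicographically,
  l = 0..L−1, m = −l..l. The packing order is part of the CSV contract.

## Light-field descriptor

Five observation points on the enclosing sphere of radius 2r (r = largest
vertex radius about the internal center): the +z, +x and +y principal views
and two diagonal views at zenith π/3 and 2π/3 in the azimuth-π/3
half-plane. Each view is an orthographic binary rasterization of all faces
(default 256²; a convergence test covers the resolution choice), inscribed
into the unit disk by its minimal enclosing circle (computed exactly with
Welzl's algorithm on the convex hull of foreground pixels) — removing
translation and scale. Zernike moments are computed as area-weighted pixel
sums of f·V*_mn with the standard (n+1)/π normalization so that the plain
synthesis sum reconstructs the silhouette; the bare "plain" sum is
available and differs only by per-(n, m) constants, which no invariance
property depends on. Camera roll is fixed deterministically (world z
projected into the view plane as image "up"; the polar view uses world x),
because real-part features are roll-dependent while moduli are not —
`modulus` is the default feature mode for exactly that reason.

## Clustering and separability statistics

Features are z-scored by default (without it, the a00 column and the volume
column would dominate every distance). k-means uses 20 restarts and a fixed
seed; model selection reports both the silhouette argmax and the elbow
(maximum second difference of inertia) without a silent tie-break.
Separability between the control and treated groups is tested two ways:

* per cluster, an Agresti–Caffo adjusted-Wald test comparing the cluster's
  membership rate in control vs treated (add one success and one failure to
  each sample; z-test on the adjusted proportions). Raw p-values are the
  primary readout; a Holm-adjusted column is emitted alongside, clearly
  labeled.
* overall, an uncorrected Pearson chi-squared test on the k×2
  cluster-by-group table (uncorrected so that on a 2×2 table χ² equals the
  squared two-proportion z statistic). A warning is raised when an expected
  count falls below 5.

`best_separability_report` reproduces the descriptor-comparison procedure:
every reduction in {none, PCA, t-SNE, UMAP} is clustered at its
silhouette-selected k and the configuration with the smallest overall
chi-squared p is reported together with the full per-configuration table.
Note this is a selection over four analyses: the winning p-value is a
model-selection readout, not a single calibrated test — the per-cluster
null calibration below is computed within a fixed clustering and is
unaffected. t-SNE (perplexity 30, capped at (n−1)/3) and UMAP
(15 neighbors, min_dist 0.1) run seeded; embeddings are reproducible, not
canonical.

## Synthetic spines

Each spine is a lathe solid: a circular profile R(t) revolved about the
spine axis (+y), with the junction disk in the y=0 plane and its rim
exported as the junction region. Class archetypes: mushroom (head radius
0.50, neck 0.16×0.45), thin (0.21, 0.11×1.00), stubby (0.45, neck length
0), filopodia (tapered shaft, tip cap 0.08 < shaft 0.13 — headless), all in
arbitrary-but-consistent length units (think µm). Heads are ellipsoids
(axial semi-axis = eccentricity × radius) fused where the head
cross-section equals the neck radius. A lateral bend shears ring centers
toward +x (tip offset 15% of length by default); since shear preserves
cross-section areas, the solid volume remains exactly π∫R(t)²dt, which the
tests use as an analytic oracle. Gaussian jitter (sd 0.01) is applied along
vertex normals to all vertices except the flat junction disk, keeping the
rim exactly planar and the base watertight.

Populations draw classes from a per-group mixture (default 40/30/20/10
mushroom/thin/stubby/filopodia in both groups), scatter parameters with
lognormal(σ=0.08) per-spine jitter, and apply multiplicative treated-group
effects — head radius ×0.7 and neck length ×1.4 by default, a
volume-reducing, elongating phenotype. What the generator does **not**
emulate: segmentation noise and topology defects, dendrite-attached
geometry beyond a flat rim, within-spine surface texture, or realistic
class-conditional covariance of parameters. Tests passing on these
populations therefore validate the estimators and the statistical
machinery, not performance on microscope-derived meshes.

## Problem sizes and determinism

The shipped experiments use: 200×400 (θ, φ) and 400² disk quadratures for
orthonormality; N=10⁵ directions for the sphere fixed point; 20 band-limited
fixtures at N=4×10⁴ (dense enough that the least-squares fit is limited by
conditioning, not sampling); and 20 independent populations of 100 spines
per group for the separability experiment, whose per-cluster test is
additionally calibrated on 500 label permutations (rejection rate expected
in [0.02, 0.09] at α=0.05). One top-level seed drives everything;
per-spine streams are derived by hashing the spine id, so results do not
depend on dataset order.

## Known limitations

* The radial parameterization assumes the spine is nearly star-shaped from
  its internal center; long curved thin spines violate this, show high
  multi-hit fractions, and reconstruct poorly — they are reported, not
  silently dropped.
* The harmonic descriptor is pose-dependent by design; orientation errors
  (e.g. a mis-annotated junction region) translate directly into descriptor
  differences.
* Five silhouettes do not determine a 3D shape; the light-field descriptor
  supports comparison and clustering, not full 3D reconstruction.
* k-means with Euclidean distance inherits all the usual caveats
  (spherical clusters, sensitivity to feature scaling); the pipeline
  surfaces silhouette and elbow diagnostics rather than hiding them.
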