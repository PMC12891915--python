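# spineshape

3D shape descriptors and morphology clustering for dendritic spines.

Dendritic spines — the micron-scale protrusions that carry most excitatory
synapses — change shape with learning and with disease. Classical analyses
reduce a segmented spine mesh to a handful of scalar metrics (volume, neck
length, head diameter, ...), which discards most of the surface geometry.
`spineshape` implements two full-surface descriptors for triangulated spine
meshes, plus the statistical pipeline needed to ask whether two populations
(for example untreated neurons vs an amyloid-β Alzheimer's model) occupy
morphology space differently:

1. **Spherical-harmonics descriptor.** The spine is rotated into a canonical
   pose (junction rim to the xz-plane, maximal residual variance on z), the
   surface radius is tabulated as a function of direction from the spine's
   *internal center* (the skeleton point nearest the center of mass), and the
   radial function is expanded in real orthonormal spherical harmonics:

       f(θ, φ) ≈ Σ_{l<L} Σ_{|m|≤l} a_lm · Y_lm(θ, φ)

   The coefficient vector `a` (length L², default L=10 → 100 numbers,
   estimated from N=140 sampled directions) is the shape signature, and the
   same expansion reconstructs an approximation mesh by displacing icosphere
   vertices — so a spine can be stored, edited and regenerated as 100 numbers.

2. **Light-field descriptor.** The oriented spine is enclosed in a sphere of
   radius 2r carrying five fixed observation points (the three principal
   orthogonal views plus two diagonal ones). Each view yields a binary
   orthographic silhouette, inscribed into the unit disk and expanded in
   complex Zernike moments

       a_mn = Σ_{x²+y²≤1} f(x, y) · V*_mn(r, θ) · dA,   n ≤ M

   (default M=10 → 36 moments per view, 180 per spine). Moment moduli are
   invariant to in-plane rotation and, via the disk inscription, to scale.

3. **Morphology pipeline.** Descriptor vectors (optionally with the volume
   scalar) are z-scored, optionally reduced (PCA / t-SNE / UMAP), clustered
   with k-means (elbow + silhouette model selection), and group separability
   is scored per cluster with the Agresti–Caffo adjusted-Wald two-proportion
   test and overall with a Pearson chi-squared test on the k×2
   cluster-by-group table. Reconstruction fidelity is scored with the
   symmetric Hausdorff distance.

Because no spine mesh dataset ships with the package, a parametric generator
(`spineshape.synth`) builds watertight head-and-neck meshes for the four
classical morphology classes (mushroom, thin, stubby, filopodia) and
two-group populations with controllable treated-group effects (smaller
heads, longer necks). The generator is first-class, tested code: it is the
package's demo data, its test fixture factory, and a harness for power
analyses.

## Worked example

```bash
spineshape synth  --out pop --n-per-group 8 --seed 1
spineshape encode --input pop --out feats --junctions pop/junctions.json --descriptor both
spineshape cluster --features feats/sphharm.csv --groups pop/labels.csv \
                   --volumes feats/volumes.csv --out clus -k 3 --seed 1
spineshape reconstruct --features feats/sphharm.csv --spine-id control_0000 \
                   --out rec.ply --original pop/control_0000.ply --junctions pop/junctions.json
```

prints (seed 1, this machine):

```
wrote 16 spines to pop
encoded 16/16 spines; 0 failure records
k=3 none: 0/3 clusters separate groups (chi2 p=0.319)
wrote rec.ply (2562 vertices, 13 clamped)
symmetric Hausdorff vs original: 0.2931
```

Reading the numbers: all 16 synthetic spines passed the full encoding chain
(no "decomposition not possible" records); with only 8 spines per group the
chi-squared test rightly finds no significant group separation (p = 0.32 —
power requires ~100 spines per group, see `docs/methods.md`); and the
100-coefficient harmonic code reconstructs the first control spine (a
stubby, bounding-box diagonal 1.53) to a symmetric Hausdorff distance of
0.29 length units, with 13 of 2562 icosphere vertices clamped where the
truncated expansion rang below zero. The same functions are importable from
Python (`from spineshape import encode_sphharm, cluster_group_report, ...`).

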