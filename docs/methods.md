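# Methods

This note documents the models, algorithms and numerical choices behind
`seedgrad`. The package analyses the connectivity of a small seed region
(modeled on the basal forebrain, the subcortical source of cortical
cholinergic innervation) with the cerebral cortex, in two imaging-derived
modalities at once: a *structural* connectome of streamline-count-like
weights and a *functional* connectome of Pearson correlations, both shaped
`m` seed voxels by `n` cortical parcels. The scientific object of interest
is the set of continuous axes ("gradients") along which seed voxels change
their cortical connectivity profile, and the degree to which the structural
and functional axes coincide ("tethering") or diverge ("detethering").

## Gradients: normalized-angle affinity and diffusion-map embedding

Each seed voxel's connectivity profile (a matrix row) is first sparsified to
its strongest `1 - sparsity` fraction of entries (default sparsity 0.9, the
common toolbox default for this analysis family). The affinity between
voxels u and v is the normalized angle of the sparsified profiles,

    a(u, v) = 1 - arccos(cos(x_u, x_v)) / pi,

mapping cosine similarity in [-1, 1] to affinity in [0, 1]. Because the
kernel is cosine-based it is invariant to positive per-row rescaling, so the
structural (count-valued) and functional (correlation-valued) modalities are
embedded on the same footing.

The embedding is the standard diffusion map: density normalization of the
affinity with exponent `alpha` (default 0.5), row normalization into a
Markov operator, and eigendecomposition of its symmetric conjugate (dense
`eigh`; seed-region problems are small, m <= a few thousand). The trivial
constant eigenvector is dropped; components are ordered by eigenvalue.
`diffusion_time = 0` selects the automatic multiscale scaling
`lambda / (1 - lambda)`. Explained variance of component k is defined as
`lambda_k / sum(positive nontrivial lambdas)` — conventions differ between
toolboxes, so the definition is fixed here explicitly.

Eigenvector signs are arbitrary; for determinism each component is oriented
so that its correlation with the first spatial coordinate of the seed voxels
is nonnegative (falling back to making the largest-magnitude entry positive
when no reference is available).

The number of retained components uses a variance-plateau rule: keep the
largest `k` such that every component up to `k` exceeds twice the median of
the spectrum beyond it (factor configurable; minimum 1). The pipeline caps
retention at 6 structural and 4 functional components.

## Tethering: the variance-weighted residual map

For every retained pair (structural component i, functional component j),
both score vectors are standardized and the structural one is regressed on
the functional one by ordinary least squares; with standardized variables
the slope is the Pearson correlation, and the total squared residual
`n (1 - r^2)` is direction-symmetric (the per-voxel residual values are
not — only the aggregate is). The detethering map is

    xbar_v = sum_k (w_i,k + w_j,k) * x_k,v^2 ,

summing over pairs k, where `w_i`, `w_j` are the explained-variance
fractions of the paired components and `x_k` the residual vector of pair k.
Weights are used literally (unnormalized) by default; normalization to unit
sum is an option. The same construction applied across cortical parcels to
gradient-weighted cortical maps yields the cortical detethering map, reusing
the seed-level explained-variance weights.

Pairwise shared variance is reported as the squared Pearson correlation per
pair; its significance is assessed against variogram-matched surrogates of
the structural component — a surrogate rather than parametric null, so the
spatial autocorrelation of the gradients is respected — with a
Bonferroni-style threshold of 0.05 / n_pairs when a familywise criterion is
wanted.

Subregion contrasts (mean difference and coefficient-of-variation
difference, CoV = 100 * sd / mean with sample sd) are computed on values
rescaled to [0, 1], against surrogate-map permutation nulls with the
two-sided `+1`-corrected p-value `p = (1 + #{|null| >= |obs|}) / (1 + N)`.

## Cortical projection

The cortical expression of a gradient is the connectivity matrix with each
row multiplied by its voxel's gradient score, averaged over voxels
(unweighted mean; no connectivity-strength reweighting). The map is linear
in the gradient. Network decompositions group parcels by supplied labels
(synthetic contiguous groupings by default; real 7-network labels can be
supplied via CSV) and order networks by mean value.

## Surface geodesics

Geodesic distance is along the triangulated mesh, not through 3-D space.
The solver initializes with multi-source Dijkstra on the mesh edge graph and
then iterates a vectorized local update per triangle: given tentative
distances at two corners A, B, the triangle is laid out in the plane, the
virtual point source consistent with (d_A, d_B) is reconstructed below the
A-B edge, and the third corner C is proposed the straight-line distance to
that source whenever the connecting ray enters through the A-B edge
(otherwise edge-wise propagation `min(d_A + |AC|, d_B + |BC|)`). This is the
local step of exact polyhedral geodesic algorithms; iterated to a fixpoint
(monotone decreasing, tolerance 1e-9) it converges in ~100 sweeps on a
subdivision-5 icosphere, where the maximum error against the analytic
great-circle distance measures 0.74% (mean 0.13%). A pure
Dijkstra-plus-unfolded-chords graph was evaluated first and rejected: its
best achievable max error on the icosphere was 5% (and two-triangle-strip
chords degenerate into through-vertex paths on a triangular lattice).

Medial-wall vertices are removed from the path graph and flagged NaN;
unreachable vertices are flagged NaN with a warning. Seed labels come from
thresholding a per-vertex probability map at 0.5 (inclusive). Parcellation
of a vertex map takes the mean over member vertices, ignoring flagged ones.

## Spatial null models

**Spin test.** Parcel centroids on the unit sphere are rotated by a uniform
random rotation (QR of a Gaussian 3x3 draw, determinant forced positive) and
every parcel receives the value of its nearest original centroid; the
correlation of the spun map A with the fixed map B forms the null. The
identity rotation is a fixed point, and every assigned value exists in the
original map. Rotation is a symmetry of the *full* sphere: with a medial-wall
cap, rotated positions falling inside the cap get rim-parcel values
duplicated, which narrows the null and inflates the false-positive rate
(measured 0.12-0.15 at alpha = 0.05 on a 5%-capped sphere versus 0.04-0.07
without a cap). Calibration checks therefore run on an uncapped sphere; spin
tests on masked real data share this caveat.

**Variogram-matched surrogates.** For domains without spherical geometry
(seed voxels in mm space), surrogates preserve spatial autocorrelation by
construction: permute the source values; smooth the permutation with a
Gaussian distance kernel over each point's nearest pv-percent of neighbors
(pv = 60; the point itself is included) for each of 10 log-spaced kernel
scales spanning the observed distance range; fit the source's 25-bin
equal-count variogram by nonnegative least squares on (slope, intercept)
with 1/gamma relative weighting; take the best-fitting scale and form
`sqrt(beta) * (smoothed - mean) + sqrt(alpha) * noise`; finally rank-remap
onto the source's empirical value distribution (on by default), so the
value multiset is preserved exactly. Nonnegative, relatively-weighted
fitting matters: an unconstrained absolute-error fit inflates the nugget and
roughens surrogates at short lags, where the variogram is smallest.

A note on attainable fidelity: a single surrogate's binned variogram
deviates from the source's by sampling noise alone; on small domains (a few
hundred points with strong autocorrelation) even fresh draws from the true
generative model deviate by ~20% per bin. The fidelity the generator is
accountable for — and what the tests measure — is on a field ergodic at the
domain scale (1000 grid points, correlation length one grid spacing), where
the per-surrogate mean relative deviation is 7-9%.

**Bootstrap contrast of correlations.** To compare r(x, yA) with r(x, yB)
on a shared map x, parcels are resampled with replacement jointly across the
three maps; the 95% CI is percentile-based, and `p_boot` is twice the
smaller tail fraction of bootstrap differences crossing zero, capped at 1
(the estimator is fixed here because reporting conventions differ).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes and
nothing else — no hemodynamics, no diffusion signal, no tracer kinetics.

* **Geometry.** The cortex analog is a unit icosphere (subdivision 4 by
  default: 2562 vertices), optionally with a polar-cap medial-wall analog
  (5% of vertices). Parcels (default 100) grow from random seed vertices by
  round-robin breadth-first expansion, ties broken by vertex index. The
  seed region is a voxel grid (default 5x5x5, 1 mm spacing) below the
  sphere, with the planted gradient the rescaled projection of voxel
  coordinates onto a fixed oblique axis, and two subregions ('A'/'B' —
  analogs of the anteromedial and posterolateral cholinergic cell groups)
  split along that axis by `floor(m * split)`.

* **Connectomes.** Both modalities express one bilinear field. The voxel
  loading is `u in [0.2, 1]` (affine in the planted gradient; the positive
  floor keeps every profile's within-row ordering fixed, as for real
  streamline counts whose strong targets stay strong along an axis). The
  parcel profile `c` ranks parcels along a smooth centroid axis and places
  the top decile — a "hub" set — in [0.35, 1] with the remainder in
  [-1, -0.15]. The value gap at the boundary gives the heavy-tailed target
  distribution of tractography (few strong targets, many weak) and keeps
  the top-decile support of every profile stable under count noise, which
  row sparsification at 0.9 would otherwise amplify into affinity noise.
  Expected structural counts are `50 * (1 + 0.9 * u * c)` (about 5 to 95
  streamlines); subjects draw Poisson counts around a mean-preserving
  log-normally jittered rate (jitter scale `noise_sd`). The functional
  *population* correlation is proportional to the same field with the voxel
  loading replaced by a coupled axis
  `u_f = sqrt(kappa) * (u - mean) + sqrt(1 - kappa) * u_perp + mean`,
  where `kappa` is the intermodal coupling (the fraction of gradient
  variance shared between modalities — the generative parameterization is a
  modeling choice; the analysis only measures it) and `u_perp` a second,
  orthogonalized spatial axis of the seed grid. Functional data are realized
  as timeseries: i.i.d. standard-normal parcel latents mixed into voxel
  series with the target correlations as weights plus idiosyncratic noise
  topping every voxel up to equal total variance, so the population
  voxel-parcel correlation equals the target exactly.

* **The noise-free limit.** At `noise_sd = 0` the generator returns the
  deterministic population objects: real-valued expected counts and
  population correlations, identical across subjects. In this limit the two
  modalities at `kappa = 1` are exactly proportional matrices — equal
  normalized-angle affinities, hence identical gradients — and because the
  expected matrix is rank-2 (constant plus `u x c`), every
  gradient-weighted cortical map of either modality is exactly affine in
  `c`, making all pair maps perfectly collinear and the cortical residual
  map zero to machine precision. This is the designed end-to-end zero
  point of the detethering pipeline. It also means that at zero noise the
  cortical residual map is degenerate for *any* coupling; away from the
  limit, sampling noise and the coupling axis both contribute, and the mean
  seed-level weighted residual decreases monotonically in `kappa`.

* **Covariate maps.** Spatially autocorrelated scalar maps (myelin-like,
  tracer-density-like, and spin-test calibration inputs) are Gaussian white
  noise smoothed with a great-circle Gaussian kernel of the requested
  correlation length (radians), parcel-averaged, and standardized.

## Reference study conditions and problem sizes

The default `RunConfig` fixes the study at 125 seed voxels x 100 parcels,
173 subjects, 3840 functional timepoints (four concatenated runs of 960),
subject-level rate jitter `noise_sd = 0.3`, intermodal coupling 0.5,
sparsity 0.9, 1000 variogram surrogates, 10000 spins, 10000 bootstrap
draws, seed-label threshold 0.5. Tests and the acceptance script use these
sizes (null counts are reduced where a check does not depend on them:
spin-calibration uses 1000 spins per map pair, the bootstrap power check
2000 draws per replicate) so the whole suite runs in minutes on one CPU.

## Known limitations

* The generator's rank-2 expected connectome is intentionally the simplest
  structure expressing one shared axis; real connectomes have higher-rank
  topographies, so passing tests demonstrate correctness of the machinery
  and calibration of the nulls, not performance on rich topographies.
* Out-of-sample transform is undefined for the single-dataset embedding
  (`DiffusionGradients.transform` returns fitted scores); no Procrustes
  alignment across datasets is provided.
* The geodesic solver is first-order accurate; distances can undershoot the
  true polyhedral geodesic by up to ~1% near the seed antipode.
* Spin tests on medial-wall-masked parcellations are mildly anticonservative
  (see above); the variogram-surrogate route is the alternative when the
  domain is not a full sphere.
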