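# seedgrad

Multimodal connectivity gradients of a seed region and the cortex.

`seedgrad` analyses the connectivity of a small seed region — modeled on the
basal forebrain, the subcortical source of the cortical cholinergic
projection — with the cerebral cortex in two modalities at once: a
*structural* connectome of streamline-count-like weights and a *functional*
connectome of Pearson correlations, both shaped `m` seed voxels by `n`
cortical parcels. It is written for researchers who want to ask, on their
own seed-to-cortex matrices or on fully synthetic data with planted ground
truth:

* along which continuous axes ("gradients") do seed voxels change their
  cortical connectivity profile, per modality?
* how strongly do the structural and functional axes coincide (tethering)
  or diverge (detethering), and where?
* how does the cortical expression of these axes relate to covariates such
  as geodesic distance from the seed, myelin content, or tracer density —
  judged against spatial null models that respect autocorrelation?

## The model in brief

Gradients are diffusion-map embeddings of a normalized-angle affinity: for
seed voxels with (sparsified) connectivity rows `x_u`, `x_v`,

    a(u, v) = 1 − arccos(cos(x_u, x_v)) / π ,

followed by density normalization (α = 0.5), row normalization into a
Markov operator, and eigendecomposition; component k carries an
explained-variance fraction `w_k` (its share of the nontrivial spectrum).

Detethering is quantified by the variance-weighted residual map over all
retained structural × functional component pairs k = (i, j):

    x̄_v = Σ_k (w_i,k + w_j,k) · x²_k,v ,

where `x_k` is the residual of regressing the standardized structural
component on the standardized functional one. The same construction across
parcels, applied to gradient-weighted cortical maps
(`map_j = mean_v gradient_v · conn_vj`), yields the cortical detethering
map. Inference uses spin tests (random sphere rotations of parcel
centroids), variogram-matched surrogate maps, and bootstrap contrasts of
correlations. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from seedgrad import synthetic
from seedgrad.connectome import average_connectomes
from seedgrad.gradients import DiffusionGradients, select_components
from seedgrad.tethering import make_pair_residuals, weighted_residual_map

# synthetic study: spherical cortex, 100 parcels, 125-voxel seed region,
# 173 subjects, half of the gradient variance shared between modalities
surface = synthetic.make_sphere_surface(4, medial_wall_fraction=0.05)
parcellation = synthetic.make_parcellation(surface, 100, seed=0)
seed_region = synthetic.make_seed_region((5, 5, 5), subregion_split=0.4, seed=0)
truth = synthetic.make_truth(seed_region, parcellation, intermodal_coupling=0.5, seed=0)
structural, functional, _ = synthetic.simulate_connectomes(
    seed_region, parcellation, truth, noise_sd=0.3, n_subjects=173, n_timepoints=3840
)
conn_s = average_connectomes(structural)
conn_f = average_connectomes(functional)

grads_s = DiffusionGradients(n_components=10).fit(conn_s.values).to_gradient_set("structural")
grads_f = DiffusionGradients(n_components=10).fit(conn_f.values).to_gradient_set("functional")
rho = spearmanr(grads_s.component(0), truth.planted_gradient).statistic
print(f"sG1 vs planted axis: Spearman rho = {abs(rho):.3f}")
print(f"structural variance fractions: {np.round(grads_s.explained_variance[:4], 3)}")

ks = min(select_components(grads_s.explained_variance), 6)
kf = min(select_components(grads_f.explained_variance), 4)
pairs = make_pair_residuals(grads_s, grads_f, ks, kf)
wrm = weighted_residual_map(pairs)
print(f"retained {ks} structural x {kf} functional components -> {len(pairs)} pairs")
print(f"mean weighted residual (detethering): {wrm.values.mean():.3f}")
```

prints

```
sG1 vs planted axis: Spearman rho = 0.901
structural variance fractions: [0.236 0.057 0.051 0.047]
retained 1 structural x 3 functional components -> 3 pairs
mean weighted residual (detethering): 1.101
```

The first structural gradient recovers the planted anatomical axis of the
seed region (ρ = 0.90 at realistic noise; exactly 1.0 in the noise-free
limit). The mean weighted residual is the study's detethering summary: on
this data it falls from ≈1.34 at coupling 0 to ≈0.73 at coupling 1,
because residuals shrink as the two modalities share more gradient
variance. In the exact noise-free, fully-coupled limit the cortical
residual map is zero to machine precision — the pipeline's designed null
point.

The same pipeline is scriptable from the shell:

```
seedgrad run-all --seed 1 -o out/        # all stages, CSV outputs + provenance
seedgrad tether --seed 1                 # R² matrix and subregion contrasts
seedgrad simulate -o data/ --coupling 1  # just the synthetic dataset
```

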