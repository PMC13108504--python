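# mindrat

Structural similarity networks for the rat cortex from voxel-level MRI
features, with the topology, validation and longitudinal statistics needed to
study how the cortical "architectome" develops, ages, and responds to
early-life stress.

## Who this is for

Researchers analysing regional magnetization-transfer-ratio (MTR) maps — or
any scalar microstructural feature sampled per voxel within a parcellation —
who want to estimate Morphometric INverse Divergence (MIND) networks and run
a complete, reproducible analysis around them: hub and rich-club topology
against distance-preserving null models, validation against
cytoarchitecture, tract tracing and gene expression, linear mixed-effects
models of developmental and aging change, and permutation-based case–control
inference. A synthetic-cohort generator with analytic ground truth makes
every stage testable without access to MRI data.

## The model

For each scan, the MTR values of the voxels in region *i* are summarised by
a fitted Gaussian N(μᵢ, σᵢ²). The edge weight between regions *i* and *j* is

    w_ij = 1 / (1 + KL_sym(i, j)),        w ∈ (0, 1]

where KL_sym is the symmetrized Kullback–Leibler divergence between the two
regional distributions. By default each divergence is estimated after
drawing the *same* number of points from both fitted distributions, which
removes the estimator's sensitivity to region size; a closed-form analytic
path and a nonparametric k-nearest-neighbour path are also provided.

On the resulting weighted networks the package computes nodal strength
s = Σⱼ w_ij, hubs (top-*k* strength, *k* = 10), and the weighted rich-club
coefficient

    Φ = W_{>s} / W_{max,>s}

(the summed weight among hub–hub edges over the equally many strongest edges
anywhere in the network). Significance is assessed against nulls that
reshuffle edge weights only within distance bins, preserving the spatial
embedding. Longitudinal change per epoch (development, postnatal days
20–35; aging, days 63–230) is modelled as

    normalized strength ~ age + TBV + (1 | subject)
    normalized weight   ~ age + TBV + (1 | subject) + (1 | ROI-edge)

with the age *t*-statistic (Δs, Δw) as the standardized effect, and stress
effects at day 63 as the group coefficient of
`strength ~ group + sex + age + TBV`, scored by a *z* within a subject-level
group-permutation distribution.

## Worked example

```python
import numpy as np
import mindrat as mr

# a synthetic 20-region, 4-system cortex with known ground truth
models = mr.generate_parcellation(n_regions=20, n_systems=4, seed=1)
truth = mr.make_truth(models, dev_slope={"S00": 0.0008}, subject_sd=0.005)
parc = mr.Parcellation.from_region_models(models)

# one scan -> one MIND network
scan = mr.generate_scan(truth, subject_intercept=0.0, age=63.0,
                        group="control", tbv=1500.0, seed=7)
net = mr.build_mind_network(scan, parc, mr.MindParams(estimator="resampled",
                                                      n_resamples=5000, seed=7))

# topology against distance-preserving nulls
strengths = mr.nodal_strength(net)
hubs = mr.top_hubs(strengths, k=10)
rc = mr.rich_club(net, hubs)
dm = mr.edge_distances(parc.centroids())
nulls = mr.null_ensemble(net, dm, n_nulls=1000, seed=7)
phi_nulls = nulls.statistics(
    lambda nn: mr.rich_club(nn, mr.top_hubs(mr.nodal_strength(nn), k=10)).phi)
res = mr.permutation_z_p(rc.phi, phi_nulls)
dw = mr.distance_weight_correlation(net, dm)

iu = np.triu_indices(20, k=1)
r_truth = np.corrcoef(net.triu_values(), truth.true_similarity[iu])[0, 1]
print(f"recovery of planted similarity: r = {r_truth:.3f}")
print(f"rich club phi = {rc.phi:.3f} (null median {np.median(phi_nulls):.3f}, "
      f"z = {res.z:.1f}, p = {res.p:.2g})")
print(f"distance-weight correlation: r = {dw.pearson_r:.3f}")
```

Output:

```
recovery of planted similarity: r = 0.963
rich club phi = 0.917 (null median 0.847, z = 1.9, p = 0.045)
distance-weight correlation: r = -0.841
```

The estimated network recovers the planted similarity structure almost
exactly (r = 0.963); hub–hub edges carry more weight than the
distance-matched null expectation (Φ = 0.917 vs a null median of 0.847);
and edge weights fall with spatial distance (r = −0.841), as the generator's
proximity–similarity coupling dictates.

## Command-line pipeline

The same stages run end-to-end from a shell:

```bash
mindrat simulate --out-dir run --seed 1     # synthetic cohort + references
mindrat networks --out-dir run              # per-scan networks + medians
mindrat analyze  --out-dir run              # topology/validation/inference
mindrat report   --out-dir run              # print the JSON report bundle
```

All outputs are CSV/JSON with a manifest of seeds and checksums; a TOML
config file (`--config`) can override any `PipelineConfig` field.

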