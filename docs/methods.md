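# Methods

This note documents the models and procedures implemented in `mindrat`,
the assumptions they make, the defaults and why they were chosen, and what
the synthetic-data tests do and do not demonstrate.

## Network estimation

**Model.** Each region's voxel-level MTR values are treated as draws from a
Gaussian N(μᵢ, σᵢ²), fitted by sample mean and sample SD (n−1 denominator).
The edge weight between regions i and j is w = 1/(1 + KL_sym), with KL_sym
the mean of the two directed Gaussian Kullback–Leibler divergences. The
symmetrization is applied *before* the 1/(1+KL) transform; this guarantees a
symmetric network, which every downstream analysis requires. Identical
distributions give w = 1; w is strictly decreasing in KL_sym and bounded in
(0, 1].

**Region-size balancing.** The divergence estimate must not depend on how
many voxels a region happens to contain. The "resampled" estimator therefore
draws the same number of points (default 5,000) from each fitted Gaussian
before estimating the divergence. Two divergence estimators operate on the
draws:

* `method="refit"` (default): refit a Gaussian to each resample by sample
  moments and evaluate the closed form on the refits. This is unbiased to
  O(1/n) and accurate to well under 0.1 nats at n = 5,000 across mean
  separations up to 2σ and SD ratios up to 2.
* `method="knn"`: the nonparametric k-nearest-neighbour density estimator
  (k = 3), which makes no distributional assumption. We measured its bias
  directly: accurate for equal-SD pairs, but it systematically
  underestimates divergences once the narrower sample no longer covers the
  wider one's tails (−0.17 to −0.44 nats at SD ratio 2, n = 5,000; larger k
  and rank/CDF-transform variants are no better, and KDE plug-in estimators
  overshoot instead). Since the pipeline fits Gaussians in any case, the
  refit estimator is the default; the k-NN path is retained for users who
  want a distribution-free check at moderate divergences.

The closed form on the original fits (`estimator="analytic"`) is the exact
limit of the resampled path and is used as the fast path for large
simulation studies.

**Numerical safeguards.** Fitted SDs are floored at 10⁻⁶ of the scan's
global feature SD so near-degenerate regions cannot produce unbounded
divergences; regions with *exactly* constant values have no estimable
distribution and are dropped (and reported) rather than floored. Regions
with fewer than `min_voxels` (default 20) voxels are dropped and listed in
the network metadata. Negative k-NN estimates truncate to 0, preserving
w ≤ 1. Per-edge resampling seeds derive from (scan seed, sorted region
pair), so results are independent of pair evaluation order.

## Topology and null models

Nodal strength is the sum of a region's off-diagonal incident weights; hubs
are the k = 10 highest-strength regions (ties broken by label order, so hub
sets are deterministic). The weighted rich-club coefficient divides the
summed weight of hub–hub edges by the sum of the equally many strongest
edge weights anywhere in the network; both sums run over unordered pairs
(the conventional ordered-pair count, 90 for 10 hubs, is reported alongside
— the factor of two cancels in the ratio).

Null networks preserve the spatial embedding: unique edges are sorted by
Euclidean centroid distance into equal-count bins (default 3:
proximal/intermediate/distal; remainder edges join the proximal-most bins;
ties resolve by label pair), and weights are permuted only within bins.
Each bin's weight multiset is conserved exactly. At study scale
(20+ regions) the null networks' distance–weight correlation stays within
0.1 of the source network's; with many fewer regions the bins are too
coarse for that bound, which is why the corresponding test runs at 20
regions. Ensembles are lazy — nulls are regenerated deterministically from
(source, bins, seed) — so 10,000-null ensembles cost one network of memory.

Permutation p-values use the add-one convention,
p = (1 + #{null ≥ observed}) / (1 + n): the smallest reportable p with
10,000 nulls is 1.0 × 10⁻⁴, and a permutation test can never report p = 0.
z is the observed statistic's standard score within the nulls; a zero null
SD leaves z undefined (signalled) while p is still returned.

## Validation against external references

* **Distance**: Pearson correlation (Spearman as sensitivity) between edge
  weight and inter-centroid Euclidean distance over unique edges.
* **Cytoarchitecture**: percentage of intraclass (same cortical type) edges
  among the ⌈d·E⌉ top-weighted edges across densities d = 1%…10% (0% has no
  edges; rank-based, hence invariant to monotone weight transforms), and
  rank-based (Mann–Whitney) comparisons of weights between class-pair
  categories with Benjamini–Hochberg correction.
* **Tract tracing**: the Jaccard index of ordinal connection profiles —
  for pair (i, j), over third regions k, matching nonzero weights count as
  intersection and any-nonzero as union. The pair's own direct edge is
  excluded (it has no meaning in a similarity-of-profiles reading), and
  zero–zero agreements do not count by default (`count_zero_matches`
  exposes the alternative). Monotone transforms of the ordinal levels (such
  as log₁₀) cannot change equality or nonzero patterns, so no transform is
  applied. Alignment with MIND weights is Spearman's ρ, tested against the
  distance-preserving nulls.
* **Expression**: pairwise Pearson correlation of regional expression
  profiles, then Spearman alignment with edge weights against the same
  nulls. Constant profiles make the alignment undefined and are signalled.
* **Atlas crosswalk**: reference-space edge weight = median over all
  source-pair weights mapping to a reference pair; subdivisions of one
  reference region contribute nothing off-diagonal; unmapped sources are
  dropped with a warning.

## Longitudinal and case–control inference

Epochs follow the study design: development spans postnatal days 20–35 and
aging 63–230, both inclusive. "Normalized" responses are z-scored (sample
SD) across the observations entering each fit, making t-statistics
comparable across units. Node-level models are linear mixed models with a
subject random intercept fitted by REML; edge-level models pool the
ROI-level edges between two systems and add an ROI-edge random intercept
(subject and edge enter as crossed variance components). Singular or
non-converging fits fall back to ordinary least squares with a flag;
designs with a single timepoint per subject or a single ROI-edge cannot
identify the random effect and use the fallback directly. Node-level change
is flagged at |t| > 2 and edge-level change at |t| > 3.3; both thresholds
are parameters.

Case–control effects at day 63 are the group coefficient of
`normalized value ~ group + sex + age + TBV` (plus an ROI-edge random
intercept at the edge level); covariates that are constant in a given
design (e.g. a single-sex cohort) are dropped from the formula. The
permutation null shuffles group labels at the subject level — all scans of
a subject move together, which with one scan per subject reduces to
scan-level shuffling — and significance is |z| > 1.96 in the permuted
effect distribution. The stress–development coupling is the Pearson
correlation between edge-level stress effects and developmental Δw, tested
by permuting the edge assignment of the effects.

Strength distributions across timepoints are compared with a
Kruskal–Wallis omnibus on per-region median strengths and Dunn's pairwise
post-hoc test (tie-corrected rank-sum z statistics, two-sided normal
p-values, BH-adjusted). Dunn's test is implemented here because no
installed package provides it.

## The synthetic-data generator

The generator emulates the structure of a longitudinal rat MRI study:

* **Regions and systems**: regions are assigned to systems in contiguous
  blocks; systems cluster spatially; regional means follow a smooth spatial
  gradient plus a system offset plus independent noise, and regional SDs
  follow their own smooth gradient — so spatially close regions have
  similar full generative distributions, planting the proximity–similarity
  coupling real cortical data show. Default MTR means sit near 0.45 with
  SDs near 0.025 (dimensionless MTR units), and region sizes of a few
  hundred voxels, in the range typical of rodent cortical parcellations.
* **Age and group effects**: per-system mean slopes apply piecewise —
  a development slope over days 20–35, a plateau, and an aging slope from
  day 63 — and group offsets apply to stressed animals from day 63 onward,
  so the adult case–control contrast is well-posed. Defaults plant a
  development slope of 8 × 10⁻⁴ MTR/day and a stress offset of −0.01 MTR
  units on one target system: large enough that the planted direction of
  the *network-level* response is unambiguous, small relative to regional
  SDs.
* **Subjects**: intercepts are drawn once per subject (SD 5 × 10⁻³) and
  reused across timepoints; per-scan seeds derive from (cohort seed,
  subject, timepoint), so any scan is reproducible in isolation. Brain
  volumes grow mildly with age around a subject baseline.
* **Reference assets**: ordinal tract matrices, cortical-type tables,
  expression profiles and atlas crosswalks are generated from the same
  planted similarity with a controllable noise level, so external-reference
  alignments have known sign.

Because a subject intercept (and any global volume effect) shifts *all*
regional means equally, it cancels in between-region divergences: network
measures carry little subject-level variance by construction, and mixed
models on synthetic strengths typically estimate near-zero random-effect
variance. This is a property of the generative model, not a bug — planted
slope and group effects act through *relative* mean shifts.

**Sign conventions for recovery tests.** A planted positive mean slope on
one system raises or lowers that system's *strength* depending on whether
the shift moves it toward or away from the rest of the network's feature
distribution. Recovery tests therefore derive the expected direction from
the analytic truth (true strengths at the epoch endpoints) rather than from
the slope's sign.

**What the generator does not emulate**: spatial autocorrelation of voxel
noise within a region, non-Gaussian or skewed MTR distributions, scanner or
session effects, litter structure, motion artefacts, and registration
error. Passing recovery and calibration tests therefore shows the
statistical machinery is correct under the stated model, not that the
pipeline is robust to every property of real MRI data.

## Problem sizes

Tests and the acceptance script run at the study's design scale for a
single unit of analysis — networks of 20 regions in 4 systems, cohorts of
12 subjects over 4 timepoints, 500 voxels per region, 5,000 resamples —
with repetition counts chosen per check: 50 cohorts for recovery and
calibration rates, 400 small networks for rich-club calibration, 200 runs
for coupling calibration, 10,000 nulls and permutations where a single run
is assessed, and 100–200 permutations per fit where a rate over many
cohorts is the quantity of interest.

## Known limitations

* The refit divergence estimator assumes the Gaussian model is adequate;
  heavy-tailed regional distributions would bias both it and the fits
  themselves. The k-NN path relaxes the assumption at the cost of the
  documented tail bias.
* Crossed random effects use variance components in a single-group layout
  (statsmodels MixedLM); exact degrees of freedom are not chased, which is
  why t-statistics rather than mixed-model p-values are the primary
  standardized effect.
* Hemisphere is metadata only; the network takes whatever regions the
  parcellation lists and applies no homologue merging.
* Only a single feature per voxel is supported (no multivariate networks).
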