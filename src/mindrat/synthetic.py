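"""Synthetic cohort generator with known ground truth.

Emulates the study conditions of a longitudinal rat MRI experiment: each
cortical region contributes a Gaussian cloud of magnetization-transfer-ratio
(MTR) voxel values; regional means drift with age (a development epoch and an
aging epoch with separate per-system slopes), shift under early-life stress,
scale weakly with total brain volume, and carry subject-specific random
intercepts. The analytic similarity between two regions' generative Gaussians
(w = 1/(1 + symmetrized KL)) is the planted ground truth every downstream
estimator is tested against.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._common import derive_seed

#: Ages (postnatal days) delimiting the two modelled epochs.
DEV_EPOCH = (20.0, 35.0)
AGING_EPOCH = (63.0, 230.0)

#: Stress offsets apply from this age onward (adult contrast is at PND 63).
DEFAULT_STRESS_ONSET = 63.0


@dataclass
class GenerativeRegionModel:
    """Gaussian generative model for one region's MTR voxel values."""

    region_id: str
    system_id: str
    centroid: np.ndarray  # 3-vector, abstract spatial units
    mu: float  # feature mean (MTR, dimensionless)
    sigma: float  # feature SD, > 0
    n_voxels: int

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.shape != (3,) or not np.all(np.isfinite(self.centroid)):
            raise ValueError(f"centroid must be a finite 3-vector ({self.region_id})")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0 ({self.region_id})")
        if self.n_voxels < 10:
            raise ValueError(f"n_voxels must be >= 10 ({self.region_id})")


def true_edge_weight(model_i: GenerativeRegionModel,
                     model_j: GenerativeRegionModel) -> float:
    """Analytic edge weight 1/(1 + KLsym) between two generative Gaussians.

    KLsym is the average of the two directed closed-form Gaussian KL
    divergences; identical models give weight 1.
    """
    kl_ij = _gaussian_kl(model_i.mu, model_i.sigma, model_j.mu, model_j.sigma)
    kl_ji = _gaussian_kl(model_j.mu, model_j.sigma, model_i.mu, model_i.sigma)
    return 1.0 / (1.0 + 0.5 * (kl_ij + kl_ji))


def _gaussian_kl(mu_p, sigma_p, mu_q, sigma_q):
    return (math.log(sigma_q / sigma_p)
            + (sigma_p ** 2 + (mu_p - mu_q) ** 2) / (2.0 * sigma_q ** 2)
            - 0.5)


@dataclass
class GenerativeTruth:
    """Planted similarity structure and effect parameters for a cohort."""

    region_models: list[GenerativeRegionModel]
    true_similarity: np.ndarray
    dev_slope: dict[str, float] = field(default_factory=dict)
    age_slope: dict[str, float] = field(default_factory=dict)
    group_offset: dict[str, float] = field(default_factory=dict)
    subject_sd: float = 0.0
    tbv_coef: float = 0.0
    stress_onset_age: float = DEFAULT_STRESS_ONSET

    def __post_init__(self):
        n = len(self.region_models)
        self.true_similarity = np.asarray(self.true_similarity, dtype=float)
        if self.true_similarity.shape != (n, n):
            raise ValueError("true_similarity shape must match region count")
        if not np.allclose(self.true_similarity, self.true_similarity.T):
            raise ValueError("true_similarity must be symmetric")
        if not np.allclose(np.diag(self.true_similarity), 1.0):
            raise ValueError("true_similarity must have unit diagonal")
        off = self.true_similarity[~np.eye(n, dtype=bool)]
        if n > 1 and not (np.all(off > 0) and np.all(off <= 1)):
            raise ValueError("true_similarity entries must lie in (0, 1]")
        for d in (self.dev_slope, self.age_slope, self.group_offset):
            if not all(np.isfinite(v) for v in d.values()):
                raise ValueError("planted effect parameters must be finite")
        if not (np.isfinite(self.subject_sd) and self.subject_sd >= 0):
            raise ValueError("subject_sd must be finite and >= 0")

    @property
    def labels(self) -> list[str]:
        return [m.region_id for m in self.region_models]

    @property
    def systems(self) -> list[str]:
        return [m.system_id for m in self.region_models]

    def region_mean(self, model: GenerativeRegionModel, age: float,
                    group: str, tbv: float, subject_intercept: float) -> float:
        """Adjusted generative mean for one region at the given covariates."""
        mu = model.mu + subject_intercept + self.tbv_coef * tbv
        dev = self.dev_slope.get(model.system_id, 0.0)
        aging = self.age_slope.get(model.system_id, 0.0)
        # Piecewise-linear age trajectory: development slope over PND 20-35,
        # plateau to PND 63, aging slope thereafter.
        mu += dev * (min(age, DEV_EPOCH[1]) - DEV_EPOCH[0])
        mu += aging * max(0.0, age - AGING_EPOCH[0])
        if group == "stressed" and age >= self.stress_onset_age:
            mu += self.group_offset.get(model.system_id, 0.0)
        return mu

    def to_json(self, path) -> None:
        payload = {
            "region_models": [
                {"region_id": m.region_id, "system_id": m.system_id,
                 "centroid": m.centroid.tolist(), "mu": m.mu,
                 "sigma": m.sigma, "n_voxels": int(m.n_voxels)}
                for m in self.region_models
            ],
            "true_similarity": self.true_similarity.tolist(),
            "dev_slope": self.dev_slope,
            "age_slope": self.age_slope,
            "group_offset": self.group_offset,
            "subject_sd": self.subject_sd,
            "tbv_coef": self.tbv_coef,
            "stress_onset_age": self.stress_onset_age,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GenerativeTruth":
        with open(path) as fh:
            d = json.load(fh)
        models = [GenerativeRegionModel(
            region_id=m["region_id"], system_id=m["system_id"],
            centroid=np.array(m["centroid"]), mu=m["mu"], sigma=m["sigma"],
            n_voxels=m["n_voxels"]) for m in d["region_models"]]
        return cls(region_models=models,
                   true_similarity=np.array(d["true_similarity"]),
                   dev_slope=d["dev_slope"], age_slope=d["age_slope"],
                   group_offset=d["group_offset"], subject_sd=d["subject_sd"],
                   tbv_coef=d["tbv_coef"],
                   stress_onset_age=d["stress_onset_age"])


@dataclass
class CohortSpec:
    """Design of a synthetic cohort: subjects, timepoints, factor allocations."""

    n_subjects: int
    timepoints: list[float]
    groups: dict[str, float] = field(default_factory=lambda: {"control": 1.0})
    sexes: dict[str, float] = field(default_factory=lambda: {"male": 1.0})
    seed: int = 0
    missingness: float = 0.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        tps = list(self.timepoints)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        for name, alloc in (("groups", self.groups), ("sexes", self.sexes)):
            if not math.isclose(sum(alloc.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} allocation fractions must sum to 1")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")


def generate_parcellation(n_regions: int, n_systems: int,
                          seed: int) -> list[GenerativeRegionModel]:
    """Generate region models grouped into spatially clustered systems.

    Regions are assigned to systems in contiguous blocks. System centers are
    scattered in a 10-unit cube; regions cluster around their system center,
    and generative means follow a smooth spatial gradient plus a system
    offset plus independent noise, so spatially close regions have similar
    distributions (the planted proximity-similarity coupling).
    """
    if n_systems > n_regions:
        raise ValueError("n_systems cannot exceed n_regions")
    if n_regions < 1 or n_systems < 1:
        raise ValueError("n_regions and n_systems must be positive")
    rng = np.random.default_rng(seed)

    # contiguous, near-equal blocks
    sizes = np.full(n_systems, n_regions // n_systems)
    sizes[: n_regions % n_systems] += 1
    system_centers = rng.uniform(0.0, 10.0, size=(n_systems, 3))
    gradient = rng.normal(size=3)
    gradient /= np.linalg.norm(gradient)
    sigma_gradient = rng.normal(size=3)
    sigma_gradient /= np.linalg.norm(sigma_gradient)
    system_offsets = rng.normal(0.0, 0.02, size=n_systems)

    models: list[GenerativeRegionModel] = []
    width = len(str(n_regions))
    r = 0
    for s in range(n_systems):
        for _ in range(sizes[s]):
            centroid = system_centers[s] + rng.normal(0.0, 0.8, size=3)
            # smooth spatial gradient in mu (~0.01 MTR units per spatial unit)
            mu = (0.45 + 0.012 * float(gradient @ centroid)
                  + system_offsets[s] + rng.normal(0.0, 0.004))
            # sigma follows its own smooth spatial gradient so that nearby
            # regions have similar full distributions, not just means
            sigma = float(np.clip(0.025
                                  + 0.0012 * float(sigma_gradient @ centroid)
                                  + rng.normal(0.0, 0.001), 0.012, 0.04))
            n_vox = int(rng.integers(300, 900))
            models.append(GenerativeRegionModel(
                region_id=f"R{r:0{width}d}", system_id=f"S{s:02d}",
                centroid=centroid, mu=float(mu), sigma=sigma, n_voxels=n_vox))
            r += 1
    return models


def make_truth(region_models: list[GenerativeRegionModel], *,
               dev_slope: dict[str, float] | None = None,
               age_slope: dict[str, float] | None = None,
               group_offset: dict[str, float] | None = None,
               subject_sd: float = 0.0, tbv_coef: float = 0.0,
               stress_onset_age: float = DEFAULT_STRESS_ONSET) -> GenerativeTruth:
    """Assemble a GenerativeTruth, computing the analytic similarity matrix."""
    n = len(region_models)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = true_edge_weight(region_models[i],
                                                     region_models[j])
    return GenerativeTruth(region_models=region_models, true_similarity=sim,
                           dev_slope=dev_slope or {}, age_slope=age_slope or {},
                           group_offset=group_offset or {},
                           subject_sd=subject_sd, tbv_coef=tbv_coef,
                           stress_onset_age=stress_onset_age)


def generate_scan(truth: GenerativeTruth, subject_intercept: float, age: float,
                  group: str, tbv: float, seed: int) -> pd.DataFrame:
    """Draw one scan's voxel table (columns ``Label,MTR``) from the truth."""
    if group not in ("control", "stressed"):
        raise ValueError(f"unknown group label: {group!r}")
    lo = DEV_EPOCH[0]
    hi = AGING_EPOCH[1]
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside supported range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    labels, values = [], []
    for m in truth.region_models:
        mean = truth.region_mean(m, age, group, tbv, subject_intercept)
        vals = rng.normal(mean, m.sigma, size=m.n_voxels)
        labels.extend([m.region_id] * m.n_voxels)
        values.append(vals)
    return pd.DataFrame({"Label": labels, "MTR": np.concatenate(values)})


def generate_cohort(spec: CohortSpec, truth: GenerativeTruth
                    ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate one scan per subject x timepoint plus aligned metadata.

    Subject intercepts, group/sex assignments and baseline brain volumes are
    drawn once per subject and reused across timepoints; per-scan seeds are
    derived from the cohort seed, subject id and timepoint so individual
    scans are reproducible in isolation.

    Returns (scans, cohort) where ``scans`` maps scan_id to a voxel table and
    ``cohort`` has columns scan_id, subject, age_pnd, sex, group, tbv.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    subjects = [f"sub{idx:03d}" for idx in range(n)]
    groups = _allocate(spec.groups, n)
    sexes = _allocate(spec.sexes, n)
    intercepts = rng.normal(0.0, truth.subject_sd, size=n)
    tbv_base = rng.normal(1500.0, 40.0, size=n)  # arbitrary volume units

    scans: dict[str, pd.DataFrame] = {}
    rows = []
    for i, subj in enumerate(subjects):
        for age in spec.timepoints:
            if spec.missingness > 0 and rng.random() < spec.missingness:
                continue
            scan_id = f"{subj}_pnd{int(age):03d}"
            # brain volume grows mildly with age around the subject baseline
            tbv = float(tbv_base[i] + 0.8 * age + rng.normal(0.0, 10.0))
            scan_seed = derive_seed(spec.seed, subj, age)
            scans[scan_id] = generate_scan(truth, float(intercepts[i]), age,
                                           groups[i], tbv, scan_seed)
            rows.append({"scan_id": scan_id, "subject": subj, "age_pnd": age,
                         "sex": sexes[i], "group": groups[i], "tbv": tbv})
    cohort = pd.DataFrame(rows)
    return scans, cohort


def _allocate(fractions: dict[str, float], n: int) -> list[str]:
    """Deterministic largest-remainder allocation of n subjects to levels."""
    levels = sorted(fractions)
    counts = {lv: int(math.floor(fractions[lv] * n)) for lv in levels}
    remainders = sorted(levels, key=lambda lv: (-(fractions[lv] * n
                                                  - counts[lv]), lv))
    short = n - sum(counts.values())
    for lv in remainders[:short]:
        counts[lv] += 1
    out = []
    for lv in levels:
        out.extend([lv] * counts[lv])
    return out


#: cortical type labels cycled over systems for reference assets
_TYPE_CYCLE = ("archicortical-allocortex", "agranular-mesocortex",
               "dysgranular-mesocortex")


def generate_reference_assets(truth: GenerativeTruth, noise: float, seed: int
                              ) -> tuple[pd.DataFrame, pd.DataFrame,
                                         pd.DataFrame, pd.DataFrame]:
    """Generate external-reference stand-ins coupled to the planted similarity.

    Returns (tract, types, expression, crosswalk):

    * ``tract`` — region x region ordinal connection matrix (levels 0-3);
      at low noise, regions with similar true-similarity profiles get
      concordant connection profiles.
    * ``types`` — one cortical type label per region (systems share a type).
    * ``expression`` — region x gene profile matrix whose pairwise
      correlations rise with true similarity.
    * ``crosswalk`` — region -> reference-atlas label, adjacent same-system
      regions merged pairwise (many-to-one).
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    labels = truth.labels
    n = len(labels)
    sim = truth.true_similarity

    # Ordinal tract matrix: noisy latent similarity quantised to levels 0..3.
    latent = sim + noise * rng.normal(size=(n, n))
    np.fill_diagonal(latent, np.nan)
    flat = latent[~np.isnan(latent)]
    qs = np.nanquantile(flat, [0.4, 0.6, 0.8])
    ordinal = np.digitize(np.nan_to_num(latent, nan=0.0), qs)
    np.fill_diagonal(ordinal, 0)
    tract = pd.DataFrame(ordinal, index=labels, columns=labels)

    # Cortical types: per system, cycled through the three classes.
    systems = sorted(set(truth.systems))
    type_of_system = {s: _TYPE_CYCLE[i % len(_TYPE_CYCLE)]
                      for i, s in enumerate(systems)}
    types = pd.DataFrame({
        "region_id": labels,
        "type": [type_of_system[s] for s in truth.systems],
        "excluded": False,
    })

    # Expression: each region's profile is its (noisy) similarity row, so
    # profile correlations track true similarity.
    expr = sim + noise * rng.normal(size=(n, n))
    expression = pd.DataFrame(expr, index=labels,
                              columns=[f"gene{g:03d}" for g in range(n)])

    # Crosswalk: merge adjacent same-system regions pairwise.
    ref_labels, counter = [], 0
    i = 0
    sys_list = truth.systems
    while i < n:
        if i + 1 < n and sys_list[i] == sys_list[i + 1]:
            ref = f"REF{counter:03d}"
            ref_labels.extend([ref, ref])
            i += 2
        else:
            ref_labels.append(f"REF{counter:03d}")
            i += 1
        counter += 1
    crosswalk = pd.DataFrame({"source": labels, "reference": ref_labels})
    return tract, types, expression, crosswalk
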