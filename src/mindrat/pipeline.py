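"""End-to-end orchestration: simulate -> networks -> analyze -> report.

Each stage reads and writes plain CSV/JSON under a working directory and
records the seeds and parameters it used, so any stage can be re-run
idempotently and every statistic in the final report is traceable to its
inputs. Stage seeds derive from the single global seed by stable hashing,
keeping stages reproducible independently of one another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._common import PipelineError, derive_seed
from . import inference, synthetic, topology, validation
from .io import Parcellation, edge_distances, read_voxel_table, write_voxel_table
from .mind import MindParams, MINDNetwork, build_mind_network, median_network

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables for a pipeline run (defaults follow the study design)."""

    out_dir: str = "mindrat_run"
    seed: int = 0
    # seed for the generative truth; defaults to deriving from `seed`. Set it
    # explicitly to draw independent cohorts from one shared truth.
    truth_seed: int | None = None
    # synthetic cohort
    n_regions: int = 20
    n_systems: int = 4
    n_subjects: int = 12
    timepoints: tuple = (20.0, 35.0, 63.0, 230.0)
    groups: dict = field(default_factory=lambda: {"control": 0.5,
                                                  "stressed": 0.5})
    sexes: dict = field(default_factory=lambda: {"female": 0.5, "male": 0.5})
    subject_sd: float = 0.005
    dev_slope: float = 0.0008    # MTR units per day, planted in one system
    age_slope: float = -0.0002
    group_offset: float = -0.01
    reference_noise: float = 0.05
    # estimator
    estimator: str = "resampled"
    n_resamples: int = 5_000
    knn_k: int = 3
    min_voxels: int = 20
    sigma_floor_frac: float = 1e-6
    # analysis
    hub_k: int = 10
    n_bins: int = 3
    n_nulls: int = 10_000
    n_perm_group: int = 1_000
    n_perm_coupling: int = 10_000
    densities: tuple = validation.DEFAULT_DENSITIES
    node_t_threshold: float = inference.NODE_T_THRESHOLD
    edge_t_threshold: float = inference.EDGE_T_THRESHOLD
    run_nulls: bool = True

    def __post_init__(self):
        for name in ("n_regions", "n_systems", "n_subjects", "n_resamples",
                     "hub_k", "n_bins", "n_nulls", "n_perm_group",
                     "n_perm_coupling", "min_voxels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not all(0 < d <= 1 for d in self.densities):
            raise ValueError("densities must lie in (0, 1]")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a TOML (or JSON) config file, applying keyword overrides."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            import tomllib

            data = tomllib.loads(text)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def mind_params(self) -> MindParams:
        return MindParams(estimator=self.estimator,
                          n_resamples=self.n_resamples, k=self.knn_k,
                          min_voxels=self.min_voxels,
                          sigma_floor_frac=self.sigma_floor_frac,
                          seed=derive_seed(self.seed, "networks"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_truth(config: PipelineConfig) -> synthetic.GenerativeTruth:
    """Build the planted truth for a config: slopes/offsets target system S00,
    the aging slope additionally targets S01 with opposite sign (so epoch
    coupling has planted anticorrelation to recover)."""
    base = config.truth_seed if config.truth_seed is not None else config.seed
    models = synthetic.generate_parcellation(
        config.n_regions, config.n_systems, seed=derive_seed(base,
                                                             "parcellation"))
    systems = sorted({m.system_id for m in models})
    dev = {systems[0]: config.dev_slope}
    age = {systems[0]: config.age_slope}
    if len(systems) > 1:
        age[systems[1]] = -config.age_slope
    offset = {systems[0]: config.group_offset}
    return synthetic.make_truth(models, dev_slope=dev, age_slope=age,
                                group_offset=offset,
                                subject_sd=config.subject_sd)


def run_simulate(config: PipelineConfig) -> dict:
    """Write the synthetic cohort, truth, parcellation and reference assets."""
    out = Path(config.out_dir)
    try:
        (out / "scans").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineError(f"cannot create output dir {out}: {exc}") from exc

    truth = default_truth(config)
    spec = synthetic.CohortSpec(n_subjects=config.n_subjects,
                                timepoints=list(config.timepoints),
                                groups=dict(config.groups),
                                sexes=dict(config.sexes),
                                seed=derive_seed(config.seed, "cohort"))
    scans, cohort = synthetic.generate_cohort(spec, truth)
    tract, types, expression, crosswalk = synthetic.generate_reference_assets(
        truth, noise=config.reference_noise,
        seed=derive_seed(config.seed, "references"))

    manifest = {"seed": config.seed, "stage": "simulate", "files": {}}
    for scan_id, voxels in scans.items():
        path = out / "scans" / f"{scan_id}.csv"
        write_voxel_table(voxels, path)
        manifest["files"][str(path.relative_to(out))] = _sha256(path)
    cohort.to_csv(out / "cohort.csv", index=False)
    truth.to_json(out / "truth.json")
    Parcellation.from_region_models(truth.region_models).to_json(
        out / "parcellation.json")
    tract.to_csv(out / "tract.csv")
    types.to_csv(out / "types.csv", index=False)
    expression.to_csv(out / "expression.csv")
    crosswalk.to_csv(out / "crosswalk.csv", index=False)
    for name in ("cohort.csv", "truth.json", "parcellation.json", "tract.csv",
                 "types.csv", "expression.csv", "crosswalk.csv"):
        manifest["files"][name] = _sha256(out / name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("simulate: wrote %d scans to %s", len(scans), out)
    return manifest


def run_networks(config: PipelineConfig) -> dict:
    """Build per-scan MIND networks plus per-timepoint/group medians."""
    out = Path(config.out_dir)
    cohort_path = out / "cohort.csv"
    if not cohort_path.exists():
        raise PipelineError(f"missing cohort table {cohort_path}")
    cohort = pd.read_csv(cohort_path)
    parcellation = Parcellation.from_json(out / "parcellation.json")
    params = config.mind_params()
    (out / "networks").mkdir(exist_ok=True)

    networks: dict[str, MINDNetwork] = {}
    qc = {"params": dataclasses.asdict(params), "dropped_regions": {}}
    for scan_id in cohort["scan_id"]:
        scan_path = out / "scans" / f"{scan_id}.csv"
        if not scan_path.exists():
            raise PipelineError(f"missing voxel table for scan {scan_id}")
        voxels = read_voxel_table(scan_path)
        scan_params = dataclasses.replace(
            params, seed=derive_seed(params.seed, scan_id))
        net = build_mind_network(voxels, parcellation, scan_params)
        networks[scan_id] = net
        net.to_csv(out / "networks" / f"{scan_id}.csv")
        if net.meta["dropped_regions"]:
            qc["dropped_regions"][scan_id] = net.meta["dropped_regions"]

    (out / "medians").mkdir(exist_ok=True)
    for age, sub in cohort.groupby("age_pnd"):
        med = median_network([networks[s] for s in sub["scan_id"]])
        med.to_csv(out / "medians" / f"pnd{int(age):03d}.csv")
        for group, gsub in sub.groupby("group"):
            med = median_network([networks[s] for s in gsub["scan_id"]])
            med.to_csv(out / "medians" / f"pnd{int(age):03d}_{group}.csv")
    (out / "networks_qc.json").write_text(json.dumps(qc, indent=1))
    log.info("networks: built %d networks", len(networks))
    return qc


def load_networks(config: PipelineConfig) -> tuple[dict, pd.DataFrame]:
    out = Path(config.out_dir)
    cohort = pd.read_csv(out / "cohort.csv")
    networks = {s: MINDNetwork.from_csv(out / "networks" / f"{s}.csv")
                for s in cohort["scan_id"]}
    return networks, cohort


def strength_table(networks: dict, cohort: pd.DataFrame) -> pd.DataFrame:
    """Long table of per-scan nodal strengths joined to scan metadata."""
    rows = []
    for scan_id, net in networks.items():
        s = topology.nodal_strength(net)
        for region, val in s.items():
            rows.append({"scan_id": scan_id, "unit": region, "value": val})
    return pd.DataFrame(rows).merge(cohort, on="scan_id")


def edge_table(networks: dict, cohort: pd.DataFrame,
               systems: dict[str, str]) -> pd.DataFrame:
    """Long table of per-scan ROI-edge weights with system-pair labels."""
    rows = []
    for scan_id, net in networks.items():
        for a, b, w in net.triu_pairs():
            pair = "--".join(sorted((systems[a], systems[b])))
            rows.append({"scan_id": scan_id, "roi_edge": f"{a}--{b}",
                         "system_pair": pair, "value": w})
    return pd.DataFrame(rows).merge(cohort, on="scan_id")


def node_slopes(strengths: pd.DataFrame, epoch: str,
                t_threshold: float = inference.NODE_T_THRESHOLD
                ) -> list[inference.SlopeResult]:
    sub = inference.select_epoch(strengths, epoch)
    results = [inference.fit_node_slope(g, region, epoch=epoch,
                                        t_threshold=t_threshold)
               for region, g in sub.groupby("unit")]
    return inference.adjust_slopes_fdr(results)


def system_edge_slopes(edges: pd.DataFrame, epoch: str,
                       t_threshold: float = inference.EDGE_T_THRESHOLD
                       ) -> list[inference.SlopeResult]:
    sub = inference.select_epoch(edges, epoch)
    results = [inference.fit_system_edge_slope(g, tuple(pair.split("--")),
                                               epoch=epoch,
                                               t_threshold=t_threshold)
               for pair, g in sub.groupby("system_pair")]
    return inference.adjust_slopes_fdr(results)


def run_analysis(config: PipelineConfig) -> dict:
    """Topology, validation and inference; returns (and writes) the report."""
    out = Path(config.out_dir)
    networks, cohort = load_networks(config)
    parcellation = Parcellation.from_json(out / "parcellation.json")
    systems = parcellation.systems()
    distances = edge_distances(parcellation.centroids())
    report: dict = {"seed": config.seed,
                    "params": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in dataclasses.asdict(config).items()}}

    # normative network: median across the full cohort's scans
    normative = median_network(list(networks.values()))
    strengths = topology.nodal_strength(normative)
    hubs = topology.top_hubs(strengths, k=config.hub_k)
    rc = topology.rich_club(normative, hubs)
    report["topology"] = {"hubs": hubs, "phi": rc.phi,
                          "n_hub_pairs_ordered": rc.n_hub_pairs_ordered}
    strengths.to_csv(out / "strength.csv")

    dist_used = distances if set(distances.labels) == set(normative.labels) \
        else None
    nulls = None
    if config.run_nulls and dist_used is not None:
        nulls = topology.null_ensemble(normative, dist_used,
                                       n_nulls=config.n_nulls,
                                       seed=derive_seed(config.seed, "nulls"),
                                       n_bins=config.n_bins)
        phi_nulls = nulls.statistics(
            lambda nn: topology.rich_club(
                nn, topology.top_hubs(topology.nodal_strength(nn),
                                      k=config.hub_k)).phi)
        pr = topology.permutation_z_p(rc.phi, phi_nulls)
        report["topology"].update({"phi_null_median": float(np.median(phi_nulls)),
                                   "phi_z": pr.z, "phi_p": pr.p})

    # validation against references
    dw = validation.distance_weight_correlation(normative, distances)
    report["validation"] = {"distance_weight_r": dw.pearson_r,
                            "distance_weight_rho": dw.spearman_rho}
    tract_path = out / "tract.csv"
    if tract_path.exists() and nulls is not None:
        tract = pd.read_csv(tract_path, index_col=0)
        tr = validation.tract_mind_alignment(normative, tract, nulls)
        report["validation"]["tract_rho"] = tr.observed
        report["validation"]["tract_z"] = tr.z
        report["validation"]["tract_p"] = tr.p
    types_path = out / "types.csv"
    if types_path.exists():
        types = pd.read_csv(types_path)
        curve = validation.intraclass_edge_curve(normative, types,
                                                 config.densities)
        curve.to_csv(out / "intraclass_curve.csv", index=False)
        report["validation"]["intraclass_mean_pct"] = float(
            curve["pct_intraclass"].mean())
        pairs = validation.class_pair_weight_test(normative, types)
        pairs.to_csv(out / "class_pair_tests.csv", index=False)
    expr_path = out / "expression.csv"
    if expr_path.exists() and nulls is not None:
        expression = pd.read_csv(expr_path, index_col=0)
        ea = validation.expression_alignment(normative, expression, nulls)
        report["validation"]["expression_rho"] = ea.observed
        report["validation"]["expression_p"] = ea.p

    # longitudinal slopes and epoch coupling
    st = strength_table(networks, cohort)
    et = edge_table(networks, cohort, systems)
    slope_rows = []
    epoch_results = {}
    for epoch in ("development", "aging"):
        nodes = node_slopes(st, epoch, config.node_t_threshold)
        edges_r = system_edge_slopes(et, epoch, config.edge_t_threshold)
        epoch_results[epoch] = {"nodes": nodes, "edges": edges_r}
        slope_rows.extend(dataclasses.asdict(r) for r in nodes + edges_r)
    pd.DataFrame(slope_rows).to_csv(out / "slopes.csv", index=False)
    r_nodes, p_nodes, _ = inference.epoch_coupling(
        epoch_results["development"]["nodes"], epoch_results["aging"]["nodes"])
    r_edges, p_edges, _ = inference.epoch_coupling(
        epoch_results["development"]["edges"], epoch_results["aging"]["edges"])
    report["development"] = {
        "node_coupling_r": r_nodes, "node_coupling_p": p_nodes,
        "edge_coupling_r": r_edges, "edge_coupling_p": p_edges,
        "n_sig_nodes_dev": sum(r.significant for r in
                               epoch_results["development"]["nodes"]),
        "n_sig_edges_dev": sum(r.significant for r in
                               epoch_results["development"]["edges"])}

    # case-control contrast at the adult timepoint
    adult = cohort[cohort["age_pnd"] == 63.0]
    report["stress"] = {}
    if adult["group"].nunique() >= 2:
        adult_scans = set(adult["scan_id"])
        st_adult = st[st["scan_id"].isin(adult_scans)]
        effects = []
        for region, g in st_adult.groupby("unit"):
            res = inference.permuted_group_null(
                g, region, n_perm=config.n_perm_group,
                seed=derive_seed(config.seed, "group", region))
            effects.append(res)
        pd.DataFrame([dataclasses.asdict(e) for e in effects]).to_csv(
            out / "group_effects.csv", index=False)
        report["stress"]["n_sig_regions"] = sum(e.significant for e in effects)

        et_adult = et[et["scan_id"].isin(adult_scans)]
        edge_effects = {pair: inference.fit_group_effect(g, pair,
                                                         edge_level=True)
                        for pair, g in et_adult.groupby("system_pair")}
        dev_t = {r.unit: r.t_stat
                 for r in epoch_results["development"]["edges"]
                 if not r.flagged}
        shared = sorted(set(edge_effects) & set(dev_t))
        coup = inference.stress_development_coupling(
            {k: edge_effects[k] for k in shared},
            {k: dev_t[k] for k in shared},
            n_perm=config.n_perm_coupling,
            seed=derive_seed(config.seed, "coupling"),
            alternative="two-sided")
        report["stress"].update({"coupling_r": coup.observed,
                                 "coupling_z": coup.z, "coupling_p": coup.p})

    # strength distributions across timepoints (per-region medians)
    med_strengths = {}
    for age, sub in cohort.groupby("age_pnd"):
        nets = [networks[s] for s in sub["scan_id"]]
        med = median_network(nets)
        med_strengths[f"pnd{int(age)}"] = topology.nodal_strength(
            median_network(nets)).to_numpy()
        del med
    h, p, dunn = inference.strength_distribution_tests(med_strengths)
    dunn.to_csv(out / "dunn_tests.csv", index=False)
    report["timepoints"] = {"kruskal_h": h, "kruskal_p": p}

    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                default=float))
    log.info("analysis: report written to %s", out / "report.json")
    return report


def run_report(config: PipelineConfig) -> dict:
    """Collate the report bundle (reads report.json written by run_analysis)."""
    path = Path(config.out_dir) / "report.json"
    if not path.exists():
        raise PipelineError(f"no report at {path}; run the analyze stage first")
    report = json.loads(path.read_text())
    return report
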