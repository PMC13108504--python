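"""Validation of similarity networks against external cortical references.

A biologically meaningful similarity network should (i) decay with spatial
distance, (ii) concentrate its strongest edges within cytoarchitectonic
classes, (iii) align with the similarity of axonal connection profiles from
tract tracing (Jaccard index over ordinal connection matrices), and (iv)
align with regional gene-expression similarity. Alignment statistics are
scored against distance-preserving null ensembles; class comparisons use
rank tests with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._common import LabeledMatrix
from .mind import MINDNetwork
from .topology import NullEnsemble, PermutationResult, permutation_z_p

log = logging.getLogger(__name__)

DEFAULT_DENSITIES = tuple(d / 100 for d in range(1, 11))  # 1%..10%


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_edges: int


def _matched_triu(network: MINDNetwork, other: LabeledMatrix
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle vectors of both matrices over the shared node set."""
    shared = [r for r in network.labels if r in set(other.labels)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared regions")
    wi = [network.index(r) for r in shared]
    oi = [other.labels.index(r) for r in shared]
    w = network.values[np.ix_(wi, wi)]
    o = other.values[np.ix_(oi, oi)]
    iu = np.triu_indices(len(shared), k=1)
    return w[iu], o[iu]


def distance_weight_correlation(network: MINDNetwork,
                                distances: LabeledMatrix) -> CorrelationResult:
    """Correlation between edge weight and Euclidean center-to-center distance.

    Pearson r is the primary statistic; Spearman rho is returned as a
    rank-based sensitivity check.
    """
    w, d = _matched_triu(network, distances)
    if len(w) < 3:
        raise ValueError("need at least 3 edges")
    pr = stats.pearsonr(d, w)
    sr = stats.spearmanr(d, w)
    return CorrelationResult(pearson_r=float(pr.statistic),
                             pearson_p=float(pr.pvalue),
                             spearman_rho=float(sr.statistic),
                             spearman_p=float(sr.pvalue), n_edges=len(w))


def jaccard_profile_similarity(tract: pd.DataFrame,
                               count_zero_matches: bool = False
                               ) -> LabeledMatrix:
    """Jaccard similarity of ordinal tract-tracing connection profiles.

    For regions i and j, over all third regions k: the intersection counts k
    where the ordinal weights agree and are both nonzero (with
    ``count_zero_matches`` the zero-zero agreements count too), the union
    counts k where either is nonzero; J = |intersection| / |union|, 0 when
    the union is empty, and J(i, i) = 1 by convention.
    """
    if tract.shape[0] != tract.shape[1] or list(tract.index) != list(tract.columns):
        raise ValueError("tract matrix must be square with matching labels")
    labels = [str(c) for c in tract.columns]
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 regions")
    m = tract.to_numpy()
    out = np.eye(n)
    for i, j in combinations(range(n), 2):
        mask = np.ones(n, dtype=bool)
        mask[[i, j]] = False
        a, b = m[i, mask], m[j, mask]
        agree = a == b
        both_nz = (a != 0) & (b != 0)
        inter = int(np.sum(agree & both_nz))
        union = int(np.sum((a != 0) | (b != 0)))
        if count_zero_matches:
            inter += int(np.sum(agree & ~both_nz & ((a == 0) & (b == 0))))
            union = len(a)
        out[i, j] = out[j, i] = inter / union if union else 0.0
    return LabeledMatrix(labels=labels, values=out, meta={"kind": "jaccard"})


def _null_spearman(other: LabeledMatrix):
    def fn(null_net: MINDNetwork) -> float:
        w, o = _matched_triu(null_net, other)
        return float(stats.spearmanr(o, w).statistic)
    return fn


def tract_mind_alignment(network: MINDNetwork, tract: pd.DataFrame,
                         nulls: NullEnsemble,
                         count_zero_matches: bool = False) -> PermutationResult:
    """Spearman alignment of tract-profile Jaccard with edge weights vs nulls."""
    jac = jaccard_profile_similarity(tract, count_zero_matches)
    w, o = _matched_triu(network, jac)
    if len(w) == 0:
        raise ValueError("no overlapping region pairs")
    observed = float(stats.spearmanr(o, w).statistic)
    null_vals = nulls.statistics(_null_spearman(jac))
    return permutation_z_p(observed, null_vals, alternative="greater")


def _clean_types(types: pd.DataFrame) -> pd.Series:
    t = types.copy()
    if "excluded" in t.columns:
        t = t[~t["excluded"].astype(bool)]
    return pd.Series(t["type"].to_numpy(), index=t["region_id"].astype(str))


def intraclass_edge_curve(network: MINDNetwork, types: pd.DataFrame,
                          densities=DEFAULT_DENSITIES) -> pd.DataFrame:
    """Percentage of same-type ("intraclass") edges among top-weighted edges.

    For each density d the ceil(d * E) highest-weight unique edges are taken
    (ties at the cut resolved by label order) and the percentage whose two
    endpoints share a cortical type is reported. Regions flagged excluded in
    the type table are removed before thresholding. Densities that round to
    zero edges are skipped with a warning.
    """
    type_of = _clean_types(types)
    keep = [r for r in network.labels if r in type_of.index]
    idx = [network.index(r) for r in keep]
    sub = network.values[np.ix_(idx, idx)]
    edges = []
    for a, b in combinations(range(len(keep)), 2):
        edges.append(((keep[a], keep[b]), sub[a, b]))
    edges.sort(key=lambda e: (-e[1], e[0]))
    n_edges = len(edges)
    rows = []
    for d in densities:
        if not 0 < d <= 1:
            raise ValueError(f"density {d} outside (0, 1]")
        m = int(np.ceil(d * n_edges))
        if m == 0:
            warnings.warn(f"density {d} yields 0 edges; skipped", stacklevel=2)
            continue
        top = edges[:m]
        intra = sum(1 for (a, b), _ in top if type_of[a] == type_of[b])
        rows.append({"density": d, "n_edges": m,
                     "pct_intraclass": 100.0 * intra / m})
    return pd.DataFrame(rows)


def class_pair_weight_test(networks, types: pd.DataFrame) -> pd.DataFrame:
    """Rank-test comparison of edge weights between cytoarchitectonic class pairs.

    Edges are categorised by their endpoint types (e.g. allo-allo, allo-meso,
    meso-meso); every pair of categories is compared with a two-sided
    Mann-Whitney U test and q-values are Benjamini-Hochberg adjusted.
    Accepts a single network or a list (edges pooled across networks).
    """
    if isinstance(networks, MINDNetwork):
        networks = [networks]
    type_of = _clean_types(types)
    buckets: dict[str, list[float]] = {}
    for net in networks:
        keep = [r for r in net.labels if r in type_of.index]
        for a, b in combinations(keep, 2):
            cat = "|".join(sorted((str(type_of[a]), str(type_of[b]))))
            buckets.setdefault(cat, []).append(
                net.values[net.index(a), net.index(b)])
    usable = {c: v for c, v in buckets.items() if len(v) >= 2}
    for c in set(buckets) - set(usable):
        warnings.warn(f"class-pair category {c!r} has < 2 edges; excluded",
                      stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least 2 class-pair categories with >= 2 edges")
    rows = []
    for c1, c2 in combinations(sorted(usable), 2):
        res = stats.mannwhitneyu(usable[c1], usable[c2],
                                 alternative="two-sided")
        rows.append({"category_a": c1, "category_b": c2,
                     "median_a": float(np.median(usable[c1])),
                     "median_b": float(np.median(usable[c2])),
                     "u_stat": float(res.statistic),
                     "p_value": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def expression_similarity(expression: pd.DataFrame) -> LabeledMatrix:
    """Pairwise Pearson correlation matrix of regional expression profiles."""
    if expression.isna().any().any():
        raise ValueError("expression table contains missing values")
    profiles = expression.to_numpy(dtype=float)
    if np.any(profiles.std(axis=1) == 0):
        raise ValueError("zero-variance expression profile; similarity undefined")
    corr = np.corrcoef(profiles)
    np.fill_diagonal(corr, 1.0)
    return LabeledMatrix(labels=[str(r) for r in expression.index],
                         values=corr, meta={"kind": "expression"})


def expression_alignment(network: MINDNetwork, expression: pd.DataFrame,
                         nulls: NullEnsemble) -> PermutationResult:
    """Spearman alignment of expression-profile similarity with edge weights."""
    sim = expression_similarity(expression)
    w, o = _matched_triu(network, sim)
    if np.std(o) == 0:
        raise ValueError("expression similarity is constant; alignment undefined")
    observed = float(stats.spearmanr(o, w).statistic)
    null_vals = nulls.statistics(_null_spearman(sim))
    return permutation_z_p(observed, null_vals, alternative="greater")


def crosswalk_aggregate(network: MINDNetwork,
                        crosswalk: pd.DataFrame) -> MINDNetwork:
    """Project a network into a reference atlas via a many-to-one crosswalk.

    The reference-space weight for a pair of reference regions is the median
    over all source-region pair weights mapping to that pair; pairs of
    subdivisions of the same reference region contribute nothing off-diagonal.
    Source regions without a mapping are dropped with a warning.
    """
    cw = dict(zip(crosswalk["source"].astype(str),
                  crosswalk["reference"].astype(str)))
    unmapped = [r for r in network.labels if r not in cw]
    if unmapped:
        warnings.warn(f"unmapped source regions dropped: {unmapped}",
                      stacklevel=2)
        log.warning("crosswalk_aggregate dropped %d regions", len(unmapped))
    mapped = [r for r in network.labels if r in cw]
    refs = sorted({cw[r] for r in mapped})
    if len(refs) < 2:
        raise ValueError("crosswalk yields fewer than 2 reference regions")
    pos = {ref: i for i, ref in enumerate(refs)}
    pools: dict[tuple[int, int], list[float]] = {}
    for a, b in combinations(mapped, 2):
        ra, rb = cw[a], cw[b]
        if ra == rb:
            continue
        key = tuple(sorted((pos[ra], pos[rb])))
        pools.setdefault(key, []).append(
            network.values[network.index(a), network.index(b)])
    out = np.eye(len(refs))
    for (i, j), vals in pools.items():
        out[i, j] = out[j, i] = float(np.median(vals))
    return MINDNetwork(labels=refs, values=out,
                       meta={"kind": "crosswalk_aggregate",
                             "n_source": len(mapped)})
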