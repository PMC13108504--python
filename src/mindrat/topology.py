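"""Weighted-network topology: strength, hubs, rich club, distance-preserving nulls.

Nodal strength s is the sum of a region's incident edge weights. Hubs are the
k highest-strength regions (k = 10 by default). The weighted rich-club
coefficient is

    phi = W_{>s} / W_{max,>s}

the total weight among hub-hub edges divided by the sum of the equally many
strongest edge weights anywhere in the network, so phi = 1 when the hub-hub
edges are exactly the network's strongest.

Null networks preserve spatial structure: unique edges are split into
equal-count distance bins (proximal / intermediate / distal by default) and
weights are reshuffled only within bins, conserving each bin's weight
multiset and hence the coarse distance-weight relationship. Observed
statistics are scored against the null ensemble with a permutation z and an
add-one permutation p-value (minimum 1/(n_nulls + 1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._common import LabeledMatrix, derive_seed
from .mind import MINDNetwork

DEFAULT_HUB_K = 10
DEFAULT_N_BINS = 3
DEFAULT_N_NULLS = 10_000

Edge = tuple[str, str]  # sorted label pair


def nodal_strength(network: MINDNetwork) -> pd.Series:
    """Per-region strength: sum of off-diagonal incident edge weights."""
    w = network.values.copy()
    np.fill_diagonal(w, 0.0)
    return pd.Series(w.sum(axis=1), index=network.labels, name="strength")


def top_hubs(strengths: pd.Series, k: int = DEFAULT_HUB_K) -> list[str]:
    """The k regions of highest strength; ties broken by ascending label."""
    if k > len(strengths):
        raise ValueError(f"k={k} exceeds number of regions ({len(strengths)})")
    order = sorted(strengths.index, key=lambda r: (-strengths[r], r))
    return order[:k]


@dataclass
class RichClubResult:
    hubs: list[str]
    phi: float
    hub_edge_sum: float  # W_{>s}
    top_edge_sum: float  # W_{max,>s}
    n_hub_pairs: int  # unordered hub-hub pairs
    n_hub_pairs_ordered: int  # parity with the k(k-1) reporting convention


def rich_club(network: MINDNetwork, hubs: list[str]) -> RichClubResult:
    """Weighted rich-club coefficient of a hub set.

    Both sums run over unordered pairs (the ordered-pair convention doubles
    numerator and denominator alike, leaving phi unchanged; the ordered count
    is reported alongside).
    """
    if len(hubs) < 2:
        raise ValueError("need at least 2 hubs")
    unknown = sorted(set(hubs) - set(network.labels))
    if unknown:
        raise ValueError(f"hubs not in network: {unknown}")
    idx = [network.index(h) for h in hubs]
    sub = network.values[np.ix_(idx, idx)]
    m = len(hubs)
    hub_sum = float(sub[np.triu_indices(m, k=1)].sum())
    n_pairs = m * (m - 1) // 2
    all_weights = np.sort(network.triu_values())[::-1]
    top_sum = float(all_weights[:n_pairs].sum())
    return RichClubResult(hubs=list(hubs), phi=hub_sum / top_sum,
                          hub_edge_sum=hub_sum, top_edge_sum=top_sum,
                          n_hub_pairs=n_pairs,
                          n_hub_pairs_ordered=m * (m - 1))


def distance_bins(distances: LabeledMatrix,
                  n_bins: int = DEFAULT_N_BINS) -> dict[Edge, int]:
    """Assign unique edges to equal-count distance bins (0 = most proximal).

    Edges are stable-sorted by (distance, label pair) so tied distances
    resolve deterministically; when the edge count is not divisible the
    leftover edges go to the proximal-most bins.
    """
    edges = [((a, b), d) for a, b, d in distances.triu_pairs()]
    if n_bins > len(edges):
        raise ValueError(f"n_bins={n_bins} exceeds edge count ({len(edges)})")
    edges.sort(key=lambda e: (e[1], e[0]))
    n = len(edges)
    sizes = [n // n_bins + (1 if i < n % n_bins else 0) for i in range(n_bins)]
    mapping: dict[Edge, int] = {}
    pos = 0
    for b, size in enumerate(sizes):
        for (pair, _d) in edges[pos:pos + size]:
            mapping[pair] = b
        pos += size
    return mapping


def shuffle_within_bins(network: MINDNetwork, bins: dict[Edge, int],
                        seed: int = 0) -> MINDNetwork:
    """Null network: permute edge weights within each distance bin."""
    net_edges = {(a, b) for a, b, _ in network.triu_pairs()}
    if net_edges != set(bins):
        diff = sorted(net_edges ^ set(bins))[:10]
        raise ValueError(f"bin mapping does not cover network edges; "
                         f"first mismatches: {diff}")
    rng = np.random.default_rng(seed)
    pos = {lab: i for i, lab in enumerate(network.labels)}
    new = np.eye(network.n)
    by_bin: dict[int, list[Edge]] = {}
    for pair, b in bins.items():
        by_bin.setdefault(b, []).append(pair)
    for b in sorted(by_bin):
        pairs = sorted(by_bin[b])
        ii = np.array([pos[a] for a, _ in pairs])
        jj = np.array([pos[c] for _, c in pairs])
        weights = network.values[ii, jj]
        shuffled = weights[rng.permutation(len(pairs))]
        new[ii, jj] = shuffled
        new[jj, ii] = shuffled
    return MINDNetwork(labels=list(network.labels), values=new,
                       meta={"kind": "distance_null", "seed": seed})


@dataclass
class NullEnsemble:
    """Lazy ensemble of distance-preserving null networks.

    Networks are regenerated deterministically from (source, bins, seed), so
    an ensemble of any size costs O(one network) memory. ``statistics``
    evaluates a callable on every null.
    """

    source: MINDNetwork
    bins: dict[Edge, int]
    n_nulls: int = DEFAULT_N_NULLS
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")

    def iter_networks(self):
        for i in range(self.n_nulls):
            yield shuffle_within_bins(self.source, self.bins,
                                      seed=derive_seed(self.seed, "null", i))

    def statistics(self, fn) -> np.ndarray:
        return np.array([fn(null) for null in self.iter_networks()])


def null_ensemble(network: MINDNetwork, distances: LabeledMatrix,
                  n_nulls: int = DEFAULT_N_NULLS, seed: int = 0,
                  n_bins: int = DEFAULT_N_BINS) -> NullEnsemble:
    """Build a distance-preserving null ensemble for a network."""
    if set(network.labels) != set(distances.labels):
        raise ValueError("network and distance matrix node sets differ")
    bins = distance_bins(distances, n_bins=n_bins)
    return NullEnsemble(source=network, bins=bins, n_nulls=n_nulls, seed=seed,
                        meta={"n_bins": n_bins})


@dataclass
class PermutationResult:
    observed: float
    z: float  # NaN when the null SD is zero
    p: float
    n_nulls: int
    null_mean: float
    null_sd: float
    alternative: str = "greater"


def permutation_z_p(observed: float, nulls, alternative: str = "greater"
                    ) -> PermutationResult:
    """Score an observed statistic against permutation nulls.

    z = (observed - mean(nulls)) / SD(nulls). The p-value uses the add-one
    convention, p = (1 + #{null >= observed}) / (1 + n) for the upper tail
    (two-sided doubles the smaller tail, capped at 1), so the smallest
    reportable p is 1/(n + 1) — 1.0e-4 with 10,000 nulls.
    """
    nulls = np.asarray(nulls, dtype=float)
    n = len(nulls)
    if n < 2:
        raise ValueError("need at least 2 null values")
    mean, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    if sd > 0:
        z = (observed - mean) / sd
    else:
        z = float("nan")
        warnings.warn("null distribution has zero SD; z undefined",
                      stacklevel=2)
    upper = (1 + int(np.sum(nulls >= observed))) / (1 + n)
    if alternative == "greater":
        p = upper
    elif alternative == "less":
        p = (1 + int(np.sum(nulls <= observed))) / (1 + n)
    elif alternative == "two-sided":
        lower = (1 + int(np.sum(nulls <= observed))) / (1 + n)
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PermutationResult(observed=float(observed), z=z, p=p, n_nulls=n,
                             null_mean=mean, null_sd=sd,
                             alternative=alternative)
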