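import dataclasses

import numpy as np
import pandas as pd
import pytest

import mindrat as mr
from mindrat import synthetic as syn


@pytest.fixture(scope="session")
def region_models():
    models = syn.generate_parcellation(10, 3, seed=1)
    return [dataclasses.replace(m, n_voxels=300) for m in models]


@pytest.fixture(scope="session")
def truth(region_models):
    return syn.make_truth(region_models, dev_slope={"S00": 0.0008},
                          age_slope={"S00": -0.0002, "S01": 0.0002},
                          group_offset={"S00": -0.01}, subject_sd=0.005)


@pytest.fixture(scope="session")
def parcellation(region_models):
    return mr.Parcellation.from_region_models(region_models)


@pytest.fixture(scope="session")
def scan(truth):
    return syn.generate_scan(truth, 0.0, 63.0, "control", 1500.0, seed=11)


@pytest.fixture(scope="session")
def analytic_net(scan, parcellation):
    return mr.build_mind_network(scan, parcellation,
                                 mr.MindParams(estimator="analytic"))


@pytest.fixture(scope="session")
def distances(parcellation):
    return mr.edge_distances(parcellation.centroids())


def toy_network(weights: np.ndarray, labels=None) -> mr.MINDNetwork:
    """Wrap a symmetric weight matrix (unit diagonal assumed) as a network."""
    w = np.asarray(weights, dtype=float)
    labels = labels or [f"n{i}" for i in range(len(w))]
    return mr.MINDNetwork(labels=list(labels), values=w)


def random_network(n: int, rng: np.random.Generator) -> mr.MINDNetwork:
    """Random valid similarity network with weights in (0, 1]."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 1.0)
    return toy_network(w)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def true_strengths(truth, age, group="control"):
    """Analytic nodal strengths of the planted similarity at given covariates."""
    models = [dataclasses.replace(m, mu=truth.region_mean(m, age, group,
                                                          0.0, 0.0))
              for m in truth.region_models]
    n = len(models)
    s = np.zeros(n)
    for i in range(n):
        s[i] = sum(syn.true_edge_weight(models[i], models[j])
                   for j in range(n) if j != i)
    return pd.Series(s, index=[m.region_id for m in models])


def true_edge_weights(truth, age, group="control"):
    """Analytic pairwise edge weights at given covariates (upper-triangle dict)."""
    models = [dataclasses.replace(m, mu=truth.region_mean(m, age, group,
                                                          0.0, 0.0))
              for m in truth.region_models]
    out = {}
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            out[(a.region_id, b.region_id)] = syn.true_edge_weight(a, b)
    return out
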