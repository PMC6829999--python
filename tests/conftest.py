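"""Shared fixtures: tiny hand-checkable topologies and datasets."""

import numpy as np
import pytest

from pathbench.data import ExpressionDataset, PathwayCollection, PathwayTopology
from pathbench.gene_stats import welch_stats


@pytest.fixture
def path3_undirected():
    """a - b - c."""
    return PathwayTopology(
        name="path3",
        nodes=["a", "b", "c"],
        edges=[("a", "b", 1.0, False), ("b", "c", 1.0, False)],
    )


@pytest.fixture
def chain3_directed():
    """a -> b -> c with activation weights."""
    return PathwayTopology(
        name="chain3",
        nodes=["a", "b", "c"],
        edges=[("a", "b", 1.0, True), ("b", "c", 1.0, True)],
    )


@pytest.fixture
def star4_undirected():
    """center c with leaves l1..l3."""
    return PathwayTopology(
        name="star4",
        nodes=["c", "l1", "l2", "l3"],
        edges=[("c", f"l{i}", 1.0, False) for i in (1, 2, 3)],
    )


@pytest.fixture
def two_triangles():
    """Two triangles joined by a single bridge edge."""
    nodes = ["a1", "a2", "a3", "b1", "b2", "b3"]
    edges = [
        ("a1", "a2", 1.0, False),
        ("a2", "a3", 1.0, False),
        ("a1", "a3", 1.0, False),
        ("b1", "b2", 1.0, False),
        ("b2", "b3", 1.0, False),
        ("b1", "b3", 1.0, False),
        ("a3", "b1", 1.0, False),
    ]
    return PathwayTopology(name="tri2", nodes=nodes, edges=edges)


def make_dataset(values, feature_ids=None, groups=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    feature_ids = feature_ids or [f"g{i}" for i in range(p)]
    groups = groups if groups is not None else [0] * (n // 2) + [1] * (n - n // 2)
    return ExpressionDataset(values, feature_ids, [f"s{j}" for j in range(n)], groups)


@pytest.fixture
def small_dataset():
    """8 features x 12 samples of seeded Gaussian noise, two groups of 6."""
    rng = np.random.default_rng(42)
    return make_dataset(rng.standard_normal((8, 12)))


@pytest.fixture
def small_stats(small_dataset):
    return welch_stats(small_dataset)


@pytest.fixture
def signal_dataset():
    """10 features x 40 samples; features g0, g1 shifted by +2 in group 1."""
    rng = np.random.default_rng(7)
    values = rng.standard_normal((10, 40)) * 0.3
    groups = np.array([0] * 20 + [1] * 20)
    values[0, groups == 1] += 2.0
    values[1, groups == 1] += 2.0
    return make_dataset(values, groups=groups)


@pytest.fixture
def signal_stats(signal_dataset):
    return welch_stats(signal_dataset)


@pytest.fixture
def toy_collection(chain3_directed, path3_undirected):
    extra = PathwayTopology(
        name="loose",
        nodes=["g5", "g6", "g7"],
        edges=[("g5", "g6", 1.0, True)],
    )
    return PathwayCollection([chain3_directed, extra])
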