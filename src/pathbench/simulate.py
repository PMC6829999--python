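"""Synthetic two-condition expression data with pathway-aligned structure.

The generator emulates the benchmarking pipeline used throughout this
package: a single base matrix with within-pathway correlation blocks is
synthesized and standardized (every feature: mean 0, variance 1); a subset
of pathways is marked dysregulated and a detection-call (DC) fraction of
each one's members is selected by a dysregulation design (betweenness,
community, neighborhood or random); each simulation replicate then adds a
mean signal ``mu`` to the affected features of the second group and i.i.d.
Gaussian noise to every entry.  Two label regimes are supported: model I
keeps the original sample labels (group covariances may differ), model II
permutes the labels first, which nullifies covariance differences and
yields an exchangeable null when ``mu = 0``.

Marginals need not be normal: the ``skewed`` option passes the latent
Gaussian through an exponential transform before restandardizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .data import (
    ExpressionDataset,
    PathwayCollection,
    PathwayTopology,
    detect_communities,
    node_betweenness,
)

__all__ = [
    "SimulationConfig",
    "DysregulationAssignment",
    "SimulatedDataset",
    "standardize",
    "base_covariance",
    "synthesize_base_data",
    "select_dysregulated_pathways",
    "affected_by_betweenness",
    "affected_by_community",
    "affected_by_neighborhood",
    "affected_random",
    "assign_dysregulation",
    "generate_replicate",
    "synthetic_signaling_pathways",
    "synthetic_metabolic_pathways",
]

DESIGNS = ("betweenness", "community", "neighborhood", "random")


@dataclass
class SimulationConfig:
    """Study conditions for one benchmark run.

    Defaults follow the genomic-like regime: DC 0.10 (0.20 is the
    metabolomic-like value), mean signals 0.1-0.5 (metabolomic runs extend
    to 1.0), additive noise sd 0.1 on the standardized scale.
    """

    dc: float = 0.10
    q: int = 0  # number of dysregulated pathways (0 = pure null run)
    mu_grid: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    design: str = "random"
    permute_labels: bool = True  # model II by default
    noise_sd: float = 0.1
    marginal: str = "normal"
    seed: int = 0
    # base-data geometry
    n_features: int = 300
    n1: int = 100
    n2: int = 100
    rho_within: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.dc <= 1):
            raise ValueError("dc must lie in (0, 1]")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(m < 0 for m in self.mu_grid):
            raise ValueError("mu_grid must be non-negative")
        if self.marginal not in ("normal", "skewed"):
            raise ValueError("marginal must be 'normal' or 'skewed'")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mu_grid" in raw:
            raw["mu_grid"] = tuple(raw["mu_grid"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["mu_grid"] = list(self.mu_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class DysregulationAssignment:
    """Ground truth of one run: which pathways carry signal and where."""

    dysregulated_pathways: list[str]
    per_pathway_affected: dict[str, frozenset]

    @property
    def affected_features(self) -> frozenset:
        out: set = set()
        for s in self.per_pathway_affected.values():
            out |= s
        return frozenset(out)

    def pathway_is_alternative(self, pathway: PathwayTopology) -> bool:
        """A pathway counts as non-null when any member is affected
        (overlap can make more than q pathways alternative)."""
        return bool(pathway.genes & self.affected_features)


@dataclass
class SimulatedDataset:
    replicate: ExpressionDataset
    truth: DysregulationAssignment
    mu: float


# ---------------------------------------------------------------------------
# Base data
# ---------------------------------------------------------------------------


def standardize(data: ExpressionDataset) -> ExpressionDataset:
    """Per-feature standardization to mean 0 and unit variance."""
    sd = data.values.std(axis=1, ddof=0)
    bad = [f for f, s in zip(data.feature_ids, sd) if s == 0]
    if bad:
        raise ValueError(f"zero-variance features cannot be standardized: {bad[:5]}")
    values = (data.values - data.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionDataset(values, list(data.feature_ids), list(data.sample_ids), data.groups.copy())


def _block_assignment(feature_ids, pathways: PathwayCollection) -> dict[str, str]:
    """Each feature joins the correlation block of the first pathway (in
    collection order) that contains it."""
    assign: dict[str, str] = {}
    for p in pathways:
        for g in sorted(p.genes):
            assign.setdefault(g, p.name)
    return {f: assign[f] for f in feature_ids if f in assign}


def base_covariance(
    feature_ids, pathways: PathwayCollection, rho_within: float
) -> np.ndarray:
    """Population covariance of the latent base data: within-block pairwise
    correlation ``rho_within``, zero between blocks, unit variances."""
    p = len(feature_ids)
    sigma = np.eye(p)
    assign = _block_assignment(feature_ids, pathways)
    index = {f: i for i, f in enumerate(feature_ids)}
    blocks: dict[str, list[int]] = {}
    for f, b in assign.items():
        blocks.setdefault(b, []).append(index[f])
    for idx in blocks.values():
        for i in idx:
            for j in idx:
                if i != j:
                    sigma[i, j] = rho_within
    return sigma


def _feature_order(p: int, pathways: PathwayCollection) -> list[str]:
    feats: list[str] = []
    seen: set = set()
    for pw in pathways:
        for v in pw.nodes:
            for g in sorted(pw.gene_map[v]):
                if g not in seen:
                    seen.add(g)
                    feats.append(g)
    if len(feats) > p:
        raise ValueError("p smaller than the number of mapped genes")
    feats += [f"bg{i}" for i in range(p - len(feats))]
    return feats


def synthesize_base_data(
    p: int,
    n1: int,
    n2: int,
    pathways: PathwayCollection,
    rho_within: float = 0.3,
    marginal: str = "normal",
    seed: int | np.random.Generator = 0,
    feature_ids: list[str] | None = None,
) -> ExpressionDataset:
    """Latent-Gaussian base matrix with pathway-aligned correlation blocks.

    Within-pathway pairwise correlation is ``rho_within`` (single-factor
    blocks; a gene shared by several pathways is assigned to the first);
    features outside every pathway are independent.  ``marginal='skewed'``
    applies an exponential transform and restandardizes, giving non-normal
    marginals with the same block structure.  Deterministic per seed.
    """
    if not (0 <= rho_within < 1):
        raise ValueError("rho_within must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if feature_ids is None:
        feature_ids = _feature_order(p, pathways)
    else:
        missing = set().union(*[pw.genes for pw in pathways]) - set(feature_ids)
        if missing or len(feature_ids) != p:
            raise ValueError("feature_ids must cover all mapped genes and have length p")
    n = n1 + n2
    assign = _block_assignment(feature_ids, pathways)
    block_names = sorted({b for b in assign.values()})
    factors = {b: rng.standard_normal(n) for b in block_names}
    noise = rng.standard_normal((p, n))
    values = np.empty((p, n))
    for i, f in enumerate(feature_ids):
        if f in assign:
            values[i] = np.sqrt(rho_within) * factors[assign[f]] + np.sqrt(
                1 - rho_within
            ) * noise[i]
        else:
            values[i] = noise[i]
    if marginal == "skewed":
        values = np.exp(values)
        values = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, ddof=0, keepdims=True
        )
    elif marginal != "normal":
        raise ValueError("marginal must be 'normal' or 'skewed'")
    groups = np.array([0] * n1 + [1] * n2)
    samples = [f"s{i}" for i in range(n)]
    return ExpressionDataset(values, feature_ids, samples, groups)


# ---------------------------------------------------------------------------
# Dysregulation designs
# ---------------------------------------------------------------------------


def _dc_target(pathway: PathwayTopology, dc: float) -> int:
    return int(np.ceil(dc * pathway.n_nodes))


def _nodes_to_features(pathway: PathwayTopology, nodes) -> frozenset:
    out: set = set()
    for v in nodes:
        out |= pathway.gene_map[v]
    return frozenset(out)


def select_dysregulated_pathways(
    pathways: PathwayCollection, q: int, rng: np.random.Generator | int | None = None
) -> list[str]:
    """Uniform sample of q pathway names, without replacement, seeded."""
    if q >= len(pathways):
        raise ValueError("q must be smaller than the number of pathways")
    rng = np.random.default_rng(rng)
    names = pathways.names
    picked = rng.choice(len(names), size=q, replace=False)
    return [names[i] for i in sorted(picked)]


def affected_by_betweenness(pathway: PathwayTopology, dc: float) -> frozenset:
    """Top betweenness nodes down to the DC target (undirected view; ties
    broken by canonical node order)."""
    if not pathway.edges:
        raise ValueError("betweenness design needs a topology with edges")
    target = _dc_target(pathway, dc)
    bw = node_betweenness(pathway, undirected=True)
    order = sorted(
        range(pathway.n_nodes),
        key=lambda i: (-bw[pathway.nodes[i]], i),
    )
    chosen = [pathway.nodes[i] for i in order[:target]]
    return _nodes_to_features(pathway, chosen)


def affected_by_community(pathway: PathwayTopology, dc: float) -> frozenset:
    """The community whose size is closest to the DC target (ties: smaller
    community first, then canonical order)."""
    target = _dc_target(pathway, dc)
    parts = detect_communities(pathway)
    best = min(parts, key=lambda c: (abs(len(c) - target), len(c)))
    return _nodes_to_features(pathway, best)


def affected_by_neighborhood(
    pathway: PathwayTopology, dc: float, rng: np.random.Generator | int | None = None
) -> frozenset:
    """Shortest-path ball around a random center grown to the DC target;
    nodes on the boundary radius are trimmed at random."""
    import networkx as nx

    rng = np.random.default_rng(rng)
    target = _dc_target(pathway, dc)
    G = pathway.to_networkx(directed=False)
    candidates = [v for v in pathway.nodes if G.degree(v) > 0] or list(pathway.nodes)
    for _ in range(10):
        center = candidates[int(rng.integers(len(candidates)))]
        dists = nx.single_source_shortest_path_length(G, center)
        if len(dists) >= target:
            by_dist: dict[int, list[str]] = {}
            for v, d in dists.items():
                by_dist.setdefault(d, []).append(v)
            chosen: list[str] = []
            for d in sorted(by_dist):
                ring = sorted(by_dist[d], key=pathway.node_index)
                if len(chosen) + len(ring) <= target:
                    chosen.extend(ring)
                else:
                    need = target - len(chosen)
                    pick = rng.choice(len(ring), size=need, replace=False)
                    chosen.extend(ring[i] for i in sorted(pick))
                if len(chosen) == target:
                    return _nodes_to_features(pathway, chosen)
    # fall back to the random design when no ball reaches the target
    return affected_random(pathway, dc, rng)


def affected_random(
    pathway: PathwayTopology, dc: float, rng: np.random.Generator | int | None = None
) -> frozenset:
    """Uniform sample of the DC target among pathway members."""
    rng = np.random.default_rng(rng)
    target = _dc_target(pathway, dc)
    pick = rng.choice(pathway.n_nodes, size=target, replace=False)
    return _nodes_to_features(pathway, [pathway.nodes[i] for i in sorted(pick)])


def assign_dysregulation(
    pathways: PathwayCollection, config: SimulationConfig
) -> DysregulationAssignment:
    """Select q dysregulated pathways and their affected features under the
    configured design.  Deterministic given the config seed."""
    rng = np.random.default_rng([config.seed, 101])
    names = (
        select_dysregulated_pathways(pathways, config.q, rng) if config.q else []
    )
    per_pathway: dict[str, frozenset] = {}
    for name in names:
        pw = pathways[name]
        if config.design == "betweenness":
            try:
                feats = affected_by_betweenness(pw, config.dc)
            except ValueError:
                feats = affected_random(pw, config.dc, rng)
        elif config.design == "community":
            feats = affected_by_community(pw, config.dc)
        elif config.design == "neighborhood":
            feats = affected_by_neighborhood(pw, config.dc, rng)
        else:
            feats = affected_random(pw, config.dc, rng)
        per_pathway[name] = feats
    return DysregulationAssignment(
        dysregulated_pathways=names, per_pathway_affected=per_pathway
    )


def generate_replicate(
    base: ExpressionDataset,
    truth: DysregulationAssignment,
    mu: float,
    config: SimulationConfig,
    replicate: int = 0,
) -> SimulatedDataset:
    """One simulation replicate: optional fresh label permutation (model
    II), mean signal ``mu`` on affected features of group 1, i.i.d.
    Gaussian noise everywhere.  Noise and permutation come from a
    replicate-indexed substream of the config seed."""
    rng = np.random.default_rng([config.seed, 7919, int(replicate)])
    groups = base.groups.copy()
    if config.permute_labels:
        groups = groups[rng.permutation(groups.size)]
    values = base.values + rng.normal(0.0, config.noise_sd, size=base.values.shape)
    if mu != 0.0 and truth.affected_features:
        feats = sorted(truth.affected_features & set(base.feature_ids))
        if feats:
            idx = base.feature_index(feats)
            values[np.ix_(idx, groups == 1)] += mu
    ds = ExpressionDataset(values, list(base.feature_ids), list(base.sample_ids), groups)
    return SimulatedDataset(replicate=ds, truth=truth, mu=mu)


# ---------------------------------------------------------------------------
# Synthetic pathway topologies
# ---------------------------------------------------------------------------


def synthetic_signaling_pathways(
    n_pathways: int = 15,
    size: int = 20,
    extra_edges: int | None = None,
    activation_prob: float = 0.7,
    seed: int = 0,
    prefix: str = "SIG",
) -> PathwayCollection:
    """Random connected DAG pathways emulating signaling topologies.

    Each pathway is a random spanning arborescence over ``size`` genes plus
    ``extra_edges`` forward shortcuts (default: one per node, about two
    edges per node in total — comparable to curated signaling maps), with
    signed weights (+1 activation with probability ``activation_prob``,
    else -1 inhibition).  Edges always point from lower to higher node
    index, so every pathway is a DAG and ``I - B`` is never singular.
    """
    rng = np.random.default_rng(seed)
    if extra_edges is None:
        extra_edges = size
    pathways = []
    for k in range(n_pathways):
        nodes = [f"{prefix}{k}_g{i}" for i in range(size)]
        edges: list[tuple] = []
        present: set = set()
        for i in range(1, size):
            j = int(rng.integers(i))
            w = 1.0 if rng.random() < activation_prob else -1.0
            edges.append((nodes[j], nodes[i], w, True))
            present.add((j, i))
        added = 0
        attempts = 0
        while added < extra_edges and attempts < 50 * extra_edges:
            attempts += 1
            i = int(rng.integers(1, size))
            j = int(rng.integers(i))
            if (j, i) in present:
                continue
            present.add((j, i))
            w = 1.0 if rng.random() < activation_prob else -1.0
            edges.append((nodes[j], nodes[i], w, True))
            added += 1
        pathways.append(PathwayTopology(name=f"{prefix}{k}", nodes=nodes, edges=edges))
    return PathwayCollection(pathways)


def synthetic_metabolic_pathways(
    n_pathways: int = 12,
    size_range: tuple = (5, 10),
    n_metabolites: int = 100,
    edge_keep_prob: float = 0.7,
    seed: int = 0,
    prefix: str = "MET",
) -> PathwayCollection:
    """Small, sparse, overlapping undirected pathways emulating metabolic
    maps with incomplete coverage.

    Members are drawn from a shared metabolite universe (overlap arises
    naturally); each pathway's edges are a random spanning tree thinned by
    ``edge_keep_prob``, so topologies are sparse and may fall into several
    connected components.
    """
    rng = np.random.default_rng(seed)
    universe = [f"m{i}" for i in range(n_metabolites)]
    pathways = []
    for k in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        pick = rng.choice(n_metabolites, size=size, replace=False)
        nodes = [universe[i] for i in sorted(pick)]
        edges: list[tuple] = []
        for i in range(1, size):
            j = int(rng.integers(i))
            if rng.random() < edge_keep_prob:
                edges.append((nodes[j], nodes[i], 1.0, False))
        pathways.append(PathwayTopology(name=f"{prefix}{k}", nodes=nodes, edges=edges))
    return PathwayCollection(pathways)
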