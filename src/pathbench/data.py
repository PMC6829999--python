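"""Shared data model, file I/O and graph primitives.

The two central containers are :class:`ExpressionDataset` (a log-scale
feature x sample matrix with a binary group assignment) and
:class:`PathwayTopology` (a named node set with a gene-to-node map and a
signed, weighted, possibly directed adjacency).  Every enrichment method in
this package consumes these two objects; the graph primitives defined here
(betweenness, largest reach, communities, components, downstream counts)
are shared by the centrality-based methods and by the dysregulation designs
of the simulation engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "LabelError",
    "NotAnalyzable",
    "ExpressionDataset",
    "PathwayTopology",
    "PathwayCollection",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "node_betweenness",
    "largest_reach",
    "detect_communities",
    "connected_components",
    "downstream_count",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class LabelError(ValueError):
    """A sample label specification is inconsistent with the data."""


class NotAnalyzable(Exception):
    """A pathway cannot be analyzed by a method (singular system, no DE
    genes, cyclic topology, ...).  Carries a human-readable reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Log-scale expression matrix (features x samples) with two groups.

    Parameters
    ----------
    values
        ``(p, n)`` float array of log expression.
    feature_ids
        ``p`` unique feature names (genes/metabolites).
    sample_ids
        ``n`` sample names.
    groups
        ``n`` integers in ``{0, 1}``; by convention group ``1`` is the
        perturbed/case condition (mean signals in simulations are added to
        group ``1``).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        p, n = self.values.shape
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match matrix")
        if len(self.sample_ids) != n or self.groups.shape != (n,):
            raise ValueError("sample annotation length does not match matrix")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if not set(np.unique(self.groups)) <= {0, 1}:
            raise LabelError("groups must be coded 0/1")
        if self.n1 == 0 or self.n2 == 0:
            raise LabelError("both groups must be non-empty")
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n1(self) -> int:
        return int(np.sum(self.groups == 0))

    @property
    def n2(self) -> int:
        return int(np.sum(self.groups == 1))

    def group_values(self, group: int) -> np.ndarray:
        return self.values[:, self.groups == group]

    def feature_index(self, features: Iterable[str]) -> np.ndarray:
        return np.array([self._index[f] for f in features], dtype=int)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.copy(),
            list(self.feature_ids),
            list(self.sample_ids),
            self.groups.copy(),
        )


def _groups_from_spec(
    sample_ids: Sequence[str], label_spec: Mapping[str, object] | Sequence[object]
) -> np.ndarray:
    """Translate a two-group label specification into 0/1 codes.

    ``label_spec`` is either a mapping ``sample -> label`` or a sequence of
    labels aligned with the sample order.  The group observed first in
    sample order becomes group 0 (reference); the other becomes group 1.
    """
    if isinstance(label_spec, Mapping):
        unknown = [s for s in label_spec if s not in set(sample_ids)]
        if unknown:
            raise LabelError(f"unknown samples in label spec: {unknown}")
        missing = [s for s in sample_ids if s not in label_spec]
        if missing:
            raise LabelError(f"samples without labels: {missing}")
        labels = [label_spec[s] for s in sample_ids]
    else:
        labels = list(label_spec)
        if len(labels) != len(sample_ids):
            raise LabelError("label sequence length does not match samples")
    levels: list[object] = []
    for lab in labels:
        if lab not in levels:
            levels.append(lab)
    if len(levels) != 2:
        raise LabelError(f"expected exactly two groups, got {levels}")
    return np.array([levels.index(lab) for lab in labels], dtype=int)


def read_expression_table(path, label_spec) -> ExpressionDataset:
    """Read a tab- or comma-delimited expression table.

    Header row holds sample ids, first column feature ids.  Sample order is
    preserved.  Raises :class:`FormatError` on non-numeric cells and
    :class:`LabelError` on label problems.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in expression table: {exc}") from exc
    feature_ids = [str(f) for f in df.index]
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError("duplicated feature id in expression table")
    sample_ids = [str(s) for s in df.columns]
    groups = _groups_from_spec(sample_ids, label_spec)
    return ExpressionDataset(values, feature_ids, sample_ids, groups)


def write_expression_table(dataset: ExpressionDataset, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(
        dataset.values, index=dataset.feature_ids, columns=dataset.sample_ids
    ).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Pathway topology
# ---------------------------------------------------------------------------


@dataclass
class PathwayTopology:
    """A pathway: ordered nodes, gene map and signed weighted edges.

    ``edges`` is a list of ``(source, target, weight, directed)`` tuples.
    Undirected edges are stored once but act symmetrically; the derived
    ``adjacency`` matrix contains the weight at ``[source, target]`` and,
    for undirected edges, also at ``[target, source]``.  Weights follow the
    usual signaling convention: ``+1`` activation, ``-1`` inhibition (any
    finite real weight is allowed).
    """

    name: str
    nodes: list[str]
    edges: list[tuple] = field(default_factory=list)
    gene_map: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"pathway {self.name}: duplicate nodes")
        node_set = set(self.nodes)
        norm_edges = []
        for e in self.edges:
            s, t, w, d = e
            w = float(w)
            if s not in node_set or t not in node_set:
                raise ValueError(f"pathway {self.name}: edge endpoint not in nodes")
            if not np.isfinite(w):
                raise ValueError(f"pathway {self.name}: non-finite edge weight")
            if s == t:
                raise ValueError(f"pathway {self.name}: self-loop at {s}")
            norm_edges.append((s, t, w, bool(d)))
        self.edges = norm_edges
        if not self.gene_map:
            self.gene_map = {v: frozenset([v]) for v in self.nodes}
        else:
            self.gene_map = {v: frozenset(self.gene_map.get(v, [v])) for v in self.nodes}
        for v, genes in self.gene_map.items():
            if not genes:
                raise ValueError(f"pathway {self.name}: empty gene set for node {v}")
        self._node_index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def is_directed(self) -> bool:
        """True when every edge carries a direction."""
        return len(self.edges) > 0 and all(d for (_, _, _, d) in self.edges)

    @property
    def genes(self) -> frozenset:
        out: set = set()
        for gs in self.gene_map.values():
            out |= gs
        return frozenset(out)

    def node_index(self, node: str) -> int:
        return self._node_index[node]

    @property
    def adjacency(self) -> np.ndarray:
        """Square matrix over ``nodes``: ``A[source, target] = weight``."""
        m = self.n_nodes
        A = np.zeros((m, m))
        for s, t, w, d in self.edges:
            i, j = self._node_index[s], self._node_index[t]
            A[i, j] = w
            if not d:
                A[j, i] = w
        return A

    def to_networkx(self, directed: bool | None = None) -> nx.Graph:
        """Build a networkx view.  ``directed=None`` keeps edge semantics
        (undirected edges become reciprocal arcs in a DiGraph when any edge
        is directed); ``directed=False`` forces the undirected skeleton.
        """
        if directed is None:
            directed = any(d for (_, _, _, d) in self.edges)
        G: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        G.add_nodes_from(self.nodes)
        for s, t, w, d in self.edges:
            G.add_edge(s, t, weight=w)
            if directed and not d:
                G.add_edge(t, s, weight=w)
        return G


@dataclass
class PathwayCollection:
    """A list of pathways with unique names and a shared gene universe."""

    pathways: list[PathwayTopology]

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(set(names)) != len(names):
            raise ValueError("pathway names must be unique")
        self._by_name = {p.name: p for p in self.pathways}

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> PathwayTopology:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]

    @property
    def universe(self) -> frozenset:
        """Union of all mapped feature ids across pathways."""
        out: set = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)


def read_gmt(path) -> PathwayCollection:
    """Read a standard GMT file into membership-only topologies.

    Each line: name, description, then tab-separated members.  Members
    become singleton nodes; duplicate members on a line are deduplicated.
    """
    pathways = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            members = []
            seen = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.info("GMT %s: duplicate member %s deduplicated", name, g)
                    continue
                seen.add(g)
                members.append(g)
            pathways.append(PathwayTopology(name=name, nodes=members))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            fh.write("\t".join([p.name, "na"] + list(p.nodes)) + "\n")


def read_edge_list(path, gmt: PathwayCollection) -> PathwayCollection:
    """Attach topologies from an edge-list TSV to a membership collection.

    Columns: pathway, source, target, weight, directed(0/1).  Nodes not yet
    declared in the GMT pathway are added.  Unknown pathways are an error.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"edge list line {lineno}: expected 5 fields")
            name, s, t, w, d = fields
            try:
                w = float(w)
            except ValueError as exc:
                raise FormatError(f"edge list line {lineno}: non-numeric weight") from exc
            if d not in ("0", "1"):
                raise FormatError(f"edge list line {lineno}: directed flag must be 0/1")
            if name not in gmt:
                raise ValueError(f"edge list references unknown pathway {name!r}")
            rows.append((name, s, t, w, d == "1"))
    per_pathway: dict[str, list[tuple]] = {p.name: [] for p in gmt}
    extra_nodes: dict[str, list[str]] = {p.name: [] for p in gmt}
    declared = {p.name: set(p.nodes) for p in gmt}
    for name, s, t, w, d in rows:
        for v in (s, t):
            if v not in declared[name] and v not in extra_nodes[name]:
                extra_nodes[name].append(v)
        per_pathway[name].append((s, t, w, d))
    out = []
    for p in gmt:
        nodes = list(p.nodes) + extra_nodes[p.name]
        gene_map = dict(p.gene_map)
        for v in extra_nodes[p.name]:
            gene_map[v] = frozenset([v])
        out.append(
            PathwayTopology(
                name=p.name, nodes=nodes, edges=per_pathway[p.name], gene_map=gene_map
            )
        )
    return PathwayCollection(out)


def write_edge_list(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tsource\ttarget\tweight\tdirected\n")
        for p in collection:
            for s, t, w, d in p.edges:
                fh.write(f"{p.name}\t{s}\t{t}\t{w:g}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# Graph primitives
# ---------------------------------------------------------------------------


def node_betweenness(
    topology: PathwayTopology, undirected: bool = False
) -> dict[str, float]:
    """Shortest-path betweenness per node (unnormalized).

    Tied geodesics share credit fractionally.  Directed topologies use
    directed paths unless ``undirected`` asks for the undirected skeleton
    (the view used by the dysregulation designs).
    """
    G = topology.to_networkx(directed=False if undirected else None)
    return dict(nx.betweenness_centrality(G, normalized=False))


def largest_reach(topology: PathwayTopology) -> dict[str, float]:
    """Largest-reach centrality: the farthest a node can send *or* receive
    information along shortest paths; unreachable pairs are ignored."""
    G = topology.to_networkx()
    send = {v: 0.0 for v in topology.nodes}
    recv = {v: 0.0 for v in topology.nodes}
    for v, dists in nx.shortest_path_length(G):
        others = [d for u, d in dists.items() if u != v]
        send[v] = float(max(others)) if others else 0.0
    if G.is_directed():
        for v, dists in nx.shortest_path_length(G.reverse(copy=False)):
            others = [d for u, d in dists.items() if u != v]
            recv[v] = float(max(others)) if others else 0.0
    else:
        recv = dict(send)
    return {v: max(send[v], recv[v]) for v in topology.nodes}


def detect_communities(topology: PathwayTopology) -> list[set]:
    """Girvan-Newman edge-betweenness communities on the undirected view.

    The dendrogram is cut at the partition maximizing modularity; an
    edgeless graph yields singleton communities.  Deterministic for a fixed
    node order.
    """
    G = topology.to_networkx(directed=False)
    if G.number_of_edges() == 0:
        return [{v} for v in topology.nodes]
    base = [set(c) for c in nx.connected_components(G)]
    best, best_q = base, nx.community.modularity(G, base)
    for partition in nx.community.girvan_newman(G):
        parts = [set(c) for c in partition]
        q = nx.community.modularity(G, parts)
        if q > best_q + 1e-12:
            best, best_q = parts, q
    # canonical order: by smallest node index within each community
    order = {v: i for i, v in enumerate(topology.nodes)}
    best.sort(key=lambda c: min(order[v] for v in c))
    return best


def connected_components(topology: PathwayTopology) -> list[set]:
    """Weakly connected components, in canonical node order."""
    if topology.n_nodes == 0:
        return []
    G = topology.to_networkx(directed=False)
    comps = [set(c) for c in nx.connected_components(G)]
    order = {v: i for i, v in enumerate(topology.nodes)}
    comps.sort(key=lambda c: min(order[v] for v in c))
    return comps


def downstream_count(topology: PathwayTopology) -> dict[str, int]:
    """Number of direct downstream targets ``N_ds`` per node.

    Defined for directed signaling topologies only; an undirected pathway
    raises ``ValueError``.
    """
    if topology.edges and not topology.is_directed:
        raise ValueError("downstream_count requires a fully directed topology")
    G = topology.to_networkx(directed=True)
    return {v: int(G.out_degree(v)) for v in topology.nodes}
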