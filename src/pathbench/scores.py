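"""CePa, PRS, PathNet and CAMERA: node scores, gene-permutation nulls and
the correlation-adjusted competitive test.

CePa scores a pathway as ``s = sum_i w_i d_i`` over its nodes, where
``d_i`` flags differential expression of the node and the weight ``w_i``
comes from a centrality measure (plus a 0.01 offset to keep weights
positive).  PRS weighs each differential node by the number of downstream
differential nodes it can reach through differential intermediates and
multiplies by the node's fold change.  Both assess significance by
permuting gene-level DE labels over the measured universe.

PathNet pools all pathways into one network and combines each gene's
direct evidence (its own p-value) with indirect evidence aggregated from
its neighbors, ``SI_i = sum_j A_ij (-log10 p_j^D)``, via Fisher's method;
pathway significance is a hypergeometric test on the significant genes.

CAMERA is a competitive test on gene-level statistics whose variance is
inflated by the average inter-gene correlation: ``VIF = 1 + (m-1) rho_bar``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations

import networkx as nx
import numpy as np
from scipy import stats as sps

from .data import PathwayCollection, PathwayTopology, largest_reach, node_betweenness
from .gene_stats import GeneLevelStats, bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "NodeStats",
    "CePaResult",
    "PRSResult",
    "PathNetGeneEvidence",
    "CameraResult",
    "map_genes_to_nodes",
    "cepa_weights",
    "cepa_score",
    "cepa_pvalue",
    "prs_score",
    "prs_pvalue",
    "pooled_adjacency",
    "pathnet_indirect_evidence",
    "pathnet_combined_evidence",
    "pathnet_pathway_pvalue",
    "camera_test",
    "CEPA_MEASURES",
]

CEPA_MEASURES = ("equal", "in-degree", "out-degree", "betweenness", "largest-reach")
CEPA_OFFSET = 0.01
PRS_GATE_EPS = 1e-6
_LOG10_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Gene -> node mapping
# ---------------------------------------------------------------------------


@dataclass
class NodeStats:
    """Node-level summaries derived from gene-level statistics."""

    nodes: list[str]
    measured: np.ndarray  # node has >= 1 measured gene
    node_de: np.ndarray  # d_i: any mapped gene DE
    node_fc: np.ndarray  # max |Delta E| over mapped measured genes
    node_value: np.ndarray  # v_i per the PRS rules


def map_genes_to_nodes(
    stats: GeneLevelStats, topology: PathwayTopology, prs_gate: str = "relaxed"
) -> NodeStats:
    """Aggregate gene statistics onto pathway nodes.

    ``d_i`` is the OR of the mapped genes' DE flags, ``node_fc`` the max
    absolute mean difference.  The PRS node value is 0 for unmeasured
    nodes, 1 for measured non-differential nodes and the maximal fold
    change for differential ones.  Because the PRS score only activates
    nodes with value > 1 and standardized data can yield |Delta E| < 1 for
    genuine DE genes, the default ``relaxed`` gate lifts differential
    nodes to at least ``1 + 1e-6``; ``literal`` keeps the raw fold change.
    """
    m = topology.n_nodes
    measured = np.zeros(m, dtype=bool)
    node_de = np.zeros(m, dtype=bool)
    node_fc = np.zeros(m)
    for i, v in enumerate(topology.nodes):
        for g in topology.gene_map[v]:
            k = stats._index.get(g)
            if k is None:
                continue
            measured[i] = True
            node_fc[i] = max(node_fc[i], abs(float(stats.delta_e[k])))
            node_de[i] |= bool(stats.is_de[k])
    value = np.where(measured, 1.0, 0.0)
    if prs_gate == "relaxed":
        value = np.where(node_de, np.maximum(node_fc, 1.0 + PRS_GATE_EPS), value)
    elif prs_gate == "literal":
        value = np.where(node_de, node_fc, value)
    else:
        raise ValueError(f"unknown prs_gate {prs_gate!r}")
    return NodeStats(
        nodes=list(topology.nodes),
        measured=measured,
        node_de=node_de,
        node_fc=node_fc,
        node_value=value,
    )


# ---------------------------------------------------------------------------
# CePa
# ---------------------------------------------------------------------------


@dataclass
class CePaResult:
    pathway: str
    method: str = "CePa"
    status: str = "ok"
    reason: str | None = None
    weights: dict = field(default_factory=dict)
    score: dict = field(default_factory=dict)
    p_per_measure: dict = field(default_factory=dict)
    p_min: float | None = None


def cepa_weights(topology: PathwayTopology, measure: str) -> np.ndarray:
    """Centrality weight per node, offset by 0.01 to stay positive."""
    if measure not in CEPA_MEASURES:
        raise ValueError(f"unknown CePa measure {measure!r}")
    if measure == "equal":
        cent = np.ones(topology.n_nodes)
    elif measure in ("in-degree", "out-degree"):
        G = topology.to_networkx()
        if G.is_directed():
            deg = G.in_degree if measure == "in-degree" else G.out_degree
        else:
            deg = G.degree  # undirected graphs collapse in/out to degree
        cent = np.array([deg(v) for v in topology.nodes], dtype=float)
    elif measure == "betweenness":
        bw = node_betweenness(topology)
        cent = np.array([bw[v] for v in topology.nodes])
    else:  # largest-reach
        lr = largest_reach(topology)
        cent = np.array([lr[v] for v in topology.nodes])
    return cent + CEPA_OFFSET


def cepa_score(node_de: np.ndarray, weights: np.ndarray) -> float:
    """``s = sum_i w_i d_i``."""
    return float(weights @ node_de.astype(float))


def _node_gene_incidence(
    stats: GeneLevelStats, topology: PathwayTopology
) -> np.ndarray:
    """Binary (n_nodes, n_features) incidence of measured mapped genes."""
    M = np.zeros((topology.n_nodes, len(stats.feature_ids)), dtype=bool)
    for i, v in enumerate(topology.nodes):
        for g in topology.gene_map[v]:
            k = stats._index.get(g)
            if k is not None:
                M[i, k] = True
    return M


def _de_label_draws(
    rng: np.random.Generator, n_perm: int, n_features: int, n_de: int
) -> np.ndarray:
    """Boolean (n_perm, n_features) matrix of permuted DE label vectors."""
    keys = rng.random((n_perm, n_features))
    idx = np.argpartition(keys, n_de - 1, axis=1)[:, :n_de]
    out = np.zeros((n_perm, n_features), dtype=bool)
    np.put_along_axis(out, idx, True, axis=1)
    return out


def _exhaustive_de_labels(n_features: int, n_de: int) -> np.ndarray:
    rows = []
    for combo in combinations(range(n_features), n_de):
        row = np.zeros(n_features, dtype=bool)
        row[list(combo)] = True
        rows.append(row)
    return np.array(rows)


def cepa_pvalue(
    stats: GeneLevelStats,
    topology: PathwayTopology,
    measures=CEPA_MEASURES,
    n_perm: int = 2000,
    rng: np.random.Generator | int | None = None,
    exhaustive: bool = False,
) -> CePaResult:
    """CePa with a gene-permutation null per centrality measure.

    DE labels are permuted over the measured universe and re-mapped to
    nodes; the reported pathway p-value is the minimum over measures.
    ``exhaustive`` enumerates every placement of the DE labels instead of
    sampling (tiny universes only).
    """
    rng = np.random.default_rng(rng)
    n_de = stats.n_de
    if n_de == 0:
        return CePaResult(
            pathway=topology.name,
            status="not_analyzable",
            reason="no DE genes in the data",
        )
    node_stats = map_genes_to_nodes(stats, topology)
    incidence = _node_gene_incidence(stats, topology)
    if exhaustive:
        labels = _exhaustive_de_labels(len(stats.feature_ids), n_de)
        denom = float(labels.shape[0])
        extra = 0.0
    else:
        labels = _de_label_draws(rng, n_perm, len(stats.feature_ids), n_de)
        denom = n_perm + 1.0
        extra = 1.0
    node_de_perm = labels @ incidence.T.astype(float) > 0  # (draws, n_nodes)
    weights, score, pvals = {}, {}, {}
    for measure in measures:
        w = cepa_weights(topology, measure)
        s_obs = cepa_score(node_stats.node_de, w)
        s_perm = node_de_perm.astype(float) @ w
        pvals[measure] = float(
            (extra + np.sum(s_perm >= s_obs - 1e-12)) / denom
        )
        weights[measure] = dict(zip(topology.nodes, w))
        score[measure] = s_obs
    return CePaResult(
        pathway=topology.name,
        weights=weights,
        score=score,
        p_per_measure=pvals,
        p_min=min(pvals.values()),
    )


# ---------------------------------------------------------------------------
# PRS
# ---------------------------------------------------------------------------


@dataclass
class PRSResult:
    pathway: str
    method: str = "PRS"
    status: str = "ok"
    reason: str | None = None
    node_weight: dict = field(default_factory=dict)
    node_score: dict = field(default_factory=dict)
    raw: float = 0.0
    normalized: float = 0.0
    p: float | None = None


def _prs_from_node_stats(
    node_stats: NodeStats, topology: PathwayTopology
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Weights, node scores, raw and normalized PRS for fixed node stats."""
    m = topology.n_nodes
    active = node_stats.node_value > 1.0
    w = np.zeros(m, dtype=float)
    if np.any(active):
        G = topology.to_networkx(directed=True)
        de_nodes = {v for v, a in zip(topology.nodes, active) if a}
        H = G.subgraph(de_nodes)
        for i, v in enumerate(topology.nodes):
            if active[i]:
                w[i] = 1.0 + len(nx.descendants(H, v))
    s = np.where(active, w * node_stats.node_value, 0.0)
    raw = float(s.sum())
    n_expressed = int(np.sum(node_stats.measured))
    n_de = int(np.sum(node_stats.node_de))
    normalized = raw * (n_de / n_expressed) if n_expressed else 0.0
    return w, s, raw, normalized


def prs_score(stats: GeneLevelStats, topology: PathwayTopology) -> PRSResult:
    """Pathway Regulation Score: ``PRS = sum_i w_i v_i`` over differential
    nodes, normalized by the proportion of DE genes among expressed ones."""
    node_stats = map_genes_to_nodes(stats, topology)
    w, s, raw, normalized = _prs_from_node_stats(node_stats, topology)
    return PRSResult(
        pathway=topology.name,
        node_weight=dict(zip(topology.nodes, w)),
        node_score=dict(zip(topology.nodes, s)),
        raw=raw,
        normalized=normalized,
    )


def prs_pvalue(
    stats: GeneLevelStats,
    topology: PathwayTopology,
    n_perm: int = 2000,
    rng: np.random.Generator | int | None = None,
    exhaustive: bool = False,
) -> PRSResult:
    """Gene-permutation p-value for the normalized PRS.

    DE flags and |Delta E| values travel together under the permutation.
    Raw and permuted scores are standardized by the permutation mean and
    standard deviation before the one-sided comparison.
    """
    rng = np.random.default_rng(rng)
    if stats.n_de == 0:
        return PRSResult(
            pathway=topology.name,
            status="not_analyzable",
            reason="no DE genes in the data",
        )
    result = prs_score(stats, topology)
    n = len(stats.feature_ids)

    def _score_for(order: np.ndarray) -> float:
        permuted = GeneLevelStats(
            feature_ids=stats.feature_ids,
            delta_e=stats.delta_e[order],
            t_stat=stats.t_stat[order],
            df=stats.df[order],
            p_value=stats.p_value[order],
            q_value=stats.q_value[order],
            is_de=stats.is_de[order],
        )
        node_stats = map_genes_to_nodes(permuted, topology)
        return _prs_from_node_stats(node_stats, topology)[3]

    if exhaustive:
        perm_scores = np.array(
            [_score_for(np.array(order)) for order in permutations(range(n))]
        )
        denom = float(perm_scores.size)
        extra = 0.0
    else:
        perm_scores = np.array(
            [_score_for(rng.permutation(n)) for _ in range(n_perm)]
        )
        denom = n_perm + 1.0
        extra = 1.0
    mu, sd = float(perm_scores.mean()), float(perm_scores.std(ddof=0))
    if sd == 0.0:
        logger.warning("PRS %s: degenerate permutation distribution", topology.name)
        result.p = 1.0
        return result
    z_obs = (result.normalized - mu) / sd
    z_perm = (perm_scores - mu) / sd
    result.p = float((extra + np.sum(z_perm >= z_obs - 1e-12)) / denom)
    return result


# ---------------------------------------------------------------------------
# PathNet
# ---------------------------------------------------------------------------


@dataclass
class PathNetGeneEvidence:
    """Gene-level PathNet quantities on the pooled pathway."""

    genes: list[str]
    p_direct: np.ndarray
    si: np.ndarray
    p_indirect: np.ndarray
    p_combined: np.ndarray
    significant: np.ndarray  # BH(p_combined) <= threshold
    threshold: float


def pooled_adjacency(collection: PathwayCollection) -> tuple[list[str], np.ndarray]:
    """Union of all pathways as one binary undirected adjacency.

    Node identity is the mapped feature id; genes interact when any
    pathway links nodes mapping to them.  Returns (genes, matrix) with
    genes in sorted order.
    """
    genes = sorted(collection.universe)
    index = {g: i for i, g in enumerate(genes)}
    A = np.zeros((len(genes), len(genes)))
    for p in collection:
        for s, t, _w, _d in p.edges:
            for gs in p.gene_map[s]:
                for gt in p.gene_map[t]:
                    i, j = index[gs], index[gt]
                    if i != j:
                        A[i, j] = 1.0
                        A[j, i] = 1.0
    return genes, A


def pathnet_indirect_evidence(p_direct: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """``SI_i = sum_{j != i} A_ij * (-log10 p_j^D)``."""
    p = np.asarray(p_direct, dtype=float)
    if np.any(p <= 0):
        logger.warning("PathNet: zero direct p-values clamped to machine floor")
    nlp = -np.log10(np.clip(p, _LOG10_FLOOR, 1.0))
    return adjacency @ nlp


def pathnet_combined_evidence(
    p_direct: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 2000,
    rng: np.random.Generator | int | None = None,
    genes: list[str] | None = None,
    threshold: float = 0.05,
) -> PathNetGeneEvidence:
    """Combine direct and permutation-calibrated indirect evidence.

    The indirect p-value of each gene compares its observed ``SI`` with
    values under random reassignment of the direct p-values across the
    pooled genes; Fisher's method with 4 degrees of freedom yields the
    combined gene-level p-value.
    """
    rng = np.random.default_rng(rng)
    p_direct = np.asarray(p_direct, dtype=float)
    n = p_direct.size
    si = pathnet_indirect_evidence(p_direct, adjacency)
    nlp = -np.log10(np.clip(p_direct, _LOG10_FLOOR, 1.0))
    perm_cols = np.column_stack([nlp[rng.permutation(n)] for _ in range(n_perm)])
    si_perm = adjacency @ perm_cols  # (n, n_perm)
    p_indirect = (1.0 + np.sum(si_perm >= si[:, None] - 1e-12, axis=1)) / (n_perm + 1.0)
    chi2 = -2.0 * (
        np.log(np.clip(p_direct, _LOG10_FLOOR, 1.0)) + np.log(p_indirect)
    )
    p_combined = sps.chi2.sf(chi2, df=4)
    return PathNetGeneEvidence(
        genes=list(genes) if genes is not None else [str(i) for i in range(n)],
        p_direct=p_direct,
        si=si,
        p_indirect=p_indirect,
        p_combined=p_combined,
        significant=bh_adjust(p_combined) <= threshold,
        threshold=threshold,
    )


def pathnet_pathway_pvalue(
    evidence: PathNetGeneEvidence, pathway_genes, universe_size: int | None = None
) -> float:
    """Hypergeometric upper tail of significant genes inside the pathway,
    against the pooled-pathway universe.  No significant genes -> p = 1."""
    n_sig = int(np.sum(evidence.significant))
    if n_sig == 0:
        return 1.0
    index = {g: i for i, g in enumerate(evidence.genes)}
    members = [index[g] for g in pathway_genes if g in index]
    k = int(np.sum(evidence.significant[members]))
    N = universe_size if universe_size is not None else len(evidence.genes)
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, n_sig, len(members)))


# ---------------------------------------------------------------------------
# CAMERA
# ---------------------------------------------------------------------------


@dataclass
class CameraResult:
    pathway: str
    method: str = "CAMERA"
    status: str = "ok"
    reason: str | None = None
    m: int = 0
    rho_bar: float = 0.0
    vif: float = 1.0
    delta: float = 0.0
    s_pool: float = 0.0
    ts: float | None = None
    p: float | None = None


def camera_test(stats: GeneLevelStats, members, data, pathway: str = "") -> CameraResult:
    """Competitive test of pathway-mean z against the rest of the genome.

    ``TS = delta / (s_pool * sqrt(VIF/m + 1/(p-m)))`` with
    ``delta = (zbar_G - zbar) p/(p-m)`` and ``VIF = 1 + (m-1) rho_bar``.
    ``rho_bar`` is the average pairwise Pearson correlation of the member
    genes' within-group-centered expression residuals.  Two-sided p from
    the standard normal.
    """
    z = stats.z_score
    p_total = z.size
    members = sorted(set(members) & set(stats.feature_ids))
    m = len(members)
    if m < 2:
        return CameraResult(
            pathway=pathway, status="not_analyzable", reason="fewer than 2 measured genes"
        )
    if m >= p_total:
        raise ValueError("pathway covers the whole universe; competitive test undefined")
    idx = stats.feature_index(members)
    # residuals: remove per-feature group means
    resid = data.values.copy()
    for g in (0, 1):
        cols = data.groups == g
        resid[:, cols] -= resid[:, cols].mean(axis=1, keepdims=True)
    sub = resid[data.feature_index(members)]
    corr = np.corrcoef(sub)
    iu = np.triu_indices(m, k=1)
    rho_bar = float(np.mean(corr[iu]))
    rho_bar = max(rho_bar, -1.0 / (m - 1) + 1e-12)
    vif = 1.0 + (m - 1) * rho_bar
    assert vif > 0
    zbar_g = float(z[idx].mean())
    zbar = float(z.mean())
    delta = (zbar_g - zbar) * p_total / (p_total - m)
    s_pool = float(np.std(z, ddof=1))
    if s_pool == 0.0:
        return CameraResult(
            pathway=pathway, status="not_analyzable", reason="degenerate z-scores"
        )
    ts = delta / (s_pool * np.sqrt(vif / m + 1.0 / (p_total - m)))
    return CameraResult(
        pathway=pathway,
        m=m,
        rho_bar=rho_bar,
        vif=vif,
        delta=delta,
        s_pool=s_pool,
        ts=float(ts),
        p=float(2.0 * sps.norm.sf(abs(ts))),
    )
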