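"""Pathway-Express and SPIA: perturbation propagation on signaling graphs.

Both methods propagate per-gene expression changes ``Delta E`` through a
directed pathway via the perturbation factor

    PF(g_i) = Delta E(g_i) + sum_{j -> i} beta_ij PF(g_j) / N_ds(g_j),

where ``beta_ij`` is the signed interaction weight and ``N_ds(g_j)`` the
number of direct targets of the upstream gene.  Writing ``B_ij =
beta_ij / N_ds(g_j)``, PF solves the linear system ``(I - B) PF = Delta E``;
a pathway with singular ``I - B`` cannot be analyzed.

Pathway-Express combines an over-representation p-value with the impact
factor ``IF(G) = log(1/P_NDE) + sum |PF| / (N_de(G) * mean|Delta E|)`` and
scores it against a Gamma(2, 1) null, ``P_G = (f + 1) e^{-f}``.  Its
cutoff-free variant drops the ORA term and evaluates ``sum |PF|`` by gene
permutation.  SPIA combines the same ORA evidence with a bootstrap p-value
for the net accumulation ``t_A = sum (PF - Delta E)`` through
``P_G = c - c ln c`` with ``c = P_NDE * P_PB``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .data import PathwayTopology
from .gene_stats import GeneLevelStats

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationResult",
    "node_delta_e",
    "perturbation_factors",
    "ora_pvalue",
    "impact_factor",
    "pe_pvalue",
    "pe_nocut_pvalue",
    "spia_net_accumulation",
    "spia_perturbation_pvalue",
    "spia_combined_pvalue",
    "pathway_express",
    "spia",
]

_COND_LIMIT = 1e12
_TINY = np.finfo(float).tiny


@dataclass
class PerturbationResult:
    """Per-pathway output of Pathway-Express / SPIA."""

    pathway: str
    method: str
    status: str = "ok"  # "ok" or "not_analyzable"
    reason: str | None = None
    pf: dict = field(default_factory=dict)
    t_a: float | None = None
    n_de_pathway: int | None = None
    mean_abs_de: float | None = None
    p_nde: float | None = None
    p_pb: float | None = None
    impact_factor: float | None = None
    statistic: float | None = None
    p_global: float | None = None

    @classmethod
    def not_analyzable(cls, pathway: str, method: str, reason: str):
        return cls(pathway=pathway, method=method, status="not_analyzable", reason=reason)


def node_delta_e(
    stats: GeneLevelStats, topology: PathwayTopology, de_only: bool = False
) -> np.ndarray:
    """Per-node Delta E: mean over mapped, measured genes; 0 otherwise.

    With ``de_only`` the contribution of non-DE genes is zeroed (the SPIA
    and cutoff Pathway-Express convention).  Genes absent from the dataset
    contribute no evidence but the node stays in the system, keeping the
    dimension of ``I - B`` equal to the topology.
    """
    out = np.zeros(topology.n_nodes)
    for i, v in enumerate(topology.nodes):
        vals = []
        for g in topology.gene_map[v]:
            if g in stats._index:
                k = stats._index[g]
                if de_only and not bool(stats.is_de[k]):
                    vals.append(0.0)
                else:
                    vals.append(float(stats.delta_e[k]))
        if vals:
            out[i] = float(np.mean(vals))
    return out


def _propagation_matrix(topology: PathwayTopology) -> np.ndarray:
    """``B`` with ``B[i, j] = beta_ij / N_ds(g_j)`` for every edge j->i."""
    if topology.edges and not topology.is_directed:
        raise ValueError("perturbation propagation requires a directed topology")
    A = topology.adjacency  # A[source, target]
    n_ds = (A != 0).sum(axis=1).astype(float)  # out-degree per source
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(n_ds[:, None] > 0, A / n_ds[:, None], 0.0)
    return scaled.T  # row = target i, column = source j


def _solve_pf(B: np.ndarray, delta: np.ndarray) -> np.ndarray:
    m = np.eye(B.shape[0]) - B
    if np.linalg.cond(m) > _COND_LIMIT:
        raise np.linalg.LinAlgError("I - B is singular")
    pf = np.linalg.solve(m, delta)
    resid = np.linalg.norm(m @ pf - delta)
    if resid > 1e-8 * max(np.linalg.norm(delta), 1.0):
        raise np.linalg.LinAlgError("PF solve did not reach tolerance")
    return pf


def perturbation_factors(delta_e: np.ndarray, topology: PathwayTopology) -> np.ndarray:
    """Solve ``(I - B) PF = Delta E`` for the node-level PF vector.

    Raises ``numpy.linalg.LinAlgError`` when ``I - B`` is singular; callers
    translate this into a not-analyzable status.
    """
    delta_e = np.asarray(delta_e, dtype=float)
    if delta_e.shape != (topology.n_nodes,):
        raise ValueError("delta_e must align with topology nodes")
    return _solve_pf(_propagation_matrix(topology), delta_e)


def ora_pvalue(
    n_de_pathway: int, pathway_size: int, n_de_universe: int, universe_size: int
) -> float:
    """Hypergeometric upper-tail ``P(X >= n_de_pathway)`` (ORA evidence)."""
    if not (0 <= n_de_pathway <= pathway_size <= universe_size):
        raise ValueError("inconsistent ORA counts")
    if n_de_universe > universe_size:
        raise ValueError("more DE genes than universe")
    if n_de_pathway == 0:
        return 1.0
    return float(
        sps.hypergeom.sf(n_de_pathway - 1, universe_size, n_de_universe, pathway_size)
    )


def impact_factor(
    p_nde: float, sum_abs_pf: float, n_de_pathway: int, mean_abs_de: float
) -> float:
    """``IF(G) = log(1/P_NDE) + sum|PF| / (N_de(G) * mean|Delta E|)``."""
    if n_de_pathway <= 0:
        raise ValueError("impact factor requires DE genes in the pathway")
    if mean_abs_de <= 0:
        raise ValueError("impact factor requires a positive mean |Delta E|")
    return float(np.log(1.0 / p_nde) + sum_abs_pf / (n_de_pathway * mean_abs_de))


def pe_pvalue(f: float) -> float:
    """Gamma(2, 1) survival at the impact factor: ``P_G = (f + 1) e^{-f}``."""
    if f < 0:
        raise ValueError("impact factor must be non-negative")
    return float((f + 1.0) * np.exp(-f))


def _random_subsets(rng: np.random.Generator, n_draws: int, pool: int, k: int) -> np.ndarray:
    """``(n_draws, k)`` array of distinct indices into ``range(pool)``."""
    keys = rng.random((n_draws, pool))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def pe_nocut_pvalue(
    stats: GeneLevelStats,
    topology: PathwayTopology,
    n_perm: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Cutoff-free Pathway-Express: gene-permutation p for ``sum |PF|``.

    The observed statistic uses the full (uncut) Delta E of the pathway's
    nodes; the null reassigns node values by sampling Delta E from all
    measured genes.  Returns ``(statistic, p)`` with the add-one estimator.
    """
    rng = np.random.default_rng(rng)
    delta = node_delta_e(stats, topology, de_only=False)
    B = _propagation_matrix(topology)
    m = np.eye(B.shape[0]) - B
    if np.linalg.cond(m) > _COND_LIMIT:
        raise np.linalg.LinAlgError("I - B is singular")
    minv = np.linalg.inv(m)
    observed = float(np.abs(minv @ delta).sum())
    pool = stats.delta_e
    idx = _random_subsets(rng, n_perm, pool.size, topology.n_nodes)
    perm_vals = pool[idx]  # (n_perm, n_nodes)
    perm_stats = np.abs(perm_vals @ minv.T).sum(axis=1)
    p = (1.0 + np.sum(perm_stats >= observed - 1e-12)) / (n_perm + 1.0)
    return observed, float(p)


def spia_net_accumulation(pf: np.ndarray, delta_e: np.ndarray) -> float:
    """``t_A(G) = sum_i {PF(g_i) - Delta E(g_i)}``."""
    return float(np.sum(pf - delta_e))


def spia_perturbation_pvalue(
    stats: GeneLevelStats,
    topology: PathwayTopology,
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = None,
    center: bool = True,
) -> tuple[float, float]:
    """Bootstrap p-value for the net accumulation ``t_A``.

    Each draw places ``N_de(G)`` Delta E values, sampled from the data's DE
    genes, on randomly chosen pathway nodes.  The permuted statistics are
    centered at their median (configurable) and compared two-sidedly with
    the observed ``t_A``.  Returns ``(t_A, P_PB)``.
    """
    rng = np.random.default_rng(rng)
    de_pool = stats.delta_e[stats.is_de]
    if de_pool.size == 0:
        raise ValueError("no DE genes in the data")
    pathway_genes = topology.genes & set(stats.feature_ids)
    nde_pathway = int(
        np.sum(stats.is_de[stats.feature_index(sorted(pathway_genes))])
    )
    if nde_pathway == 0:
        raise ValueError("no DE genes in the pathway")
    delta = node_delta_e(stats, topology, de_only=True)
    B = _propagation_matrix(topology)
    minv = np.linalg.inv(np.eye(B.shape[0]) - B)  # singularity checked upstream
    coef = minv.sum(axis=0) - 1.0  # t_A = coef . delta (linearity of the solve)
    t_obs = float(coef @ delta)
    k = min(nde_pathway, topology.n_nodes)
    pos = _random_subsets(rng, n_boot, topology.n_nodes, k)
    if de_pool.size >= k:
        val_idx = _random_subsets(rng, n_boot, de_pool.size, k)
        vals = de_pool[val_idx]
    else:
        vals = rng.choice(de_pool, size=(n_boot, k), replace=True)
    t_perm = np.sum(coef[pos] * vals, axis=1)
    med = float(np.median(t_perm)) if center else 0.0
    exceed = np.abs(t_perm - med) >= np.abs(t_obs - med) - 1e-12
    p = (1.0 + int(np.sum(exceed))) / (n_boot + 1.0)
    return t_obs, float(p)


def spia_combined_pvalue(p_nde: float, p_pb: float) -> float:
    """Fisher-style combination ``P_G = c - c ln c`` with ``c = P_NDE P_PB``."""
    for name, p in (("p_nde", p_nde), ("p_pb", p_pb)):
        if p <= 0.0:
            logger.warning("%s = %g clamped to smallest positive float", name, p)
    c = max(p_nde, _TINY) * max(p_pb, _TINY)
    return float(c - c * np.log(c))


# ---------------------------------------------------------------------------
# High-level per-pathway drivers
# ---------------------------------------------------------------------------


def pathway_express(
    stats: GeneLevelStats,
    topology: PathwayTopology,
    use_cutoff: bool = True,
    n_perm: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> PerturbationResult:
    """Run Pathway-Express (PE.Cut with ORA + impact factor, or the
    cutoff-free PE.noCut gene-permutation variant) on one pathway."""
    method = "PE.Cut" if use_cutoff else "PE.noCut"
    if not use_cutoff:
        try:
            stat, p = pe_nocut_pvalue(stats, topology, n_perm=n_perm, rng=rng)
        except np.linalg.LinAlgError:
            return PerturbationResult.not_analyzable(
                topology.name, method, "singular I - B"
            )
        return PerturbationResult(
            pathway=topology.name, method=method, statistic=stat, p_global=p
        )
    universe = set(stats.feature_ids)
    pathway_genes = sorted(topology.genes & universe)
    if not pathway_genes:
        return PerturbationResult.not_analyzable(
            topology.name, method, "no pathway genes measured"
        )
    n_de_universe = stats.n_de
    if n_de_universe == 0:
        return PerturbationResult.not_analyzable(
            topology.name, method, "no DE genes in the data"
        )
    idx = stats.feature_index(pathway_genes)
    n_de_pathway = int(np.sum(stats.is_de[idx]))
    if n_de_pathway == 0:
        return PerturbationResult.not_analyzable(
            topology.name, method, "no DE genes in the pathway"
        )
    p_nde = ora_pvalue(n_de_pathway, len(pathway_genes), n_de_universe, len(universe))
    delta = node_delta_e(stats, topology, de_only=True)
    try:
        pf = perturbation_factors(delta, topology)
    except np.linalg.LinAlgError:
        return PerturbationResult.not_analyzable(topology.name, method, "singular I - B")
    mean_abs_de = float(np.mean(np.abs(stats.delta_e[stats.is_de])))
    f = impact_factor(p_nde, float(np.abs(pf).sum()), n_de_pathway, mean_abs_de)
    return PerturbationResult(
        pathway=topology.name,
        method=method,
        pf=dict(zip(topology.nodes, pf)),
        n_de_pathway=n_de_pathway,
        mean_abs_de=mean_abs_de,
        p_nde=p_nde,
        impact_factor=f,
        statistic=f,
        p_global=pe_pvalue(f),
    )


def spia(
    stats: GeneLevelStats,
    topology: PathwayTopology,
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> PerturbationResult:
    """Run SPIA on one pathway: ORA evidence + bootstrap perturbation
    evidence, combined as ``P_G = c - c ln c``."""
    method = "SPIA"
    universe = set(stats.feature_ids)
    pathway_genes = sorted(topology.genes & universe)
    if not pathway_genes:
        return PerturbationResult.not_analyzable(
            topology.name, method, "no pathway genes measured"
        )
    if stats.n_de == 0:
        return PerturbationResult.not_analyzable(
            topology.name, method, "no DE genes in the data"
        )
    idx = stats.feature_index(pathway_genes)
    n_de_pathway = int(np.sum(stats.is_de[idx]))
    if n_de_pathway == 0:
        return PerturbationResult.not_analyzable(
            topology.name, method, "no DE genes in the pathway"
        )
    delta = node_delta_e(stats, topology, de_only=True)
    try:
        pf = perturbation_factors(delta, topology)
    except np.linalg.LinAlgError:
        return PerturbationResult.not_analyzable(topology.name, method, "singular I - B")
    p_nde = ora_pvalue(n_de_pathway, len(pathway_genes), stats.n_de, len(universe))
    t_a, p_pb = spia_perturbation_pvalue(stats, topology, n_boot=n_boot, rng=rng)
    p_g = spia_combined_pvalue(p_nde, p_pb)
    return PerturbationResult(
        pathway=topology.name,
        method=method,
        pf=dict(zip(topology.nodes, pf)),
        t_a=t_a,
        n_de_pathway=n_de_pathway,
        p_nde=p_nde,
        p_pb=p_pb,
        statistic=t_a,
        p_global=p_g,
    )
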