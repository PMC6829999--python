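"""Self-contained topology-aware tests: NetGSA, topologyGSA and DEGraph.

NetGSA models each sample as ``Y = Lambda mu_k + Lambda gamma + eps`` where
``Lambda Lambda' = (I - A)^{-1}`` is the influence matrix of the network
``A``, ``gamma ~ N(0, sigma_gamma^2 I)`` are random baseline effects and
``eps ~ N(0, sigma_eps^2 I)`` is noise.  Variance components are estimated
by restricted maximum likelihood and pathway enrichment is a Wald test of
a contrast of the condition means.

topologyGSA converts a DAG pathway to its moral graph, fits Gaussian
graphical models with covariances constrained to that graph (iterative
proportional scaling), tests equality of the two covariances by a
likelihood ratio, and then tests equality of means by a Hotelling-type
statistic (pooled covariance) or a multivariate Behrens-Fisher
approximation, depending on the variance-test outcome.

DEGraph tests equality of means in the graph-Fourier space: member
expression is projected onto the low-frequency eigenvectors of the graph
Laplacian and a Hotelling T^2 test is run in the filtered space, per
connected component; multi-component pathways are corrected by a
sample-permutation of the minimum component p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize, stats as sps

from .data import ExpressionDataset, NotAnalyzable, PathwayTopology, connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "partial_correlation_adjacency",
    "influence_matrix",
    "NetGSAModel",
    "NetGSAFit",
    "netgsa_fit",
    "netgsa_test",
    "moralize",
    "constrained_cov_mle",
    "TopologyGSAModel",
    "TopologyGSAResult",
    "topology_gsa",
    "tgsa_variance_test",
    "tgsa_mean_test",
    "graph_fourier_basis",
    "DEGraphModel",
    "DEGraphResult",
    "degraph_test",
]


# ---------------------------------------------------------------------------
# NetGSA
# ---------------------------------------------------------------------------


def partial_correlation_adjacency(covariance: np.ndarray) -> np.ndarray:
    """Partial-correlation network weights implied by a covariance matrix.

    ``A_ij = -K_ij / sqrt(K_ii K_jj)`` with ``K`` the precision matrix and
    a zero diagonal, so that ``(I - A)^{-1}`` is proportional (after
    diagonal scaling) to the input covariance.  This is the standard way
    to turn an (estimated or known) covariance into NetGSA network
    weights under connectivity constraints.
    """
    K = np.linalg.inv(np.asarray(covariance, dtype=float))
    d = np.sqrt(np.diag(K))
    A = -K / np.outer(d, d)
    np.fill_diagonal(A, 0.0)
    return A


def influence_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Cholesky factor ``Lambda`` with ``Lambda Lambda' = (I - A)^{-1}``.

    ``I - A`` must be symmetric positive definite; if the spectral radius
    of ``A`` reaches 1 the caller should rescale the weights.
    """
    A = np.asarray(adjacency, dtype=float)
    m = np.eye(A.shape[0]) - A
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("I - A must be symmetric (undirected network)")
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "I - A is not positive definite; rescale the adjacency weights"
        ) from exc
    lam = np.linalg.cholesky(np.linalg.inv(m))
    recon = lam @ lam.T - np.linalg.inv(m)
    if np.linalg.norm(recon) > 1e-8 * max(1.0, np.linalg.norm(np.linalg.inv(m))):
        raise ArithmeticError("influence matrix reconstruction failed tolerance")
    return lam


@dataclass
class NetGSAFit:
    """REML fit of the NetGSA linear mixed model."""

    feature_ids: list[str]
    beta: np.ndarray  # (2, p): condition means mu_1, mu_2
    group_means: np.ndarray  # (2, p) observed group means (Lambda mu_k scale)
    sigma_gamma2: float
    sigma_eps2: float
    n_by_group: tuple[int, int]
    eigvals: list[np.ndarray]  # spectrum of Lambda_k Lambda_k' per condition
    lam_sq_norms: dict = field(default_factory=dict)
    reml_value: float = float("nan")

    @property
    def resid_df(self) -> int:
        return sum(self.n_by_group) - 2


class NetGSAModel:
    """NetGSA engine for a fixed network (shared or per-condition).

    Pre-computes the influence matrix and its eigen-decomposition so that
    repeated fits over simulation replicates stay cheap.
    """

    def __init__(
        self,
        adjacency: np.ndarray,
        feature_ids,
        adjacency2: np.ndarray | None = None,
    ):
        self.feature_ids = list(feature_ids)
        self._index = {f: i for i, f in enumerate(self.feature_ids)}
        self.lam = [influence_matrix(adjacency)]
        if adjacency2 is not None:
            self.lam.append(influence_matrix(adjacency2))
        else:
            self.lam.append(self.lam[0])
        self._eig = []
        for lam in self.lam:
            gram = lam @ lam.T
            d, u = np.linalg.eigh(gram)
            self._eig.append((np.maximum(d, 1e-12), u))

    def fit(self, data: ExpressionDataset) -> NetGSAFit:
        """Estimate variance components by REML and condition means by GLS.

        With a saturated per-condition mean the GLS estimate of
        ``Lambda mu_k`` is the group mean, so ``mu_k = Lambda^{-1} ybar_k``
        and REML reduces to the likelihood of within-group deviations.
        """
        if data.feature_ids != self.feature_ids:
            raise ValueError("dataset features do not match the network")
        p = len(self.feature_ids)
        groups = [data.group_values(0), data.group_values(1)]
        n_k = [g.shape[1] for g in groups]
        if min(n_k) < 2:
            raise ValueError("NetGSA needs >= 2 samples per condition")
        means = [g.mean(axis=1) for g in groups]
        # rotated within-group sums of squares, per condition spectrum
        w = []
        for k, g in enumerate(groups):
            resid = g - means[k][:, None]
            rot = self._eig[k][1].T @ resid
            w.append((rot**2).sum(axis=1))
        nu = sum(n_k) - 2

        def neg_reml(log_ratio: float) -> float:
            ratio = np.exp(log_ratio)
            denom = 0.0
            logdet = 0.0
            for k in range(2):
                d = self._eig[k][0]
                scale = ratio * d + 1.0
                denom += float(np.sum(w[k] / scale))
                logdet += (n_k[k] - 1) * float(np.sum(np.log(scale)))
            sigma_eps2 = denom / (nu * p)
            return logdet + nu * p * np.log(max(sigma_eps2, 1e-300)) + nu * p

        res = optimize.minimize_scalar(
            neg_reml, bounds=(-30.0, 15.0), method="bounded",
            options={"xatol": 1e-10},
        )
        # compare against the boundary sigma_gamma2 = 0
        best = res.x if res.fun <= neg_reml(-30.0) else -30.0
        ratio = float(np.exp(best))
        if ratio < 1e-12:
            ratio = 0.0
        denom = sum(
            float(np.sum(w[k] / (ratio * self._eig[k][0] + 1.0))) for k in range(2)
        )
        sigma_eps2 = denom / (nu * p)
        sigma_gamma2 = ratio * sigma_eps2
        beta = np.vstack(
            [
                np.linalg.solve(self.lam[k], means[k])
                for k in range(2)
            ]
        )
        return NetGSAFit(
            feature_ids=self.feature_ids,
            beta=beta,
            group_means=np.vstack(means),
            sigma_gamma2=float(sigma_gamma2),
            sigma_eps2=float(sigma_eps2),
            n_by_group=(n_k[0], n_k[1]),
            eigvals=[self._eig[k][0] for k in range(2)],
            lam_sq_norms={},
            reml_value=float(res.fun),
        )

    def test(self, fit: NetGSAFit, genes) -> tuple[float, float, float]:
        """Wald test of the pathway contrast.  Returns (TS, df, p).

        The contrast is the difference of pathway-averaged propagated
        means, ``l = (-b' Lambda_1, +b' Lambda_2) / |G|``, which evaluates
        to the pathway-mean difference of the observed group means; its
        standard error comes from the fitted covariance
        ``sigma_gamma^2 Lambda_k Lambda_k' + sigma_eps^2 I``.
        """
        b = np.zeros(len(self.feature_ids))
        members = [g for g in genes if g in self._index]
        if not members:
            raise NotAnalyzable("no pathway genes in the network")
        for g in members:
            b[self._index[g]] = 1.0
        size = float(len(members))
        est = float(b @ (fit.group_means[1] - fit.group_means[0])) / size
        var = 0.0
        grad = np.zeros(2)  # d var / d (sigma_gamma2, sigma_eps2)
        for k in range(2):
            a_k = float(np.sum((self.lam[k].T @ b) ** 2))
            c_k = float(b @ b)
            var += (fit.sigma_gamma2 * a_k + fit.sigma_eps2 * c_k) / fit.n_by_group[k]
            grad += np.array([a_k, c_k]) / fit.n_by_group[k]
        var /= size**2
        grad /= size**2
        if var <= 0:
            raise NotAnalyzable("zero standard error in Wald test")
        ts = est / np.sqrt(var)
        df = self._satterthwaite_df(fit, var, grad)
        p = float(2.0 * sps.t.sf(abs(ts), df))
        return float(ts), float(df), p

    def _satterthwaite_df(self, fit: NetGSAFit, var: float, grad: np.ndarray) -> float:
        """Degrees of freedom from the REML information of the variance
        components, ``df = 2 var^2 / (g' I^{-1} g)``."""
        info = np.zeros((2, 2))
        for k in range(2):
            d = fit.eigvals[k]
            denom = (fit.sigma_gamma2 * d + fit.sigma_eps2) ** 2
            nu_k = fit.n_by_group[k] - 1
            info += 0.5 * nu_k * np.array(
                [
                    [np.sum(d**2 / denom), np.sum(d / denom)],
                    [np.sum(d / denom), np.sum(1.0 / denom)],
                ]
            )
        try:
            cov = np.linalg.inv(info)
            denom = float(grad @ cov @ grad)
        except np.linalg.LinAlgError:
            denom = 0.0
        if denom <= 0:
            return float(fit.resid_df)
        df = 2.0 * var**2 / denom
        return float(np.clip(df, 1.0, fit.resid_df))


def netgsa_fit(
    data: ExpressionDataset,
    adjacency: np.ndarray,
    adjacency2: np.ndarray | None = None,
) -> tuple[NetGSAModel, NetGSAFit]:
    """Convenience wrapper: build the model for ``adjacency`` (optionally a
    second per-condition network) and fit it to ``data``."""
    model = NetGSAModel(adjacency, data.feature_ids, adjacency2)
    return model, model.fit(data)


def netgsa_test(model: NetGSAModel, fit: NetGSAFit, genes) -> tuple[float, float, float]:
    return model.test(fit, genes)


# ---------------------------------------------------------------------------
# topologyGSA
# ---------------------------------------------------------------------------


def moralize(topology: PathwayTopology) -> nx.Graph:
    """Moral graph of a DAG pathway: marry co-parents, drop directions.

    Raises :class:`NotAnalyzable` when the directed topology has a cycle.
    """
    G = topology.to_networkx(directed=True)
    if not nx.is_directed_acyclic_graph(G):
        raise NotAnalyzable("pathway topology is not a DAG")
    moral = nx.moral_graph(G)
    out = nx.Graph()
    out.add_nodes_from(topology.nodes)
    out.add_edges_from(moral.edges())
    return out


def constrained_cov_mle(
    sample_cov: np.ndarray,
    graph: nx.Graph,
    nodes,
    tol: float = 1e-9,
    max_sweeps: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian graphical model covariance MLE by iterative proportional
    scaling over the maximal cliques of ``graph``.

    Returns ``(Sigma, K)``; the fitted covariance matches ``sample_cov``
    on every clique and the precision ``K`` is exactly zero off-graph.
    """
    nodes = list(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    S = np.asarray(sample_cov, dtype=float)
    p = S.shape[0]
    cliques = [np.array(sorted(index[v] for v in c)) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: tuple(c))
    K = np.diag(1.0 / np.diag(S))
    scale = float(np.max(np.abs(S)))
    for _ in range(max_sweeps):
        delta = 0.0
        for c in cliques:
            sigma = np.linalg.inv(K)
            update = np.linalg.inv(S[np.ix_(c, c)]) - np.linalg.inv(sigma[np.ix_(c, c)])
            K[np.ix_(c, c)] += update
            delta = max(delta, float(np.max(np.abs(update))))
        if delta < tol * max(1.0, 1.0 / scale):
            break
    sigma = np.linalg.inv(K)
    return sigma, K


def _gauss_loglik(sigma: np.ndarray, K: np.ndarray, S: np.ndarray, n: int) -> float:
    """Profile Gaussian log-likelihood (mean at MLE), up to constants."""
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise NotAnalyzable("fitted covariance not positive definite")
    return -0.5 * n * (logdet + float(np.sum(K * S)))


@dataclass
class TopologyGSAResult:
    pathway: str
    method: str = "topologyGSA"
    status: str = "ok"
    reason: str | None = None
    lrt_var: float | None = None
    p_var: float | None = None
    branch: str | None = None  # equal_var | unequal_var
    statistic: float | None = None
    df: tuple | None = None
    p: float | None = None


class TopologyGSAModel:
    """topologyGSA engine for one pathway: caches the moral graph, the
    node/feature alignment and the covariance-parameter count."""

    def __init__(self, topology: PathwayTopology):
        self.topology = topology
        self.moral = moralize(topology)  # may raise NotAnalyzable
        self.nodes = list(topology.nodes)
        self.n_cov_params = len(self.nodes) + self.moral.number_of_edges()

    def node_matrix(self, data: ExpressionDataset) -> tuple[np.ndarray, list[str]]:
        """Node-level expression: mean over mapped measured genes.  Nodes
        with no measured gene are dropped (with the induced subgraph)."""
        rows, kept = [], []
        for v in self.nodes:
            idx = [data._index[g] for g in self.topology.gene_map[v] if g in data._index]
            if idx:
                rows.append(data.values[idx].mean(axis=0))
                kept.append(v)
        return np.array(rows), kept

    def test(self, data: ExpressionDataset, alpha: float = 0.05) -> TopologyGSAResult:
        name = self.topology.name
        X, kept = self.node_matrix(data)
        if len(kept) == 0:
            return TopologyGSAResult(name, status="not_analyzable", reason="no measured genes")
        graph = self.moral.subgraph(kept)
        p = len(kept)
        n1 = data.n1
        n2 = data.n2
        if min(n1, n2) <= p:
            return TopologyGSAResult(
                name,
                status="not_analyzable",
                reason="pathway size not smaller than the minimum group size",
            )
        g0 = X[:, data.groups == 0]
        g1 = X[:, data.groups == 1]
        try:
            lrt, p_var, fits = _tgsa_variance(g0, g1, graph, kept, self.n_cov_params_of(kept))
            branch = "equal_var" if p_var >= alpha else "unequal_var"
            stat, dfs, p_mean = _tgsa_mean(g0, g1, graph, kept, branch, fits)
        except NotAnalyzable as exc:
            return TopologyGSAResult(name, status="not_analyzable", reason=exc.reason)
        return TopologyGSAResult(
            name,
            lrt_var=lrt,
            p_var=p_var,
            branch=branch,
            statistic=stat,
            df=dfs,
            p=p_mean,
        )

    def n_cov_params_of(self, kept) -> int:
        sub = self.moral.subgraph(kept)
        return len(kept) + sub.number_of_edges()


def _ml_cov(g: np.ndarray) -> np.ndarray:
    resid = g - g.mean(axis=1, keepdims=True)
    return resid @ resid.T / g.shape[1]


def _tgsa_variance(g0, g1, graph, nodes, n_params):
    n1, n2 = g0.shape[1], g1.shape[1]
    S1, S2 = _ml_cov(g0), _ml_cov(g1)
    Sp = (n1 * S1 + n2 * S2) / (n1 + n2)
    fit1 = constrained_cov_mle(S1, graph, nodes)
    fit2 = constrained_cov_mle(S2, graph, nodes)
    fitp = constrained_cov_mle(Sp, graph, nodes)
    ll_sep = _gauss_loglik(fit1[0], fit1[1], S1, n1) + _gauss_loglik(fit2[0], fit2[1], S2, n2)
    ll_pool = _gauss_loglik(fitp[0], fitp[1], S1, n1) + _gauss_loglik(fitp[0], fitp[1], S2, n2)
    lrt = max(2.0 * (ll_sep - ll_pool), 0.0)
    p_var = float(sps.chi2.sf(lrt, df=n_params))
    return lrt, p_var, (fit1, fit2, fitp)


def _tgsa_mean(g0, g1, graph, nodes, branch, fits):
    fit1, fit2, fitp = fits
    n1, n2 = g0.shape[1], g1.shape[1]
    n = n1 + n2
    p = g0.shape[0]
    d = g1.mean(axis=1) - g0.mean(axis=1)
    if branch == "equal_var":
        # Hotelling T^2 with the pooled constrained covariance (unbiased scale)
        sigma = fitp[0] * n / (n - 2)
        try:
            t2 = float(n1 * n2 / n * d @ np.linalg.solve(sigma, d))
        except np.linalg.LinAlgError:
            raise NotAnalyzable("singular pooled covariance")
        if n - p - 1 <= 0:
            raise NotAnalyzable("not enough samples for the F reference")
        f_stat = t2 * (n - p - 1) / ((n - 2) * p)
        p_val = float(sps.f.sf(f_stat, p, n - p - 1))
        return t2, (p, n - p - 1), p_val
    # Behrens-Fisher branch: Krishnamoorthy-Yu Satterthwaite-matched F
    s1 = fit1[0] * n1 / (n1 - 1) / n1
    s2 = fit2[0] * n2 / (n2 - 1) / n2
    try:
        w = np.linalg.inv(s1 + s2)
    except np.linalg.LinAlgError:
        raise NotAnalyzable("singular combined covariance")
    t2 = float(d @ w @ d)
    acc = 0.0
    for s_k, n_k in ((s1, n1), (s2, n2)):
        m = s_k @ w
        acc += (np.trace(m @ m) + np.trace(m) ** 2) / (n_k - 1)
    nu = (p + p**2) / max(acc, 1e-12)
    nu = max(nu, p + 1.0 + 1e-6)
    f_stat = t2 * (nu - p + 1) / (nu * p)
    p_val = float(sps.f.sf(f_stat, p, nu - p + 1))
    return t2, (p, nu - p + 1), p_val


def topology_gsa(
    data: ExpressionDataset, topology: PathwayTopology, alpha: float = 0.05
) -> TopologyGSAResult:
    """Run topologyGSA on one pathway (DAG check, variance LRT, mean test)."""
    try:
        model = TopologyGSAModel(topology)
    except NotAnalyzable as exc:
        return TopologyGSAResult(
            topology.name, status="not_analyzable", reason=exc.reason
        )
    return model.test(data, alpha=alpha)


def tgsa_variance_test(data: ExpressionDataset, topology: PathwayTopology):
    """Equality-of-covariances LRT under the moral-graph constraint.
    Returns (LRT, df, p)."""
    model = TopologyGSAModel(topology)
    X, kept = model.node_matrix(data)
    graph = model.moral.subgraph(kept)
    if min(data.n1, data.n2) <= len(kept):
        raise NotAnalyzable("pathway size not smaller than the minimum group size")
    g0, g1 = X[:, data.groups == 0], X[:, data.groups == 1]
    df = model.n_cov_params_of(kept)
    lrt, p_var, _ = _tgsa_variance(g0, g1, graph, kept, df)
    return lrt, df, p_var


def tgsa_mean_test(
    data: ExpressionDataset, topology: PathwayTopology, alpha: float = 0.05
):
    """Equality-of-means test, branching on the variance test at ``alpha``.
    Returns a :class:`TopologyGSAResult`."""
    return topology_gsa(data, topology, alpha=alpha)


# ---------------------------------------------------------------------------
# DEGraph
# ---------------------------------------------------------------------------


def graph_fourier_basis(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the combinatorial Laplacian of an undirected
    component.  Returns (eigenvalues ascending, orthonormal basis columns);
    the first eigenvector of a connected component is constant."""
    A = (np.abs(np.asarray(adjacency, dtype=float)) > 0).astype(float)
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    L = np.diag(A.sum(axis=1)) - A
    evals, evecs = np.linalg.eigh(L)
    return evals, evecs


@dataclass
class DEGraphResult:
    pathway: str
    method: str = "DEGraph"
    status: str = "ok"
    reason: str | None = None
    component_p: list = field(default_factory=list)
    t2: float | None = None
    k: int | None = None
    p: float | None = None


def _hotelling_two_sample(X: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Classical two-sample Hotelling T^2 in k dimensions with an F
    reference.  ``X`` is (k, n).  Returns (T^2, p)."""
    k, n = X.shape
    g0, g1 = X[:, groups == 0], X[:, groups == 1]
    n0, n1 = g0.shape[1], g1.shape[1]
    d = g1.mean(axis=1) - g0.mean(axis=1)
    r0 = g0 - g0.mean(axis=1, keepdims=True)
    r1 = g1 - g1.mean(axis=1, keepdims=True)
    s_pool = (r0 @ r0.T + r1 @ r1.T) / (n - 2)
    if k == 1:
        var = float(s_pool[0, 0])
        if var == 0:
            return 0.0, 1.0
        t2 = n0 * n1 / n * d[0] ** 2 / var
    else:
        try:
            t2 = float(n0 * n1 / n * d @ np.linalg.solve(s_pool, d))
        except np.linalg.LinAlgError:
            raise NotAnalyzable("singular pooled covariance in filtered space")
    if n - k - 1 <= 0:
        raise NotAnalyzable("not enough samples for the F reference")
    f_stat = t2 * (n - k - 1) / ((n - 2) * k)
    return t2, float(sps.f.sf(f_stat, k, n - k - 1))


class DEGraphModel:
    """DEGraph engine for one pathway: caches components and Fourier bases.

    ``k`` is the number of retained low-frequency components; the default
    keeps ceil(0.2 * component size), at least 2, clamped to the component
    size.  A fraction in (0, 1) may be given instead of a count.
    """

    def __init__(self, topology: PathwayTopology, k: int | float | None = None):
        self.topology = topology
        self.k = k
        comps = connected_components(topology)
        order = {v: i for i, v in enumerate(topology.nodes)}
        A = topology.adjacency
        self.components = []
        for comp in comps:
            idx = np.array(sorted(order[v] for v in comp))
            evals, evecs = graph_fourier_basis(A[np.ix_(idx, idx)])
            self.components.append(([topology.nodes[i] for i in idx], evals, evecs))

    def _k_for(self, size: int, n: int) -> int:
        if self.k is None:
            k = max(2, int(np.ceil(0.2 * size)))
        elif isinstance(self.k, float) and 0 < self.k < 1:
            k = max(2, int(np.ceil(self.k * size)))
        else:
            k = int(self.k)
        if k > size and self.k is not None:
            logger.warning("DEGraph %s: k clamped to component size", self.topology.name)
        return int(min(k, size, n - 2))

    def _component_data(self, data: ExpressionDataset):
        """Projected node-level matrices, one per analyzable component."""
        out = []
        for nodes, _evals, evecs in self.components:
            rows, kept_pos = [], []
            for pos, v in enumerate(nodes):
                idx = [
                    data._index[g]
                    for g in self.topology.gene_map[v]
                    if g in data._index
                ]
                if idx:
                    rows.append(data.values[idx].mean(axis=0))
                    kept_pos.append(pos)
            if not rows:
                continue
            X = np.array(rows)
            if len(kept_pos) == len(nodes):
                basis = evecs
            else:
                # recompute the basis on the measured induced subgraph
                order = {v: i for i, v in enumerate(self.topology.nodes)}
                idxs = np.array([order[nodes[p]] for p in kept_pos])
                A = self.topology.adjacency
                _, basis = graph_fourier_basis(A[np.ix_(idxs, idxs)])
            k = self._k_for(X.shape[0], data.n_samples)
            out.append(basis[:, :k].T @ X)  # (k, n)
        return out

    def test(
        self,
        data: ExpressionDataset,
        n_perm: int = 200,
        rng: np.random.Generator | int | None = None,
    ) -> DEGraphResult:
        name = self.topology.name
        try:
            projected = self._component_data(data)
            if not projected:
                return DEGraphResult(name, status="not_analyzable", reason="no measured genes")
            stats = [_hotelling_two_sample(P, data.groups) for P in projected]
        except NotAnalyzable as exc:
            return DEGraphResult(name, status="not_analyzable", reason=exc.reason)
        pvals = [p for (_t2, p) in stats]
        best = int(np.argmin(pvals))
        t2, k = stats[best][0], projected[best].shape[0]
        if len(projected) == 1:
            return DEGraphResult(name, component_p=pvals, t2=t2, k=k, p=pvals[best])
        # multi-component correction: permutation null of the min p-value
        rng = np.random.default_rng(rng)
        obs = min(pvals)
        count = 0
        for _ in range(n_perm):
            perm_groups = rng.permutation(data.groups)
            try:
                perm_p = min(
                    _hotelling_two_sample(P, perm_groups)[1] for P in projected
                )
            except NotAnalyzable:
                perm_p = 1.0
            if perm_p <= obs + 1e-12:
                count += 1
        p_corr = (1.0 + count) / (n_perm + 1.0)
        return DEGraphResult(name, component_p=pvals, t2=t2, k=k, p=float(p_corr))


def degraph_test(
    data: ExpressionDataset,
    topology: PathwayTopology,
    k: int | float | None = None,
    n_perm: int = 200,
    rng: np.random.Generator | int | None = None,
) -> DEGraphResult:
    """Run DEGraph on one pathway (see :class:`DEGraphModel`)."""
    return DEGraphModel(topology, k=k).test(data, n_perm=n_perm, rng=rng)
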