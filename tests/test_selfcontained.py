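"""NetGSA / topologyGSA / DEGraph: influence algebra, REML recovery,
graphical-model MLE against a numerical optimizer, graph-Fourier tests
against textbook Hotelling."""

import networkx as nx
import numpy as np
import pytest
from scipy import optimize, stats as sps

from pathbench.data import NotAnalyzable, PathwayTopology
from pathbench.gene_stats import welch_stats
from pathbench.selfcontained import (
    DEGraphModel,
    NetGSAModel,
    TopologyGSAModel,
    constrained_cov_mle,
    degraph_test,
    graph_fourier_basis,
    influence_matrix,
    moralize,
    partial_correlation_adjacency,
    topology_gsa,
)
from pathbench.simulate import synthetic_signaling_pathways
from tests.conftest import make_dataset


def hotelling_oracle(X, groups):
    """Textbook two-sample Hotelling T^2 with F reference (independent
    implementation used as the oracle)."""
    g0, g1 = X[:, groups == 0], X[:, groups == 1]
    n0, n1 = g0.shape[1], g1.shape[1]
    n, k = n0 + n1, X.shape[0]
    d = g1.mean(axis=1) - g0.mean(axis=1)
    S = ((n0 - 1) * np.cov(g0) + (n1 - 1) * np.cov(g1)) / (n - 2)
    S = np.atleast_2d(S)
    t2 = n0 * n1 / n * float(d @ np.linalg.solve(S, d))
    f = t2 * (n - k - 1) / ((n - 2) * k)
    return t2, float(sps.f.sf(f, k, n - k - 1))


class TestInfluence:
    def test_identity_for_empty_network(self):
        np.testing.assert_allclose(influence_matrix(np.zeros((3, 3))), np.eye(3))

    def test_two_node_closed_form(self):
        A = np.array([[0.0, 0.5], [0.5, 0.0]])
        lam = influence_matrix(A)
        inv = np.linalg.inv(np.eye(2) - A)  # hand-invertible 2x2
        np.testing.assert_allclose(lam @ lam.T, inv, atol=1e-10)
        assert lam[0, 1] == pytest.approx(0.0)  # lower-triangular factor

    def test_spectral_radius_one_rejected(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="positive definite"):
            influence_matrix(A)

    def test_partial_correlation_adjacency_inverts_block(self):
        sigma = np.array([[1.0, 0.3, 0.3], [0.3, 1.0, 0.3], [0.3, 0.3, 1.0]])
        A = partial_correlation_adjacency(sigma)
        assert np.all(np.diag(A) == 0)
        # (I - A) must be proportional to the precision up to diagonal scaling
        gram = np.linalg.inv(np.eye(3) - A)
        corr = gram / np.sqrt(np.outer(np.diag(gram), np.diag(gram)))
        np.testing.assert_allclose(corr, sigma, atol=1e-10)


class TestNetGSA:
    def _simulate(self, lam, mu1, mu2, n1, n2, sg2, se2, rng):
        p = lam.shape[0]
        ys = []
        for mu, n in ((mu1, n1), (mu2, n2)):
            gamma = rng.normal(0, np.sqrt(sg2), size=(p, n))
            eps = rng.normal(0, np.sqrt(se2), size=(p, n))
            ys.append(lam @ (mu[:, None] + gamma) + eps)
        values = np.hstack(ys)
        return make_dataset(values, groups=[0] * n1 + [1] * n2)

    def test_identity_network_recovers_group_means(self):
        rng = np.random.default_rng(0)
        p = 10
        mu1, mu2 = np.zeros(p), np.full(p, 0.5)
        lam = np.eye(p)
        ds = self._simulate(lam, mu1, mu2, 60, 60, 0.0, 1.0, rng)
        model = NetGSAModel(np.zeros((p, p)), ds.feature_ids)
        fit = model.fit(ds)
        assert fit.sigma_gamma2 + fit.sigma_eps2 == pytest.approx(1.0, abs=0.15)
        np.testing.assert_allclose(fit.beta[0], ds.group_values(0).mean(axis=1))
        np.testing.assert_allclose(fit.beta[1], ds.group_values(1).mean(axis=1))

    def test_reml_recovers_variance_components_on_chain(self):
        # chain network, sigma_gamma2 = 1, sigma_eps2 = 0.25
        p, reps = 10, 30
        A = np.zeros((p, p))
        for i in range(p - 1):
            A[i, i + 1] = A[i + 1, i] = 0.4
        lam = influence_matrix(A)
        rng = np.random.default_rng(42)
        model = NetGSAModel(A, [f"g{i}" for i in range(p)])
        est = []
        for _ in range(reps):
            ds = self._simulate(lam, np.zeros(p), np.zeros(p), 50, 50, 1.0, 0.25, rng)
            fit = model.fit(ds)
            est.append((fit.sigma_gamma2, fit.sigma_eps2))
        est = np.array(est)
        se = est.std(axis=0) / np.sqrt(reps)
        assert abs(est[:, 0].mean() - 1.0) < 2.5 * max(se[0], 0.02)
        assert abs(est[:, 1].mean() - 0.25) < 2.5 * max(se[1], 0.02)

    def test_null_contrast_near_zero(self):
        rng = np.random.default_rng(5)
        p = 8
        lam = np.eye(p)
        mu = rng.standard_normal(p)
        ds = self._simulate(lam, mu, mu, 40, 40, 0.5, 0.5, rng)
        model = NetGSAModel(np.zeros((p, p)), ds.feature_ids)
        fit = model.fit(ds)
        ts, df, pval = model.test(fit, ds.feature_ids[:4])
        assert abs(ts) < 3.0 and pval > 0.001

    def test_reduces_to_pathway_mean_t_test_without_network(self):
        rng = np.random.default_rng(9)
        p, n = 30, 200
        ds = make_dataset(rng.standard_normal((p, n)))
        model = NetGSAModel(np.zeros((p, p)), ds.feature_ids)
        fit = model.fit(ds)
        members = ds.feature_ids[:6]
        ts, _df, _p = model.test(fit, members)
        avg = ds.values[:6].mean(axis=0)
        t_direct = sps.ttest_ind(avg[ds.groups == 1], avg[ds.groups == 0]).statistic
        assert ts == pytest.approx(t_direct, abs=0.25)

    def test_detects_mean_shift(self):
        rng = np.random.default_rng(3)
        p = 12
        A = np.zeros((p, p))
        lam = np.eye(p)
        mu2 = np.zeros(p)
        mu2[:4] = 0.5
        ds = self._simulate(lam, np.zeros(p), mu2, 60, 60, 0.2, 0.8, rng)
        model = NetGSAModel(A, ds.feature_ids)
        fit = model.fit(ds)
        _ts, _df, pval = model.test(fit, ds.feature_ids[:4])
        assert pval < 0.01

    def test_rewired_network_with_common_baseline_detected(self):
        # identical baseline means, different condition networks: the
        # propagated means Lambda_k mu differ, which the contrast picks up
        rng = np.random.default_rng(8)
        p = 10
        A1 = np.zeros((p, p))
        A2 = np.zeros((p, p))
        for i in range(p - 1):
            A2[i, i + 1] = A2[i + 1, i] = 0.45
        lam1, lam2 = influence_matrix(A1), influence_matrix(A2)
        mu = np.full(p, 1.0)
        rejections = 0
        for r in range(20):
            ys = []
            for lam, n in ((lam1, 40), (lam2, 40)):
                gamma = rng.normal(0, 0.3, size=(p, n))
                eps = rng.normal(0, 0.5, size=(p, n))
                ys.append(lam @ (mu[:, None] + gamma) + eps)
            ds = make_dataset(np.hstack(ys), groups=[0] * 40 + [1] * 40)
            model = NetGSAModel(A1, ds.feature_ids, adjacency2=A2)
            fit = model.fit(ds)
            _ts, _df, pval = model.test(fit, ds.feature_ids)
            rejections += pval <= 0.05
        assert rejections / 20 > 0.3  # well above the nominal level


class TestMoralize:
    def test_v_structure_marries_parents(self):
        topo = PathwayTopology(
            name="v",
            nodes=["a", "b", "c"],
            edges=[("a", "c", 1.0, True), ("b", "c", 1.0, True)],
        )
        moral = moralize(topo)
        assert moral.has_edge("a", "b") and moral.has_edge("a", "c")

    def test_chain_has_no_extra_edges(self, chain3_directed):
        moral = moralize(chain3_directed)
        assert sorted(map(sorted, moral.edges())) == [["a", "b"], ["b", "c"]]

    def test_cycle_not_analyzable(self):
        topo = PathwayTopology(
            name="cy",
            nodes=["a", "b"],
            edges=[("a", "b", 1.0, True), ("b", "a", 1.0, True)],
        )
        with pytest.raises(NotAnalyzable):
            moralize(topo)


class TestConstrainedCov:
    def _sample_cov(self, p, seed, n=200):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((p, n))
        return np.cov(x, ddof=0)

    def test_complete_graph_is_unconstrained(self):
        S = self._sample_cov(3, 0)
        g = nx.complete_graph(3)
        sigma, _ = constrained_cov_mle(S, g, [0, 1, 2])
        np.testing.assert_allclose(sigma, S, atol=1e-7)

    def test_empty_graph_is_independence_model(self):
        S = self._sample_cov(3, 1)
        g = nx.empty_graph(3)
        sigma, K = constrained_cov_mle(S, g, [0, 1, 2])
        np.testing.assert_allclose(sigma, np.diag(np.diag(S)), atol=1e-8)

    def test_off_graph_precision_zero_and_clique_match(self):
        S = self._sample_cov(4, 2)
        g = nx.path_graph(4)
        sigma, K = constrained_cov_mle(S, g, [0, 1, 2, 3])
        assert abs(K[0, 2]) < 1e-6 and abs(K[0, 3]) < 1e-6 and abs(K[1, 3]) < 1e-6
        for i, j in g.edges():
            assert sigma[i, j] == pytest.approx(S[i, j], abs=1e-7)
        np.testing.assert_allclose(np.diag(sigma), np.diag(S), atol=1e-7)

    def test_matches_numerical_likelihood_maximization_on_chain(self):
        # independent oracle: maximize the Gaussian log-likelihood over the
        # free precision entries of the 3-chain with a generic optimizer
        S = self._sample_cov(3, 3)
        g = nx.path_graph(3)
        sigma, _ = constrained_cov_mle(S, g, [0, 1, 2])

        def unpack(theta):
            k11, k22, k33, k12, k23 = theta
            return np.array([[k11, k12, 0.0], [k12, k22, k23], [0.0, k23, k33]])

        def negloglik(theta):
            K = unpack(theta)
            sign, logdet = np.linalg.slogdet(K)
            if sign <= 0:
                return 1e9
            return -(logdet - float(np.sum(K * S)))

        x0 = np.array([1.0 / S[0, 0], 1.0 / S[1, 1], 1.0 / S[2, 2], 0.0, 0.0])
        res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        sigma_opt = np.linalg.inv(unpack(res.x))
        np.testing.assert_allclose(sigma, sigma_opt, atol=1e-4)


class TestTopologyGSA:
    def _dataset(self, topo, shift=0.0, seed=0, n=60, sd=1.0):
        rng = np.random.default_rng(seed)
        p = topo.n_nodes
        values = rng.standard_normal((p, 2 * n)) * sd
        groups = np.array([0] * n + [1] * n)
        values[:, groups == 1] += shift
        return make_dataset(values, feature_ids=list(topo.nodes), groups=groups)

    def test_identical_distributions_keep_null(self, chain3_directed):
        ds = self._dataset(chain3_directed, seed=4)
        res = topology_gsa(ds, chain3_directed)
        assert res.status == "ok"
        assert res.p > 0.01 and res.p_var > 0.01

    def test_cycle_reported_not_analyzable(self):
        topo = PathwayTopology(
            name="cy",
            nodes=["a", "b"],
            edges=[("a", "b", 1.0, True), ("b", "a", 1.0, True)],
        )
        ds = self._dataset(PathwayTopology(name="x", nodes=["a", "b"]), seed=1)
        res = topology_gsa(ds, topo)
        assert res.status == "not_analyzable" and "DAG" in res.reason

    def test_small_sample_not_analyzable(self, chain3_directed):
        ds = self._dataset(chain3_directed, seed=2, n=3)
        res = topology_gsa(ds, chain3_directed)
        assert res.status == "not_analyzable"

    def test_variance_test_detects_scale_change(self, chain3_directed):
        rng = np.random.default_rng(11)
        p, n = 3, 100
        values = np.hstack(
            [rng.standard_normal((p, n)), 2.0 * rng.standard_normal((p, n))]
        )
        ds = make_dataset(values, feature_ids=list(chain3_directed.nodes),
                          groups=[0] * n + [1] * n)
        res = topology_gsa(ds, chain3_directed)
        assert res.p_var < 0.01 and res.branch == "unequal_var"

    def test_equal_branch_complete_graph_matches_hotelling_oracle(self):
        # a complete moral graph leaves the covariance unconstrained, so
        # the mean test must agree with classical Hotelling T^2
        topo = PathwayTopology(
            name="tri",
            nodes=["a", "b", "c"],
            edges=[("a", "c", 1.0, True), ("b", "c", 1.0, True), ("a", "b", 1.0, True)],
        )
        ds = self._dataset(topo, shift=0.25, seed=6, n=80)
        res = topology_gsa(ds, topo)
        assert res.branch == "equal_var"
        X = ds.values
        t2, p = hotelling_oracle(X, ds.groups)
        assert res.statistic == pytest.approx(t2, rel=1e-8)
        assert res.p == pytest.approx(p, rel=1e-8)

    def test_mean_shift_detected(self, chain3_directed):
        ds = self._dataset(chain3_directed, shift=0.5, seed=7, n=100)
        res = topology_gsa(ds, chain3_directed)
        assert res.p < 1e-4


class TestGraphFourier:
    def test_path3_spectrum(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        evals, evecs = graph_fourier_basis(A)
        np.testing.assert_allclose(evals, [0.0, 1.0, 3.0], atol=1e-10)
        first = evecs[:, 0]
        np.testing.assert_allclose(first, np.full(3, first[0]), atol=1e-10)
        np.testing.assert_allclose(evecs.T @ evecs, np.eye(3), atol=1e-10)


class TestDEGraph:
    def test_full_basis_equals_unfiltered_hotelling(self):
        topo = synthetic_signaling_pathways(n_pathways=1, size=6, seed=2).pathways[0]
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.standard_normal((6, 60)) + 0.2,
                          feature_ids=list(topo.nodes))
        res = degraph_test(ds, topo, k=6)
        t2, p = hotelling_oracle(ds.values, ds.groups)
        assert res.p == pytest.approx(p, rel=1e-8)

    def test_single_gene_component_is_squared_t(self):
        topo = PathwayTopology(name="one", nodes=["g0"])
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.standard_normal((1, 40)))
        res = degraph_test(ds, topo)
        t = sps.ttest_ind(
            ds.values[0, ds.groups == 1], ds.values[0, ds.groups == 0]
        )
        assert res.t2 == pytest.approx(t.statistic**2, rel=1e-8)
        assert res.p == pytest.approx(t.pvalue, rel=1e-6)

    def test_filtered_beats_unfiltered_on_smooth_shift(self):
        # shift aligned with the lowest non-constant Fourier mode: the
        # filtered test should reject at least as often as the full T^2
        topo = synthetic_signaling_pathways(n_pathways=1, size=12, seed=5).pathways[0]
        model = DEGraphModel(topo, k=3)
        full = DEGraphModel(topo, k=12)
        _nodes, evals, evecs = model.components[0]
        shift = evecs[:, 1] * 0.8
        rng = np.random.default_rng(3)
        wins_f, wins_u = 0, 0
        for r in range(25):
            values = rng.standard_normal((12, 30))
            groups = np.array([0] * 15 + [1] * 15)
            values[:, groups == 1] += shift[:, None]
            ds = make_dataset(values, feature_ids=list(topo.nodes), groups=groups)
            wins_f += model.test(ds).p <= 0.05
            wins_u += full.test(ds).p <= 0.05
        assert wins_f >= wins_u

    def test_multi_component_min_p_correction(self):
        topo = PathwayTopology(
            name="two",
            nodes=["a", "b", "c", "d"],
            edges=[("a", "b", 1.0, False), ("c", "d", 1.0, False)],
        )
        rng = np.random.default_rng(4)
        ds = make_dataset(rng.standard_normal((4, 40)),
                          feature_ids=["a", "b", "c", "d"])
        res = degraph_test(ds, topo, n_perm=99, rng=0)
        assert res.status == "ok"
        assert len(res.component_p) == 2
        assert 1.0 / 100.0 <= res.p <= 1.0
        # correction cannot make the result more significant than min p
        assert res.p >= min(res.component_p) - 1e-12

    def test_null_pvalues_roughly_uniform(self):
        topo = synthetic_signaling_pathways(n_pathways=1, size=8, seed=9).pathways[0]
        model = DEGraphModel(topo)
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(60):
            ds = make_dataset(rng.standard_normal((8, 40)),
                              feature_ids=list(topo.nodes))
            pvals.append(model.test(ds).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
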