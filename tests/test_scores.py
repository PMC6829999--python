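"""CePa / PRS / PathNet / CAMERA: node mapping, score algebra, permutation
nulls against exhaustive enumeration, and the VIF-adjusted test."""

from itertools import combinations, permutations

import numpy as np
import pytest
from scipy import stats as sps

from pathbench.data import PathwayCollection, PathwayTopology
from pathbench.scores import (
    CEPA_MEASURES,
    camera_test,
    cepa_pvalue,
    cepa_score,
    cepa_weights,
    map_genes_to_nodes,
    pathnet_combined_evidence,
    pathnet_indirect_evidence,
    pathnet_pathway_pvalue,
    pooled_adjacency,
    prs_pvalue,
    prs_score,
)
from pathbench.gene_stats import welch_stats
from tests.conftest import make_dataset
from tests.test_perturbation import stats_from


class TestNodeMapping:
    def test_or_semantics_and_max_fc(self):
        topo = PathwayTopology(
            name="p",
            nodes=["n1", "n2"],
            gene_map={"n1": {"g0", "g1"}, "n2": {"g9"}},
        )
        stats = stats_from([0.8, -0.2, 0.1], is_de=[True, False, False])
        ns = map_genes_to_nodes(stats, topo)
        assert ns.node_de[0] and not ns.node_de[1]  # OR over genes; unmeasured false
        assert ns.node_fc[0] == pytest.approx(0.8)
        assert not ns.measured[1] and ns.node_value[1] == 0.0

    def test_relaxed_gate_lifts_de_nodes_above_one(self):
        topo = PathwayTopology(name="p", nodes=["g0"])
        stats = stats_from([0.8], is_de=[True])
        assert map_genes_to_nodes(stats, topo).node_value[0] > 1.0
        literal = map_genes_to_nodes(stats, topo, prs_gate="literal")
        assert literal.node_value[0] == pytest.approx(0.8)


class TestCePa:
    def test_equal_weights_offset(self, path3_undirected):
        w = cepa_weights(path3_undirected, "equal")
        np.testing.assert_allclose(w, 1.01)

    def test_betweenness_weights_on_path(self, path3_undirected):
        w = dict(zip(path3_undirected.nodes, cepa_weights(path3_undirected, "betweenness")))
        assert w == {"a": 0.01, "b": 1.01, "c": 0.01}

    def test_isolated_node_degree_weight(self):
        topo = PathwayTopology(name="i", nodes=["a"])
        assert cepa_weights(topo, "in-degree")[0] == pytest.approx(0.01)

    def test_unknown_measure(self, path3_undirected):
        with pytest.raises(ValueError):
            cepa_weights(path3_undirected, "pagerank")

    def test_score_examples(self, path3_undirected):
        d3 = np.array([True, True, True])
        assert cepa_score(d3, cepa_weights(path3_undirected, "equal")) == pytest.approx(3.03)
        assert cepa_score(np.zeros(3, bool), np.ones(3)) == 0.0
        only_b = np.array([False, True, False])
        assert cepa_score(only_b, cepa_weights(path3_undirected, "betweenness")) == pytest.approx(1.01)

    def test_all_genes_de_gives_p_one(self, path3_undirected):
        stats = stats_from([1.0, 1.0, 1.0], is_de=[True] * 3, feature_ids=["a", "b", "c"])
        res = cepa_pvalue(stats, path3_undirected, n_perm=50, rng=0)
        assert all(p == 1.0 for p in res.p_per_measure.values())

    def test_p_min_dominates(self, signal_stats):
        topo = PathwayTopology(
            name="p", nodes=["g0", "g1", "g2"], edges=[("g0", "g1", 1.0, False)]
        )
        res = cepa_pvalue(signal_stats, topo, n_perm=200, rng=0)
        assert res.p_min <= min(res.p_per_measure.values()) + 1e-12
        assert res.p_min <= np.mean(list(res.p_per_measure.values()))

    def test_exhaustive_matches_independent_enumeration(self, path3_undirected):
        # 4-gene universe, 1 DE; nodes a, b, c map to g0, g1, g2
        topo = PathwayTopology(
            name="p3",
            nodes=["a", "b", "c"],
            edges=[("a", "b", 1.0, False), ("b", "c", 1.0, False)],
            gene_map={"a": {"g0"}, "b": {"g1"}, "c": {"g2"}},
        )
        stats = stats_from([1.0, 0.1, 0.1, 0.1], is_de=[True, False, False, False])
        res = cepa_pvalue(stats, topo, exhaustive=True)
        # independent oracle: enumerate the 4 label placements by hand
        gene_of_node = {"a": 0, "b": 1, "c": 2}
        for measure in CEPA_MEASURES:
            w = dict(zip(topo.nodes, cepa_weights(topo, measure)))
            s_obs = w["a"]  # observed: g0 (node a) is DE
            scores = []
            for de_gene in range(4):
                s = sum(
                    w[v] for v, g in gene_of_node.items() if g == de_gene
                )
                scores.append(s)
            exact = np.mean([s >= s_obs - 1e-12 for s in scores])
            assert res.p_per_measure[measure] == pytest.approx(exact)

    def test_na_without_de_genes(self, small_stats, path3_undirected):
        small_stats.is_de = np.zeros(8, bool)
        res = cepa_pvalue(small_stats, path3_undirected, n_perm=10, rng=0)
        assert res.status == "not_analyzable"


class TestPRS:
    def test_single_de_node_no_edges(self):
        topo = PathwayTopology(name="p", nodes=["g0"])
        stats = stats_from([2.0], is_de=[True])
        res = prs_score(stats, topo)
        assert res.node_weight["g0"] == 1.0 and res.raw == pytest.approx(2.0)

    def test_chain_of_two_de_nodes(self):
        topo = PathwayTopology(
            name="p", nodes=["g0", "g1"], edges=[("g0", "g1", 1.0, True)]
        )
        stats = stats_from([2.0, 2.0], is_de=[True, True])
        res = prs_score(stats, topo)
        assert res.node_weight == {"g0": 2.0, "g1": 1.0}
        assert res.raw == pytest.approx(6.0)
        assert res.normalized == pytest.approx(6.0)  # all genes DE

    def test_no_de_nodes_scores_zero(self, small_stats):
        topo = PathwayTopology(name="p", nodes=["g0", "g1"])
        small_stats.is_de = np.zeros(8, bool)
        res = prs_score(small_stats, topo)
        assert res.raw == 0.0 and res.normalized == 0.0

    def test_paths_blocked_by_non_de_intermediate(self):
        # g0 -> g1 -> g2 with g1 non-differential: g0 cannot reach g2
        topo = PathwayTopology(
            name="p",
            nodes=["g0", "g1", "g2"],
            edges=[("g0", "g1", 1.0, True), ("g1", "g2", 1.0, True)],
        )
        stats = stats_from([2.0, 0.0, 2.0], is_de=[True, False, True])
        res = prs_score(stats, topo)
        assert res.node_weight["g0"] == 1.0 and res.node_weight["g2"] == 1.0

    def test_score_monotone_when_node_becomes_de(self):
        topo = PathwayTopology(
            name="p",
            nodes=["g0", "g1", "g2"],
            edges=[("g0", "g1", 1.0, True), ("g1", "g2", 1.0, True)],
        )
        base = prs_score(stats_from([2.0, 0.1, 2.0], is_de=[True, False, True]), topo)
        more = prs_score(stats_from([2.0, 2.0, 2.0], is_de=[True, True, True]), topo)
        assert more.raw >= base.raw

    def test_exhaustive_matches_brute_force(self):
        topo = PathwayTopology(
            name="p", nodes=["g0", "g1"], edges=[("g0", "g1", 1.0, True)]
        )
        delta = np.array([2.0, 0.3, 1.5, 0.2])
        is_de = np.array([True, False, True, False])
        stats = stats_from(delta, is_de)
        res = prs_pvalue(stats, topo, exhaustive=True)
        # brute force over all 4! joint reassignments of (dE, DE) pairs
        def norm_score(order):
            s = stats_from(delta[list(order)], is_de[list(order)])
            return prs_score(s, topo).normalized

        scores = np.array([norm_score(o) for o in permutations(range(4))])
        mu, sd = scores.mean(), scores.std()
        obs = (prs_score(stats, topo).normalized - mu) / sd
        exact = np.mean((scores - mu) / sd >= obs - 1e-12)
        assert res.p == pytest.approx(exact)

    def test_degenerate_permutation_distribution(self):
        topo = PathwayTopology(name="p", nodes=["g0"])
        stats = stats_from([1.0, 1.0], is_de=[True, True])
        res = prs_pvalue(stats, topo, n_perm=20, rng=0)
        assert res.p == 1.0


class TestPathNet:
    def test_indirect_evidence_examples(self):
        A = np.zeros((3, 3))
        si = pathnet_indirect_evidence(np.array([0.5, 0.01, 0.1]), A)
        np.testing.assert_allclose(si, 0.0)  # isolated genes
        A[0, 1] = A[1, 0] = 1.0
        si = pathnet_indirect_evidence(np.array([0.5, 0.01, 0.1]), A)
        assert si[0] == pytest.approx(2.0)  # one neighbor at p=0.01
        A[0, 2] = A[2, 0] = 1.0
        si = pathnet_indirect_evidence(np.array([0.5, 0.1, 0.1]), A)
        assert si[0] == pytest.approx(2.0)  # two neighbors at p=0.1

    def test_fisher_combination_chi2_4df(self):
        A = np.zeros((2, 2))
        ev = pathnet_combined_evidence(np.array([1.0, 1.0]), A, n_perm=50, rng=0)
        np.testing.assert_allclose(ev.p_combined, 1.0)
        # p_D = p_I = e^{-1} gives chi2 = 4 on 4 df; sf = e^{-2}(1 + 2)
        assert sps.chi2.sf(4.0, 4) == pytest.approx(3.0 * np.exp(-2.0), abs=1e-10)

    def test_constant_si_not_discriminating(self):
        # 4-cycle is vertex-transitive: equal p_direct -> equal SI, p_I ~ 1
        A = np.zeros((4, 4))
        for i in range(4):
            A[i, (i + 1) % 4] = A[(i + 1) % 4, i] = 1.0
        ev = pathnet_combined_evidence(np.full(4, 0.2), A, n_perm=99, rng=0)
        assert np.ptp(ev.si) == 0.0
        np.testing.assert_allclose(ev.p_indirect, 1.0)

    def test_pathway_hypergeometric(self):
        genes = [f"g{i}" for i in range(10)]
        ev_sig = np.zeros(10, bool)
        ev_sig[:4] = True
        ev = pathnet_combined_evidence(np.full(10, 0.5), np.zeros((10, 10)), n_perm=20, rng=0, genes=genes)
        ev.significant = ev_sig
        p = pathnet_pathway_pvalue(ev, genes[:4])
        assert p == pytest.approx(1.0 / sps.comb(10, 4) if False else sps.hypergeom.sf(3, 10, 4, 4))
        assert pathnet_pathway_pvalue(ev, genes) == pytest.approx(1.0)  # pathway = universe
        ev.significant = np.zeros(10, bool)
        assert pathnet_pathway_pvalue(ev, genes[:4]) == 1.0

    def test_pooled_adjacency_union(self, chain3_directed):
        other = PathwayTopology(
            name="p2", nodes=["b", "d"], edges=[("b", "d", 1.0, False)]
        )
        genes, A = pooled_adjacency(PathwayCollection([chain3_directed, other]))
        idx = {g: i for i, g in enumerate(genes)}
        assert A[idx["a"], idx["b"]] == 1.0 and A[idx["b"], idx["a"]] == 1.0
        assert A[idx["b"], idx["d"]] == 1.0
        assert A[idx["a"], idx["d"]] == 0.0
        assert np.all(np.diag(A) == 0)


class TestCamera:
    def test_vif_formula_at_zero_correlation(self, signal_dataset, signal_stats):
        res = camera_test(signal_stats, ["g5", "g6", "g7"], signal_dataset)
        assert res.vif == pytest.approx(1.0 + (res.m - 1) * res.rho_bar)

    def test_no_shift_gives_ts_zero(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.standard_normal((6, 20)))
        stats = welch_stats(ds)
        stats.z_score = np.ones(6)  # zbar_G = zbar exactly
        res = camera_test(stats, ["g0", "g1"], ds)
        assert res.status == "not_analyzable"  # degenerate spread
        stats.z_score = np.array([1.0, 1.0, 2.0, 0.0, 2.0, 0.0])
        res = camera_test(stats, ["g0", "g1"], ds)
        assert res.ts == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_single_gene_not_analyzable(self, signal_dataset, signal_stats):
        assert camera_test(signal_stats, ["g0"], signal_dataset).status == "not_analyzable"

    def test_whole_universe_rejected(self, signal_dataset, signal_stats):
        with pytest.raises(ValueError):
            camera_test(signal_stats, signal_dataset.feature_ids, signal_dataset)

    def test_independent_genes_match_plain_two_sample_comparison(self):
        # large n, independent genes: rho_bar ~ 0, VIF ~ 1, and TS should
        # agree with the unadjusted standardized mean difference of member
        # z-scores vs the rest
        rng = np.random.default_rng(11)
        ds = make_dataset(rng.standard_normal((200, 400)))
        stats = welch_stats(ds)
        members = [f"g{i}" for i in range(30)]
        res = camera_test(stats, members, ds)
        assert abs(res.rho_bar) < 0.02
        z = stats.z_score
        m = 30
        p = 200
        delta = (z[:30].mean() - z.mean()) * p / (p - m)
        plain_ts = delta / (np.std(z, ddof=1) * np.sqrt(1.0 / m + 1.0 / (p - m)))
        assert res.ts == pytest.approx(plain_ts, abs=0.1)

    def test_detects_shifted_pathway(self, signal_dataset, signal_stats):
        res = camera_test(signal_stats, ["g0", "g1"], signal_dataset)
        assert res.status == "ok" and res.p < 0.05
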