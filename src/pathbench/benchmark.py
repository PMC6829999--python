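"""Benchmark orchestration: run all methods over simulation replicates,
estimate type-I error and power, and aggregate power rankings.

One run fixes the study conditions (a :class:`~pathbench.simulate.SimulationConfig`),
synthesizes the base matrix and ground truth once, and then, per replicate
and mean-signal level, generates data, computes gene-level statistics and
applies every registered method to every pathway.  Each (pathway, method,
mu) cell accumulates rejections at the nominal alpha, non-rejections and
not-analyzable outcomes; rejection rates are computed over the analyzable
replicates.  Rankings follow the empirical-power protocol: per pathway and
mu, methods are ranked from highest power (rank 1) to lowest, cells that
are predominantly not-analyzable get the worst rank, ties share average
ranks, and the per-pathway aggregate is the geometric mean of the ranks
across mu levels.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from . import __version__
from .data import NotAnalyzable, PathwayCollection
from .gene_stats import welch_stats
from .perturbation import pathway_express, spia
from .scores import (
    camera_test,
    cepa_pvalue,
    pathnet_combined_evidence,
    pathnet_pathway_pvalue,
    pooled_adjacency,
    prs_pvalue,
)
from .selfcontained import (
    DEGraphModel,
    NetGSAModel,
    TopologyGSAModel,
    partial_correlation_adjacency,
)
from .simulate import (
    SimulationConfig,
    assign_dysregulation,
    base_covariance,
    generate_replicate,
    standardize,
    synthesize_base_data,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ALL_METHODS",
    "BenchmarkEngine",
    "run_benchmark",
    "rejection_rates",
    "rank_powers",
    "write_results",
]

ALL_METHODS = (
    "PE.Cut",
    "PE.noCut",
    "SPIA",
    "NetGSA",
    "topologyGSA",
    "DEGraph",
    "CAMERA",
    "CePa",
    "PRS",
    "PathNet",
)

# fraction of not-analyzable replicates above which a cell counts as "NA"
# for the ranking protocol (ORA-type methods under weak signal)
NA_RANK_FRACTION = 0.5


@dataclass
class _Cell:
    n_rejected: int = 0
    n_accepted: int = 0
    n_na: int = 0


class BenchmarkEngine:
    """Caches per-run artifacts (base data, truth, per-pathway models) and
    evaluates all requested methods replicate by replicate."""

    def __init__(
        self,
        pathways: PathwayCollection,
        config: SimulationConfig,
        methods=ALL_METHODS,
        alpha: float = 0.05,
        n_perm: int = 200,
        min_edges: int = 0,
        netgsa_adjacency: np.ndarray | None = None,
    ):
        self.config = config
        self.alpha = alpha
        self.n_perm = n_perm
        self.methods = list(methods)
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if min_edges:
            kept = [p for p in pathways if len(p.edges) >= min_edges]
            dropped = len(pathways) - len(kept)
            if dropped:
                logger.info("excluding %d pathways with < %d edges", dropped, min_edges)
            pathways = PathwayCollection(kept)
        self.pathways = pathways
        base = synthesize_base_data(
            config.n_features,
            config.n1,
            config.n2,
            pathways,
            rho_within=config.rho_within,
            marginal=config.marginal,
            seed=np.random.default_rng([config.seed, 11]),
        )
        self.base = standardize(base)
        self.truth = assign_dysregulation(pathways, config)
        # per-pathway engines
        self._degraph = {p.name: DEGraphModel(p) for p in pathways}
        self._tgsa: dict[str, TopologyGSAModel | str] = {}
        for p in pathways:
            try:
                self._tgsa[p.name] = TopologyGSAModel(p)
            except NotAnalyzable as exc:
                self._tgsa[p.name] = exc.reason
        if "NetGSA" in self.methods:
            if netgsa_adjacency is None:
                sigma = base_covariance(
                    self.base.feature_ids, pathways, config.rho_within
                ) + config.noise_sd**2 * np.eye(config.n_features)
                netgsa_adjacency = partial_correlation_adjacency(sigma)
            self._netgsa = NetGSAModel(netgsa_adjacency, self.base.feature_ids)
        else:
            self._netgsa = None
        if "PathNet" in self.methods:
            self._pooled_genes, self._pooled_adj = pooled_adjacency(pathways)
        self._measured_genes = {
            p.name: sorted(p.genes & set(self.base.feature_ids)) for p in pathways
        }

    # -- per-replicate evaluation -------------------------------------------

    def _rng(self, replicate: int, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.config.seed, 104729, replicate, tag])

    def run_replicate(self, mu: float, replicate: int) -> list[tuple[str, str, float | None, str]]:
        """Evaluate every method on every pathway for one replicate.

        Returns tuples ``(pathway, method, p_value_or_None, reason)``.
        """
        sim = generate_replicate(self.base, self.truth, mu, self.config, replicate)
        data = sim.replicate
        stats = welch_stats(data)
        out: list[tuple[str, str, float | None, str]] = []

        netgsa_fit = None
        if self._netgsa is not None and "NetGSA" in self.methods:
            netgsa_fit = self._netgsa.fit(data)
        pathnet_evidence = None
        if "PathNet" in self.methods:
            p_direct = np.ones(len(self._pooled_genes))
            for i, g in enumerate(self._pooled_genes):
                k = stats._index.get(g)
                if k is not None:
                    p_direct[i] = stats.p_value[k]
            pathnet_evidence = pathnet_combined_evidence(
                p_direct,
                self._pooled_adj,
                n_perm=self.n_perm,
                rng=self._rng(replicate, 5),
                genes=self._pooled_genes,
            )

        for pw in self.pathways:
            for mi, method in enumerate(self.methods):
                try:
                    p, reason = self._run_one(
                        method, pw, data, stats, netgsa_fit, pathnet_evidence, replicate, mi
                    )
                except NotAnalyzable as exc:
                    p, reason = None, exc.reason
                except Exception as exc:  # noqa: BLE001 -- record and continue
                    logger.exception("%s failed on %s", method, pw.name)
                    p, reason = None, f"unexpected error: {exc}"
                out.append((pw.name, method, p, reason))
        return out

    def _run_one(self, method, pw, data, stats, netgsa_fit, pathnet_evidence, replicate, mi):
        rng = self._rng(replicate, 100 + mi)
        if method in ("PE.Cut", "PE.noCut"):
            if not pw.is_directed:
                return None, "topology not directed"
            res = pathway_express(
                stats, pw, use_cutoff=(method == "PE.Cut"), n_perm=self.n_perm, rng=rng
            )
            return (res.p_global, "") if res.status == "ok" else (None, res.reason)
        if method == "SPIA":
            if not pw.is_directed:
                return None, "topology not directed"
            res = spia(stats, pw, n_boot=self.n_perm, rng=rng)
            return (res.p_global, "") if res.status == "ok" else (None, res.reason)
        if method == "NetGSA":
            ts, df, p = self._netgsa.test(netgsa_fit, self._measured_genes[pw.name])
            return p, ""
        if method == "topologyGSA":
            model = self._tgsa[pw.name]
            if isinstance(model, str):
                return None, model
            res = model.test(data, alpha=self.alpha)
            return (res.p, "") if res.status == "ok" else (None, res.reason)
        if method == "DEGraph":
            res = self._degraph[pw.name].test(data, n_perm=self.n_perm, rng=rng)
            return (res.p, "") if res.status == "ok" else (None, res.reason)
        if method == "CAMERA":
            res = camera_test(stats, self._measured_genes[pw.name], data, pathway=pw.name)
            return (res.p, "") if res.status == "ok" else (None, res.reason)
        if method == "CePa":
            res = cepa_pvalue(stats, pw, n_perm=self.n_perm, rng=rng)
            return (res.p_min, "") if res.status == "ok" else (None, res.reason)
        if method == "PathNet":
            p = pathnet_pathway_pvalue(pathnet_evidence, self._measured_genes[pw.name])
            return p, ""
        if method == "PRS":
            if not pw.is_directed:
                return None, "topology not directed"
            res = prs_pvalue(stats, pw, n_perm=self.n_perm, rng=rng)
            return (res.p, "") if res.status == "ok" else (None, res.reason)
        raise ValueError(f"unknown method {method!r}")

    # -- full run -----------------------------------------------------------

    def run(self, n_replicates: int = 200, mu_levels=None) -> pd.DataFrame:
        """Accumulate rejection counts over replicates.

        ``mu_levels`` defaults to the config grid for signal runs and to
        ``(0.0,)`` for pure null runs (``q = 0``).
        """
        if mu_levels is None:
            mu_levels = (0.0,) if self.config.q == 0 else tuple(self.config.mu_grid)
        cells: dict[tuple, _Cell] = {}
        for li, mu in enumerate(mu_levels):
            for r in range(n_replicates):
                rep_index = li * n_replicates + r
                for pathway, method, p, _reason in self.run_replicate(mu, rep_index):
                    cell = cells.setdefault((pathway, method, mu), _Cell())
                    if p is None:
                        cell.n_na += 1
                    elif p <= self.alpha:
                        cell.n_rejected += 1
                    else:
                        cell.n_accepted += 1
        rows = []
        for (pathway, method, mu), cell in sorted(cells.items()):
            n_eff = cell.n_rejected + cell.n_accepted
            rows.append(
                {
                    "pathway": pathway,
                    "method": method,
                    "mu": mu,
                    "n_replicates": n_eff + cell.n_na,
                    "n_rejected": cell.n_rejected,
                    "rate": cell.n_rejected / n_eff if n_eff else np.nan,
                    "n_na": cell.n_na,
                }
            )
        return pd.DataFrame(rows)


def run_benchmark(
    pathways: PathwayCollection,
    config: SimulationConfig,
    methods=ALL_METHODS,
    n_replicates: int = 200,
    alpha: float = 0.05,
    n_perm: int = 200,
    min_edges: int = 0,
) -> tuple[pd.DataFrame, "BenchmarkEngine"]:
    """Run the full benchmark; returns the rejection table and the engine
    (which holds the base data and ground truth)."""
    engine = BenchmarkEngine(
        pathways, config, methods=methods, alpha=alpha, n_perm=n_perm, min_edges=min_edges
    )
    table = engine.run(n_replicates=n_replicates)
    return table, engine


def rejection_rates(table: pd.DataFrame, engine: BenchmarkEngine) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the rejection table into type-I (null pathways) and power
    (pathways with at least one affected member) components."""
    alt = {
        p.name for p in engine.pathways if engine.truth.pathway_is_alternative(p)
    }
    is_alt = table["pathway"].isin(alt)
    type1 = table[~is_alt].copy()
    power = table[is_alt].copy()
    return type1, power


def rank_powers(power: pd.DataFrame, na_fraction: float = NA_RANK_FRACTION) -> pd.DataFrame:
    """Per-pathway power ranking with geometric-mean aggregation.

    Rank 1 is the highest power at a given mu; cells whose not-analyzable
    fraction exceeds ``na_fraction`` (or with no analyzable replicate) are
    ranked worst; ties share average ranks.
    """
    methods = sorted(power["method"].unique())
    if len(methods) < 2:
        raise ValueError("ranking needs at least two methods")
    rows = []
    for pathway, sub in power.groupby("pathway"):
        ranks_by_mu = {}
        for mu, cell in sub.groupby("mu"):
            cell = cell.set_index("method").reindex(methods)
            rate = cell["rate"].to_numpy(dtype=float)
            na_frac = (cell["n_na"] / cell["n_replicates"]).to_numpy(dtype=float)
            score = np.where(
                np.isnan(rate) | (na_frac > na_fraction), -np.inf, rate
            )
            ranks_by_mu[mu] = rankdata(-score, method="average")
        mat = np.column_stack(list(ranks_by_mu.values()))
        geo = np.exp(np.mean(np.log(mat), axis=1))
        for i, m in enumerate(methods):
            row = {"pathway": pathway, "method": m, "geomean_rank": geo[i]}
            for j, mu in enumerate(ranks_by_mu):
                row[f"rank_mu_{mu:g}"] = mat[i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def write_results(
    out_dir,
    table: pd.DataFrame,
    engine: BenchmarkEngine,
    ranking: pd.DataFrame | None = None,
) -> dict:
    """Write benchmark/ranking/truth tables and a reproducibility manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    table.to_csv(out / "benchmark.tsv", sep="\t", index=False)
    paths["benchmark"] = out / "benchmark.tsv"
    truth_rows = []
    for p in engine.pathways:
        affected = sorted(
            engine.truth.per_pathway_affected.get(p.name, frozenset())
        )
        truth_rows.append(
            {
                "pathway": p.name,
                "dysregulated": p.name in engine.truth.dysregulated_pathways,
                "affected_features": ",".join(affected),
            }
        )
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    if ranking is not None:
        ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)
        paths["ranking"] = out / "ranking.tsv"
    digests = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in paths.items()
    }
    manifest = {
        "pathbench_version": __version__,
        "numpy_version": np.__version__,
        "config": {
            **{k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(engine.config).items()}
        },
        "alpha": engine.alpha,
        "n_perm": engine.n_perm,
        "methods": engine.methods,
        "sha256": digests,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    paths["manifest"] = out / "manifest.yaml"
    return paths
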