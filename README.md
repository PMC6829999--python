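# pathbench

Topology-based pathway enrichment methods on a single shared data model,
plus an in-silico benchmarking engine for measuring their type I error and
statistical power.

Pathway enrichment asks whether a predefined set of genes or metabolites
changes in a coordinated way between two conditions. The latest generation
of methods also uses the *topology* of the pathway — who regulates whom,
activation vs. inhibition — rather than membership alone. This package
re-implements nine widely used topology-aware methods so that they all
consume the same expression matrix and the same pathway graphs, and wraps
them in a simulation harness where the ground truth (which pathways carry
signal, and how strong it is) is known exactly. That makes it possible to
measure false-positive rates and power per method, per pathway and per
signal level, which is impossible on real data where truth is unknown.

## The methods

| method | null hypothesis | input | key statistic |
| --- | --- | --- | --- |
| Pathway-Express (PE.Cut / PE.noCut) | competitive | DE genes (optional cutoff-free) | impact factor `IF(G) = log(1/P_NDE) + Σ|PF|/(N_de·mean|ΔE|)` |
| SPIA | competitive | DE genes | net accumulation `t_A = Σ(PF − ΔE)`, `P_G = c − c·ln c` |
| NetGSA | self-contained | expression + weighted network | Wald test in `Y = Λμ_k + Λγ + ε`, `ΛΛ' = (I−A)⁻¹` |
| topologyGSA | self-contained | expression + DAG | LRT for `Σ₁=Σ₂` on the moral graph, then MANOVA / Behrens–Fisher |
| DEGraph | self-contained | expression + graph | Hotelling `T²` on low-frequency graph-Fourier components |
| CAMERA | competitive | expression + membership | `TS = δ / (s_pool·√(VIF/m + 1/(p−m)))`, `VIF = 1+(m−1)ρ̄` |
| CePa | competitive | DE genes + topology | `s = Σ wᵢdᵢ` with centrality weights, gene-permutation null |
| PRS | competitive | DE genes + topology | `PRS = Σ wᵢvᵢ` over differential nodes, downstream-DE weights |
| PathNet | competitive | gene p-values + pooled network | `SIᵢ = Σⱼ Aᵢⱼ(−log₁₀ pⱼ)`, Fisher combination, hypergeometric |

Perturbation factors solve the linear system
`PF(gᵢ) = ΔE(gᵢ) + Σ_{j→i} β_ij PF(gⱼ)/N_ds(gⱼ)`, i.e. `(I−B)·PF = ΔE`
with `B_ij = β_ij/N_ds(gⱼ)`; pathways with singular `I−B` are reported as
not analyzable, as are cutoff-dependent methods when no gene passes the
FDR 0.05 Welch/Benjamini–Hochberg filter.

## The benchmark

The simulation engine standardizes a pathway-structured base matrix
(every feature mean 0, variance 1, within-pathway correlation blocks,
optionally non-normal marginals), selects `q` pathways as dysregulated,
picks a detection-call fraction of their members by a **betweenness**,
**community**, **neighborhood** or **random** design, and then draws
replicates by adding a mean signal `μ` to the affected features of the
second group plus i.i.d. Gaussian noise. Two label regimes are supported:
model I keeps the original labels; model II permutes them first, which
equalizes the group covariances. Rejections at `α = 0.05` are tallied into
per-pathway type-I-error and power tables, and powers are aggregated into
geometric-mean ranks across signal levels (rank 1 = most powerful; methods
that cannot analyze a cell rank worst).

## Worked example

`examples/04_power_ranking.py` runs a metabolomics-flavoured benchmark
(10 small, sparse, overlapping pathways, 41 + 30 samples, detection call
0.2, signals 0.25–1.0, 40 replicates) with the five methods applicable to
non-DAG metabolic networks:

```
average power on dysregulated pathways:
mu        0.25   0.50   1.00
method
CAMERA   0.088  0.103  0.125
CePa     0.050  0.132  0.225
DEGraph  0.088  0.247  0.628
NetGSA   0.091  0.159  0.412
PathNet  0.003  0.003  0.081

geometric-mean power rank (lower = better):
DEGraph    1.49
NetGSA     1.79
CAMERA     2.91
PathNet    4.11
CePa       4.38
```

DEGraph and NetGSA — the two tests that combine expression with network
structure — take the two best ranks: their power climbs steeply with the
signal (0.63 and 0.41 at μ = 1), while the count-based methods (CePa,
PathNet) see few DE calls at these sample sizes and stay far behind. The other examples show the
nine methods on a single signaling study (`01`), the data-generating
engine itself (`02`) and a small all-null type-I-error run (`03`).

A thin CLI mirrors the library:

```bash
pathbench run --config cfg.yaml --out results/ --replicates 200 --seed 1
pathbench rank --in results/
pathbench simulate --config cfg.yaml --out replicate.tsv
```

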