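# Methods

This note records the statistical models implemented in `pathbench`, the
choices made where a method's published description leaves details open,
what the synthetic-data engine does and does not emulate, and the
numerical conventions that make runs reproducible.

## Data model

All methods consume an `ExpressionDataset` (log-scale feature × sample
matrix, two non-empty groups; group 1 is the case/perturbed condition) and
a `PathwayTopology` (ordered nodes, a gene→node map, and signed weighted
edges, directed or not; +1 encodes activation, −1 inhibition). Gene-level
inputs are Welch two-sample t statistics with Satterthwaite degrees of
freedom, Benjamini–Hochberg q-values, and DE flags at FDR ≤ 0.05. The
normal-scale statistic used by CAMERA is the quantile transform
`z = Φ⁻¹(F_t(t; df))`; the published description does not fix this
transform, so it is our choice (raw t can be substituted — the transform
is monotone, so CAMERA's ranks are unaffected, only the normal reference
calibration).

## Per-method conventions

Where a method's description is complete we follow it exactly; the items
below are the genuinely open details and how we resolved them.

**Pathway-Express / SPIA.** Perturbation factors solve `(I−B)PF = ΔE`
with `B_ij = β_ij / N_ds(g_j)`; singularity is declared when the condition
number of `I−B` exceeds 1e12, and the solve must reach a residual of
1e−8·‖ΔE‖. Genes present in the topology but absent from the dataset get
ΔE = 0 rather than being dropped, keeping the system's dimension equal to
the topology. The ORA universe is the set of features measured in the
dataset (not the union of pathway genes) — consistent with CAMERA's
"everything measured" universe. The mean |ΔE| normalizer uses all DE genes
in the dataset. The cutoff-free variant scores `Σ|PF|` computed from the
full (uncut) ΔE vector and calibrates it by reassigning node values drawn
from the all-gene ΔE pool (add-one estimator over 2000 draws by default).
SPIA's bootstrap places the dataset's DE ΔE values on `N_de(G)` randomly
chosen pathway nodes and median-centers the permuted `t_A` before the
two-sided comparison; centering is configurable (`center=False` compares
raw `|t_A|`). When either evidence p-value is exactly zero it is clamped
to the smallest positive float with a logged warning.

**CePa.** Weight measures: equal, in-degree, out-degree, betweenness,
largest reach, each offset by 0.01; undirected graphs collapse in/out to
plain degree. The null permutes gene-level DE labels over the measured
universe and re-maps them to nodes; the reported pathway p-value is the
minimum over measures, which is deliberately anti-conservative (it is the
aggregation the original comparison used, not a calibrated combination).
An exhaustive mode enumerates every placement of the DE labels for tiny
universes; the sampled mode uses the add-one estimator.

**PRS.** Node values: 0 unmeasured, 1 measured non-differential, max |ΔE|
of the mapped genes if differential. The published score only activates
nodes with value > 1, which silently zeroes the method on standardized
data where |ΔE| of true DE genes can be below 1; the default therefore
lifts differential nodes to at least 1 + 1e−6 (`prs_gate="literal"`
restores the published rule). The weight of an active node counts the
differential nodes reachable from it through differential intermediates,
itself included — one concrete reading of "downstream DE nodes, directly
or via other significant nodes"; the exhaustive-enumeration oracle in the
test suite encodes the same reading independently. The permutation null
moves (DE flag, |ΔE|) pairs jointly across the universe and standardizes
raw and permuted normalized scores by the permutation mean and sd.

**PathNet.** All pathways are pooled into one binary undirected network
over mapped features. Direct evidence is the Welch p-value (1.0 for
pooled genes missing from the dataset); indirect evidence compares
`SI_i = Σ_j A_ij(−log₁₀ p_j)` against permutations of the direct p-values
across pooled genes; Fisher's method with 4 degrees of freedom combines
the two. The gene-significance rule for the final hypergeometric test is
BH-adjusted combined p ≤ 0.05 (the published description names no rule).

**CAMERA.** The inter-gene correlation `ρ̄` is the average pairwise
Pearson correlation of the member genes' within-group-centered expression
residuals ("estimated from the data" is all the description fixes);
`VIF = 1 + (m−1)ρ̄`, floored at the theoretical minimum `−1/(m−1)`. The
reference distribution is standard normal on the z scale.

**NetGSA.** The influence matrix is the Cholesky factor of `(I−A)⁻¹`
(reconstruction checked to 1e−8); `I−A` must be symmetric positive
definite, otherwise the caller is told to rescale the weights. Because
the per-condition mean `Λμ_k` is saturated, its GLS estimate is the group
mean and REML reduces to the likelihood of within-group deviations: a
bounded one-dimensional profile over the variance ratio
`σ_γ²/σ_ε² ∈ [e⁻³⁰, e¹⁵]` (Brent, tolerance 1e−10, boundary σ_γ² = 0
checked explicitly), with everything expressed in the eigenbasis of
`ΛΛᵀ` so repeated fits cost O(p) per likelihood evaluation. The pathway
contrast is fixed to the difference of pathway-averaged propagated means,
`ℓ = (−bᵀΛ₁, +bᵀΛ₂)/|G|`, which evaluates to the pathway-mean difference
of the observed group means; the published account says only that the
contrast is "optimally defined", so this is our choice and the interface
accepts any contrast through the fitted model. The Wald statistic is
referred to a t distribution with Satterthwaite degrees of freedom
obtained from the REML information matrix of (σ_γ², σ_ε²), clamped to
[1, n−2]. With two different condition networks the same contrast also
reacts to pure rewiring when baseline means are nonzero, because
`E[ȳ_2 − ȳ_1] = (Λ₂−Λ₁)μ`.

**topologyGSA.** The DAG is moralized (co-parents married, directions
dropped); cyclic topologies are not analyzable, as are pathways whose
node count is not smaller than the smaller group size. Covariance MLEs
constrained to the moral graph are computed by iterative proportional
scaling over maximal cliques (precision exactly zero off-graph by
construction; clique marginals match the sample covariance to 1e−7;
maximum 200 sweeps). Sample covariances use the ML (1/n) scale. The
equality-of-covariances LRT is referred to χ² with df = nodes + moral
edges. The mean test branches at variance-test p < 0.05 (the switch rule
is ours): the equal-variance branch is a Hotelling-type T² with the
pooled constrained covariance rescaled to the unbiased pooled scale and
the classical F reference — exact when the moral graph is complete,
approximate otherwise; the unequal branch is the multivariate
Behrens–Fisher problem with the Krishnamoorthy–Yu Satterthwaite-matched F
approximation applied to the constrained per-group MLEs.

**DEGraph.** Per connected component, member expression is projected on
the k lowest-eigenvalue eigenvectors of the unweighted combinatorial
Laplacian and tested with the classical two-sample Hotelling T² / F. The
default k is ⌈0.2·component size⌉ with a minimum of 2, clamped to the
component size and to n−2 (no rule is published; a count or fraction can
be passed). Multi-component pathways report the minimum component
p-value, recalibrated by permuting sample labels and recomputing the
minimum (add-one, 200 permutations by default) — the published account
names a permutation correction without specifying it; this is one
concrete reading.

## Synthetic data engine

The generator emulates the standardized-real-data design: one fixed base
matrix, per-replicate noise and (optionally) label permutation.

- **Base matrix.** Latent Gaussian with single-factor correlation blocks:
  every gene of a pathway loads on that pathway's factor so that
  within-pathway pairwise correlation is `rho_within` (default 0.3) and
  between-block correlation is zero. A gene shared by several pathways is
  assigned to the first pathway's block in collection order — overlap in
  membership is preserved, overlap in correlation is not. The `skewed`
  marginal passes the latent values through `exp` and restandardizes,
  giving markedly right-skewed but still block-correlated features. The
  base is standardized to per-feature mean 0, variance 1.
- **Dysregulation.** `q` pathways are drawn uniformly; a detection-call
  fraction `dc` of members (⌈dc·|G|⌉, guaranteeing at least one feature
  in small pathways) is selected by the betweenness (top-ranked nodes on
  the undirected view, ties by canonical node order), community
  (edge-betweenness partition at maximal modularity, community size
  closest to the target), neighborhood (shortest-path ball around a
  random center, boundary trimmed at random) or random design. Defaults:
  dc = 0.10 for genomic-like runs, 0.20 for metabolomic-like ones.
- **Replicates.** Each replicate adds `μ` to the affected features of
  group 1 (after a fresh label permutation under model II) and i.i.d.
  N(0, 0.1²) noise to every entry. The noise sd is a package default on
  the standardized scale (no published value); it is configurable and
  swept in tests. Mean-signal grids default to 0.1–0.5 (genomic-like) and
  extend to 1.0 in metabolomic-like runs.
- **Determinism.** Every stochastic step draws from a substream derived
  from (config seed, fixed tag, replicate index); identical configuration
  and seed reproduce the run bit for bit, including under any
  parallelization over replicates.
- **Synthetic topologies.** Signaling-like pathways are random connected
  DAGs (spanning arborescence plus one forward shortcut per node, ≈ two
  edges per node — comparable to curated signaling maps), signed edges
  with 70% activations. Metabolic-like pathways are small (5–10 nodes),
  sparse (thinned spanning trees, possibly disconnected), undirected, and
  drawn from a shared 100-metabolite universe so they overlap. These
  generators stand in for curated pathway databases; readers for GMT +
  edge-list files accept real topologies.

What the generator does **not** emulate: heavy-tailed technical noise,
missingness/dropout, correlation that decays with graph distance rather
than being uniform within a pathway, and pathway-size distributions of
real databases. Passing benchmarks here therefore demonstrate correctness
and calibration of the implementations under controlled conditions, not
performance on any particular real data set.

## Benchmark protocol

Per replicate, every method is applied to every eligible pathway;
outcomes are *reject* (p ≤ α = 0.05), *non-reject*, or *not analyzable*
(with a recorded reason; unexpected exceptions are recorded the same way
and the run continues). Rates are computed over analyzable replicates,
with NA counts reported separately. Pathways with at least one affected
member count as alternative (membership overlap can make more than `q`
pathways alternative); the rest contribute to type I error. Rankings:
per pathway and signal level, methods are ranked by power (rank 1 best),
ties share average ranks, and cells that are predominantly not analyzable
(> 50% NA) are ranked worst; the per-pathway aggregate is the geometric
mean across signal levels. No cross-pathway multiplicity correction is
applied — raw per-pathway p-values are compared with α, matching the
per-pathway error reporting the benchmark mimics. For NetGSA the
benchmark supplies partial-correlation network weights implied by the
generator's covariance (the standard practice of estimating weights from
data under connectivity constraints, collapsed to its population limit).
Metabolomic-like runs exclude pathways with fewer than two edges.

**Calibration caveat.** Under the label-permuted null with
`rho_within = 0.3`, the self-contained tests and CAMERA are calibrated or
conservative, and PathNet is strongly conservative, but gene-permutation
competitive tests (notably the cutoff-free Pathway-Express) run above the
nominal level: their null resamples genes independently, which destroys
the within-pathway correlation of the observed statistic — exactly the
effect CAMERA's variance-inflation factor corrects. With
`rho_within = 0`, where the gene-sampling null is true, the same test is
nominal. The type-I comparison therefore reports cutoff-free
gene-permutation results as-is and excludes only the cutoff-dependent
methods that are predominantly not analyzable under the null (their
conditional rates would be based on a handful of replicates with
false-positive DE calls).

## Numerical conventions and problem sizes

Permutation/bootstrap nulls use the add-one estimator (p ≥ 1/(N+1)) with
2000 draws by default in the library and 200 in the benchmark loops.
Degenerate situations are defined rather than left to chance: zero
permutation spread gives p = 1 with a warning; zero p-values entering a
log are clamped to the machine floor; Welch features with zero variance
in both groups and equal means give t = 0, p = 1. The benchmark suites in
the tests and the acceptance script run at desk scale — 200 replicates
for null calibration, 100 for power curves, permutation depth 200, 120 to
300 features — sizes chosen so a full run completes in minutes on one CPU
while keeping Monte-Carlo error around two percentage points on a rate.

## Known limitations

- The per-measure minimum in CePa and the min-p component rule in
  DEGraph are anti-conservative by construction; both follow the
  benchmarked protocol rather than a calibrated combination.
- topologyGSA's mean test with an incomplete moral graph uses a
  misspecification-robust-ish plug-in (constrained MLE in a classical T²
  form) that is approximate; empirically it is conservative in the null
  benchmark.
- NetGSA assumes the network is given; estimating it from data under
  structural constraints is out of scope here.
- The PRS weight definition and the DEGraph multi-component correction
  implement one concrete reading of ambiguous published descriptions;
  both are flagged above and pinned by oracle tests.
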