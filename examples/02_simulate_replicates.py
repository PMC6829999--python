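"""Tour of the data-generating engine.

Synthesizes a pathway-structured base matrix, standardizes it, marks
pathways as dysregulated under the betweenness design and draws replicates
under both label regimes, printing the group-mean difference of affected
and unaffected features.
"""

import numpy as np

from pathbench.simulate import (
    SimulationConfig,
    assign_dysregulation,
    generate_replicate,
    standardize,
    synthesize_base_data,
    synthetic_signaling_pathways,
)

pathways = synthetic_signaling_pathways(n_pathways=5, size=12, seed=3)
config = SimulationConfig(
    q=2, dc=0.25, design="betweenness", seed=42,
    n_features=80, n1=50, n2=50, rho_within=0.3, noise_sd=0.1,
)

base = standardize(
    synthesize_base_data(80, 50, 50, pathways, rho_within=0.3, seed=config.seed)
)
print(f"base matrix: {base.n_features} features x {base.n_samples} samples "
      f"(every feature standardized to mean 0, sd 1)")

truth = assign_dysregulation(pathways, config)
for name in truth.dysregulated_pathways:
    print(f"dysregulated {name}: affected = {sorted(truth.per_pathway_affected[name])}")

for permute in (False, True):
    config.permute_labels = permute
    label = "model II (permuted labels)" if permute else "model I (original labels)"
    diffs_aff, diffs_un = [], []
    unaffected = sorted(set(base.feature_ids) - set(truth.affected_features))[:10]
    for r in range(50):
        sim = generate_replicate(base, truth, mu=0.5, config=config, replicate=r)
        ds = sim.replicate
        ia = ds.feature_index(sorted(truth.affected_features))
        iu = ds.feature_index(unaffected)
        diffs_aff.append(ds.values[np.ix_(ia, ds.groups == 1)].mean()
                         - ds.values[np.ix_(ia, ds.groups == 0)].mean())
        diffs_un.append(ds.values[np.ix_(iu, ds.groups == 1)].mean()
                        - ds.values[np.ix_(iu, ds.groups == 0)].mean())
    print(f"{label}: mean group difference over 50 replicates "
          f"affected = {np.mean(diffs_aff):+.3f} (target 0.5), "
          f"unaffected = {np.mean(diffs_un):+.3f} (target 0)")

print(
    "\nAffected features carry the injected mean signal; unaffected ones"
    "\ncenter at zero. Permuting labels (model II) equalizes the two"
    "\ngroups' covariances without removing the injected signal."
)
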