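"""AMOVA variance partition and Bayesian admixture with Evanno Delta K.

Simulates three differentiated groups, partitions molecular variance, and
sweeps the admixture model over K to recover the planted cluster count.
MCMC settings are reduced for a quick demonstration.
"""

import germdiv as gd

gm, truth = gd.simulate_populations(gd.PopSimConfig(
    group_sizes=(30, 30, 30), n_loci=10, fst=0.2, seed=300))

res = gd.amova(gm, truth["group_labels"], permutations=199, seed=1)
print("AMOVA percentages:",
      {k: round(v, 1) for k, v in res.percentages.items()})
print(f"Phi_ST = {res.phi_st:.3f}  Nm = {res.nm:.3f}  "
      f"permutation p = {res.permutation_p}")

sweep = gd.sweep_k(gm, range(1, 6), replicates=2, seed=400,
                   burn_in=2000, iterations=8000)
print("\nmean ln P(X|K) by K:")
print(sweep.table.round(2).to_string())
print("\nDelta K:")
print(sweep.delta_k.round(2).to_string())
print(f"\nbest K by Delta K: {sweep.best_k_deltak} (planted K = 3)")

print()
print("Phi_ST near the generator's F = 0.2 confirms the variance partition;")
print("Delta K peaks at the planted K because the likelihood gain saturates")
print("once the model matches the true number of groups.")
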