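"""Partition ten traits into colocalized clusters by divisive search.

Simulates the four-cluster design — clusters of sizes (3, 3, 2, 2), each
with its own causal variant — and runs the branch-and-bound clustering at
the default thresholds P_R* = P_A* = 0.5. Each emitted cluster carries its
posterior (PPFC), candidate shared SNP and the proportion of the posterior
that SNP explains (PPE); clusters with PPFC > 0.7 clear the reporting bar.
"""

import numpy as np

from multicoloc import PriorSpec, bb_cluster, builtin_scenario, simulate_region

scenario = builtin_scenario("iii", Q=200, sample_sizes=15000)
region, truth = simulate_region(scenario, rng=np.random.default_rng(11))
clusters, unclustered = bb_cluster(region, PriorSpec())

print("planted clusters :", [sorted(g) for g in truth.partition])
for c in clusters:
    flag = "reported" if c.passes_report_threshold else "below 0.7"
    print(f"found {list(c.trait_indices)}: PPFC={c.breakdown.ppfc:.3f} "
          f"at {c.candidate_snp} (PPE={c.ppe:.2f}) [{flag}]")
print("unclustered      :", unclustered)
# Matching trait sets between 'planted' and 'found' mean the search
# recovered the simulated colocalization structure; the PPE says how
# concentrated the fine-mapping evidence is on the named SNP.
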