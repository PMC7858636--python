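"""Colocalization when the studies share participants.

Two traits measured on fully overlapping participants with phenotype
correlation 0.5 have correlated effect estimates even at null SNPs. The
cross-trait correlation is estimated from null-SNP Z-statistics and can be
fed into the joint Bayes factor.

Two analyses are compared: ignoring the overlap (treating the studies as
independent) and adjusting the likelihood for it. Adjusting only the
likelihood is deliberately conservative — shared noise explains part of the
co-occurring association, so the colocalization posterior drops, sometimes
sharply; countering that requires trait-correlation-aware priors, which
this package does not implement (traits are a priori exchangeable). For
routine use the independent-study analysis is the pragmatic default even
under complete sample overlap; the adjusted run bounds the evidence from
below. Fine-mapping (the candidate SNP) agrees between the two.
"""

import numpy as np

from multicoloc import (
    CorrelationModel,
    PriorSpec,
    SimScenario,
    estimate_rho_hat,
    ppfc,
    simulate_region,
)

scenario = SimScenario(
    m=2, Q=300, clusters=((0, 1),), sample_sizes=10000,
    overlap_fraction=1.0, pheno_corr=0.5, ld_rho=0.9,
)
region, truth = simulate_region(scenario, rng=np.random.default_rng(5))

rho_hat = estimate_rho_hat(region.z)
print(f"estimated effect-estimate correlation: {rho_hat[0, 1]:.3f} "
      f"(theory: overlap x pheno_corr = 0.5)")

naive = ppfc(region, PriorSpec())
adjusted = ppfc(region, PriorSpec(), CorrelationModel(rho_hat))
print(f"PPFC treating studies as independent : {naive.ppfc:.4f}")
print(f"PPFC with likelihood-only adjustment : {adjusted.ppfc:.4f} "
      f"(P_R={adjusted.p_r:.3f}, P_A={adjusted.p_a:.2e})")
print(f"candidate SNP, independent analysis  : "
      f"{region.snp_ids[naive.top_snp_index]} "
      f"(planted {region.snp_ids[truth.causal[0][0]]})")
print(f"candidate SNP, adjusted analysis     : "
      f"{region.snp_ids[adjusted.top_snp_index]}")
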