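# multicoloc

Deterministic Bayesian **multi-trait colocalization** from GWAS summary
statistics.

When several traits — diseases, risk factors, molecular phenotypes — show
association signals in the same genomic region, the scientific question is
whether they share a single causal variant or merely carry distinct
variants in linkage disequilibrium. Pairwise colocalization methods answer
this two traits at a time; enumerating causal configurations jointly is
exponential in the number of traits. `multicoloc` approximates the joint
answer with linear cost in the number of traits, so dozens or hundreds of
traits can be analysed together, and partitions traits into clusters that
each share their own causal variant. It is aimed at statistical geneticists
working with regional summary statistics (effect estimate + standard error
per SNP per trait; log-odds scale for binary traits). No individual-level
data and no LD matrix are required.

## The statistic

Per trait and SNP the evidence unit is Wakefield's approximate Bayes factor
for effect prior N(0, w²) (w = 0.15 continuous, 0.2 binary),

    ln ABF = ½ ln(v²/(v²+w²)) + (z²/2) · w²/(v²+w²),   z = β̂/v.

The posterior probability of full colocalization (PPFC) — all m traits
share one causal variant among Q SNPs — is approximated by

    PPFC ≈ P_R · P_A,

where **P_R** (regional association probability) weighs the
full-colocalization class against the null and the drop-one-trait-null
classes (O(mQ) configurations), and **P_A** (alignment probability) weighs
it against the classes where m−1 traits share a SNP and one trait is
causal elsewhere (O(mQ²)). The approximation error is second order in
(1−P_R, 1−P_A), i.e. negligible exactly when colocalization would be
declared. Priors use two parameters: p (a variant is causal for one trait,
default 1e-4) and p_c (causal for an additional trait given one, default
0.02); the prior that a variant is causal for k traits is
p·∏_{i=2..k}(1−(1−p_c)^{i−1}).

When not all traits colocalize, a branch-and-bound divisive search removes,
at each step, the trait whose exclusion carries maximum posterior evidence,
emitting clusters that satisfy P_R ≥ P_R* and P_A ≥ P_A* (defaults 0.5);
clusters with PPFC > 0.7 clear the reporting bar. Per-SNP shares of the
colocalization posterior fine-map the shared variant (the top share is the
PPE — the proportion of the posterior that SNP explains). An exhaustive
(Q+1)^m enumerator doubles as the validation oracle, and a seeded
LD-aware simulator generates test regions with known causal structure.

## Worked example

`examples/01_two_trait_colocalization.py` simulates a 50-SNP region in
which two traits share one causal variant explaining 1% of trait variance
(n = 10,000 each) and runs the posterior:

```
planted causal SNP : snp_35
P_R (regional)     : 1.0000
P_A (alignment)    : 0.9946
PPFC = P_R * P_A   : 0.9946
candidate SNP      : snp_35
PPE (share of PPFC): 0.9997
top per-SNP shares : snp_35=1.000, snp_36=0.000, snp_34=0.000
```

Both criteria are met — the traits share an associated region (P_R ≈ 1)
and the shared association aligns at a single variant (P_A ≈ 0.99) — so
the traits colocalize with posterior 0.99, and essentially all of that
posterior points at the planted SNP. The other examples cover clustering
ten traits into planted groups (`02`), prior/threshold sensitivity heatmaps
(`03`), replicate batteries with pairwise accuracy metrics (`04`) and
overlapping-sample analyses (`05`).

The same machinery is scriptable from the shell:

```bash
multicoloc simulate --scenario iii --out-prefix region      # region + truth
multicoloc run --region region.tsv --out results.json       # cluster + fine-map
multicoloc sensitivity --region region.tsv --out heat.png   # prior stability
multicoloc validate --m 3 --q 40 --replicates 100 --seed 1  # oracle agreement
```

`run` writes one record per cluster — member traits, PPFC, P_R, P_A,
candidate SNP, PPE — plus a per-SNP TSV and a manifest sufficient to
reproduce the run byte for byte.

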