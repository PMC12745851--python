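# invadibe

Population-genomic inference of **isolation by distance (IBD)** and
**isolation by environment (IBE)** for invasive populations, from a SNP
genotype matrix. The package was built around the analysis of a
dual-introduction invasion — two divergent founder lineages of a social wasp
spreading through a ~150 km landscape — but every stage is generic: it
consumes a VCF (or Genepop file) plus a per-sample metadata table and asks
*what maintains genetic structure: ancestry, geography, or environment?*

## What it computes

1. **Locus filtering** in the style of the Stacks `populations` module
   (`--min-samples-per-pop`, `--min-samples-overall`, `--min-maf`,
   `--min-mac`, `--max-obs-het`).
2. **Diversity and differentiation**: nucleotide diversity π, expected and
   observed heterozygosity, private alleles, % polymorphic loci, and the
   Weir–Cockerham (1984) method-of-moments F-statistics. For two groups,

       θ̂ = Σ_l a_l / Σ_l (a_l + b_l + c_l),     F_IS = 1 − Σ_l c_l / Σ_l (b_l + c_l),

   with per-locus variance components a (among populations), b (among
   individuals) and c (within individuals), combined ratio-of-sums across
   loci; 95% CIs by locus bootstrap and significance by label permutation.
   A per-individual-pair F_ST matrix treats each diploid as a population of
   two allele copies (two-level W&C reduction).
3. **Pair table**: one row per unordered sample pair with the F_ST response,
   great-circle distance, |Δ distance| to two putative introduction points,
   |Δ| environmental covariates, and the cluster pair type.
4. **Shape-constrained additive model (SCAM)**: quasi-binomial logit
   regression of pairwise F_ST on monotone-increasing smooths (geographic
   distance, temperature gradients), nonnegative smooths (rainfall,
   moisture), a linear term and a cluster factor. Monotonicity is enforced
   by construction through a cumulative-sum-of-exponentials map over
   B-spline coefficients; smoothing is chosen by GCV.
5. **Hierarchical deviance partitioning** of F_ST variation into genetic /
   spatial / environmental components (unique and shared percentages) with
   permutation p-values.
6. **Stand-alone tests**: Mantel (with exact enumeration for tiny n),
   mito-nuclear χ² concordance, Kruskal–Wallis + Dunn (Bonferroni),
   cluster-climate permutation tests, and Evanno ΔK from a STRUCTURE-style
   log-likelihood table.
7. **Synthetic data**: a generator for dual-introduction datasets
   (Balding–Nichols founder lineages, logit-scale Gaussian-process IBD,
   lineage-linked environments, mito-nuclear discordance, missingness), so
   the whole pipeline is testable without any download.

## Worked example

```python
import numpy as np
from invadibe import (SimParams, simulate_dataset, pairwise_individual_fst,
                      build_pair_table, wc_fst, partition_deviance,
                      default_model_terms, drop_null_smooths)

sim = simulate_dataset(SimParams(seed=1))       # 47 samples, 2000 SNPs
G, lineage = sim.genotypes, sim.truth["lineage"]
ids = np.array(G.sample_ids)

fst = wc_fst(G, ids[lineage == 0], ids[lineage == 1], n_boot=199,
             n_perm=199, seed=1)
print(f"theta = {fst.theta:.3f}, CI [{fst.ci95[0]:.3f}, {fst.ci95[1]:.3f}],"
      f" p = {fst.perm_p:.3f}")

table = build_pair_table(sim.metadata, pairwise_individual_fst(G))
terms, fit = drop_null_smooths(table, default_model_terms())
print(f"{len(table)} pairs; deviance explained = "
      f"{fit.deviance_explained_:.1f}%")

res = partition_deviance(table, terms)
print({k: round(v, 1) for k, v in res.unique.items()})
```

Output from this exact script:

```
theta = 0.153, CI [0.143, 0.163], p = 0.005
1081 pairs; deviance explained = 86.7%
{'genetic': 18.3, 'spatial': 0.3, 'environmental': 0.1}
```

Reading: the two simulated founder lineages are moderately differentiated
(θ ≈ 0.15, significantly non-zero); the additive model explains most
pairwise F_ST variation, and ancestry (cluster identity) contributes by far
the largest *unique* share of explained deviance, with geography and
climate mostly overlapping it — the signature of environment co-varying with
introduction history rather than acting independently.

A command-line interface mirrors the library
(`invade-ibe simulate | convert | filter | stats | pairs | evanno | run`);
`invade-ibe run --config config.yaml` drives the full pipeline and writes a
reproducibility manifest.

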