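# Full-pipeline configuration for `invade-ibe run --config examples/config.yaml`.
#
# Either point the pipeline at real data ...
#
#   vcf: data/study_snps.vcf
#   metadata: data/study_metadata.csv
#
# ... or let it generate a synthetic dual-introduction dataset:
simulate:
  preset: study-like          # study-like | null-panmixia | ibd-only | ibe-only
  overrides: {}               # any SimParams field, e.g. {n_loci: 500}

out_dir: results/run1
seed: 1

# Stacks-style locus filters (defaults shown)
filters:
  min_samples_per_pop: 0.7
  min_populations: 1
  min_samples_overall: 0.3
  min_maf: 0.05
  min_mac: 1
  max_obs_het: 0.5

group_column: cluster         # metadata column defining populations
n_boot: 999                   # locus-bootstrap replicates for CIs
n_perm: 999                   # label permutations for the group F_ST test
partition_permutations: 199   # component permutations (0 disables)
mantel_permutations: 10000

# optional: STRUCTURE-style log-likelihood table for the Delta-K utility
# lnpk: data/lnpk.csv
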