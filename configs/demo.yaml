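# Demo pipeline configuration: every stage at desk scale (~2 min, 1 CPU).
# Omitted keys fall back to the full-scale defaults (maf 0.002, geno 0.2,
# LD 2/1/0.5, presence 0.8, pure threshold 0.05, 10 simulations x 25
# replicate fits, 100 null models, top-5 variables).
seed: 3
synth:
  n_loci: 400
  n_per_pool: 30
  env:
    n_sites: 12
    n_variables: 4
    n_loci: 80
    n_adaptive_loci: 20
    n_individuals_per_site: 8
    grid_dims: [5, 5]
admix:
  replicates: 2
bins:
  n_replicate_simulations: 2
  runs_per_sim: 2
  generations: 4
gea:
  n_trees: 40
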