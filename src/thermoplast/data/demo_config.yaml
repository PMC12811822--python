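# Demo run: every stage at reduced problem sizes.
seed: 123
stages: [simulate, tpc, perm, coexpr, windows]
simulate:
  thermal:
    n_individuals_per_group: 6
  expression:
    n_genes: 600
    module_sizes: [60, 60, 60]
  genome:
    n_genes: 40
    n_peaks: 150
tpc:
  chains: 2
  warmup: 400
  draws: 300
perm:
  n_perm: 2000
coexpr:
  top_n: 300
  min_size: 20
  n_boot: 10
windows:
  flank: 5000
  promoter_up: 1000
  promoter_down: 100
  fc_threshold: 2
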