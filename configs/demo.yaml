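# Desk-scale demo run: the full 172-subject cohort at 90 regions with a
# 50-graph null ensemble (the full-scale default is 500 nulls).
cohort:
  n_gene_negative: 80
  n_carrier: 68
  n_ftd: 24
  n_regions: 90
  n_timepoints: 512
  tr_seconds: 2.2
  seed: 0
n_nulls: 50
swaps_per_edge: 3
target_density: 0.10
output_dir: results/demo
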