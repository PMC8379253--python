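# Demonstration pipeline configuration: small synthetic cohort
# (2 vehicle + 2 treated samples, 300 cells each), default marker panel
# and the built-in CD155-axis ligand-receptor list.
#
#   tumortalk run --config examples/demo_config.yaml --out demo_out --seed 7

out_dir: demo_out
simulate:
  n_samples_per_condition: 2
  n_cells_per_sample: 300
qc:
  min_counts_per_cell: 300
  min_genes_per_cell: 100
  max_mito_fraction: 0.5
n_pcs: 7
k_neighbors: 15
resolution: 1.0
sender: cancer
receiver: cd8_t
b_permutations: 200
alpha: 0.05
seeds:
  simulate: 7
  cluster: 7
  permutation: 7
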