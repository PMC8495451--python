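# demo pipeline configuration: small synthetic dataset, all stages
seed: 7
simulate:
  reads:
    n_genes: 12
    n_cells: 20
    mean_molecules_per_cell: 40.0
    mean_reads_per_molecule: 1.5
    labeled_fraction: 0.3
    conversion_rate: 0.05
    error_rate: 0.001
    mean_T_per_read: 20.0
    snp_density: 0.002
  kinetics:
    n_genes: 40
    n_cells: 150
    one_sided_fraction: 0.15
    noise: poisson
  clones:
    n_genes: 300
    n_normal_cells: 60
    n_clone_cells: [60]
    shift: 1.0
    noise_sd: 0.2
  conditions:
    n_conditions: 3
    n_cells_per_condition: 100
    separation: 4.0
    dim: 2
moments:
  n_pcs: 30
  k: 20
kinetics:
  min_shared: 15
scna:
  window: 51
similarity:
  k: 15
gradient:
  n_bins: 20
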