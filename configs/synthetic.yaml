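# Study-scale synthetic run: three cohorts (disease n=90, technical
# replicate n=90, normal n=34) over 300 miRNA features in 10 planted
# modules; three modules lose their co-expression in the normal cohort.
output_dir: results/synthetic_run

data:
  synthetic:
    n_features: 300
    module_sizes: [40, 35, 30, 25, 22, 20, 15, 12, 8, 5]
    rho_within: 0.7
    n_ref: 90
    n_rep: 90
    n_norm: 34
    disrupted_in_norm: [8, 9, 10]
    de_features:
      miR-0188: 1.2
      miR-0189: 1.2
      miR-0190: 1.2
      miR-0191: 1.2
      miR-0192: 1.2
      miR-0193: 1.2
      miR-0194: 1.2
      miR-0195: 1.2
      miR-0196: 1.5
      miR-0197: 1.5
      miR-0198: 1.5
      miR-0199: 1.5
      miR-0200: 1.5
      miR-0001: 1.0
      miR-0002: 1.0
      miR-0041: 1.0
      miR-0042: 1.0
    rep_noise_sd: 0.3
    seed: 1

coexpr:
  fit_cut: 0.8
  min_module_size: 3
  deep_split: 2
  tom_cutoff: 0.1

preservation:
  n_perm: 200
  seed: 11

netsvm:
  lambda_margin: 0.01
  lambda_net: 0.01
  top_k_up: 20
  top_k_down: 20
  folds: 5
  seed: 7

diagnostics:
  weight_mode: netsvm
  min_subset_size: 1
  max_members: 12

annotate:
  synthesize: true
  n_genes: 200
  alpha: 0.05
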