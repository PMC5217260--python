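# Demo pipeline configuration: synthetic study at full demo scale.
# Run with:  methylong all -c examples/demo_config.yaml
out_dir: scratch/demo_run
seed: 1
sim:
  n_probes: 20000
  n_control_probes: 613
  n_snps: 5000
  n_children_per_cohort: 150
  n_causal_meqtl: 100
params:
  pca_n_perm: 200     # permutation count for control-PC selection
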