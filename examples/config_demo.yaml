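# Demo run configuration: synthetic input, two-group comparison.
# Run with:  kea run examples/config_demo.yaml
input:
  simulate:
    n_sites: 2000
    n_kinases: 43
    substrates_per_kinase: 20
    n_active: 3
comparison:
  mode: two_group
  test: treat
  reference: control
preprocess:
  loc_prob_min: 0.75
  impute: true
enrichment:
  set_p_cutoff: 0.01
  fdr_cutoff: 0.05
  b_null: 100
seed: 11
output: scratch/demo_run
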