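# Demo pipeline configuration: runs end to end in minutes on one CPU.
#   scdsim all --config examples/demo_config.yaml
seed: 42
outdir: demo_out
scenario: combined
n_beneficiaries: 2000
n_simulate: 2000
calibration_n_sim: 3000
calibration_max_iter: 12
calibration_tolerance: 2.0
penalty_strength: 1.0
penalty_kind: elastic_net
l1_ratio: 0.5
strategies: [common_care, gene_therapy]
discount_rate: 0.03
psa_draws: 20
psa_cohort_n: 150
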