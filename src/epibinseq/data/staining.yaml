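# Frozen calibrated single-clone FCM staining configuration.
n_cells: 100000
log10_antigen_median: 5.0
log10_antigen_sd: 0.5
log10_qab_median: 5.0
log10_qab_sd: 0.5
alpha: 2.5e-4
gain: 0.1124
noise_sd: 30.0
q_gate: 0.995
antigen_low_fraction: 0.04
antigen_low_factor: 1.0e-3
seed: 0
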