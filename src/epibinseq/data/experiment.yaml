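# The shipped 14-clone epitope-binning experiment.
sim:
  n_cells: 1000000
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
n_reads: 100000
negative_control: Niv
threshold: 3.0
library_sample: library
conditions:
  - {sample_id: sorted_pert_0.1nM, rab: Pert-AF647, concentration: 0.1}
  - {sample_id: sorted_pert_10nM, rab: Pert-AF647, concentration: 10.0}
  - {sample_id: sorted_tras_0.1nM, rab: Tras-AF647, concentration: 0.1}
  - {sample_id: sorted_tras_10nM, rab: Tras-AF647, concentration: 10.0}
binning_samples: [sorted_pert_0.1nM, sorted_tras_0.1nM]
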