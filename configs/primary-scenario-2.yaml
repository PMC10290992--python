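# Arrhythmia scenario (early return to systole) at phantom scale.
# Run with:  cinekalman report --config configs/primary-scenario-2.yaml --out scratch/scenario2
seed: 0
grid: {N: 32, T: 20}
scenario:
  kind: arrhythmia
  n_cycles: 3
  truncate_at_phase: 12
sampling:
  kind: radial
  n_spokes: 3
  noise_sigma: 0.01
recon:
  variants: [two_stage, random_walk]
  R_sigma2: 1.0e-4
  P0_sigma2: 1.0e-3
rescale_means: true
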