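seed: 0
et_ratios:
- 1.25
- 2.5
- 5.0
- 10.0
- 20.0
- 40.0
replicates: 3
noise_cv: 0.05
killing:
  n0: 50000.0
  k_max: 0.012
  r50: 40.0
  f_res: 0.1
luminescence:
  amp: 2.0
  k_up: 0.5
  k_deg: 0.01
  alpha_perm: 10.0
render:
  image_shape:
  - 256
  - 384
  well_pitch_px: 30.0
  well_sigma_px: 3.0
  background_flux: 1.0
  noise_cv: 0.0
  origin_px: null
  seed: 0
  n_rows: 8
  n_cols: 12
schedule:
  times:
  - 0.0
  - 2.0
  - 4.0
  - 6.0
  - 8.0
  - 10.0
  - 12.0
  - 14.0
  - 16.0
  - 18.0
  - 20.0
  - 22.0
  - 24.0
  - 26.0
  - 28.0
  - 30.0
  - 32.0
  - 34.0
  - 36.0
  - 38.0
  - 40.0
  - 42.0
  - 44.0
  - 46.0
  - 48.0
  - 50.0
  - 52.0
  - 54.0
  - 56.0
  - 58.0
  - 60.0
  - 65.0
  - 70.0
  - 75.0
  - 80.0
  - 85.0
  - 90.0
  - 95.0
  - 100.0
  - 105.0
  - 110.0
  - 115.0
  - 120.0
  - 125.0
  - 130.0
  - 135.0
  - 140.0
  - 145.0
  - 150.0
  - 155.0
  - 160.0
  - 165.0
  - 170.0
  - 175.0
  - 180.0
  - 185.0
  - 190.0
  - 195.0
  - 200.0
  - 205.0
  - 210.0
  - 215.0
  - 220.0
  - 225.0
  - 230.0
  - 235.0
  - 240.0
cra:
  max_cpm: 10000.0
  spont_frac: 0.15
  cpm_cv: 0.08
  replicates: 3
flow:
  n_targets: 50000
  n_effectors: 50000
  channel_means:
    target:
      CFSE: 4.0
      CD56: 1.0
      7AAD: 1.0
      FSC: 4.3
      SSC: 4.0
    effector:
      CFSE: 1.0
      CD56: 3.8
      7AAD: 1.0
      FSC: 3.8
      SSC: 3.5
    target_dead:
      7AAD: 3.5
  channel_cvs:
    CFSE: 0.15
    CD56: 0.15
    7AAD: 0.15
    FSC: 0.08
    SSC: 0.1
  baseline_dead_frac: 0.05
  seed: 0
gates:
  cfse_threshold: 316.22776601683796
  cd56_threshold: 316.22776601683796
  aad_threshold: 158.48931924611142
analysis:
  smoothing: 1
  sustain: 2
  t_end: 240.0
  background: none
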