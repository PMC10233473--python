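# Small end-to-end demo: simulate -> calibrate -> prepare -> train ->
# predict -> localize -> evaluate, a few minutes on one CPU.
seed: 1
simulate:
  n_pairs: 6
  n_frames: 16
  tilt_deg: 18.0
  waist_fwhm_um: 1.6
  rayleigh_um: 13.2
  focus_xy_um: 3.8           # centre of the 48-px-wide imaging field
  phantom_params:
    n: 400
    center_um: [3.8, 7.5, 0.0]
    bounds_um: [3.8, 7.5, 3.0]
    photon_rate: 60.0
calibrate:
  fov_px: [16, 448]          # wide field for the profile scan
  z_min_um: -5.0
  z_max_um: 5.0
  frames_per_z: 20
detection:
  fov_px: [96, 48]
camera:
  em_gain: 50.0
dataset:
  n_average: 16
  split_fraction: 0.8
model:
  n_stages: 2
  n_channels: 8
  batch_size: 8
  n_epochs: 4
smlm:
  drift_bins: 0   # too few localizations at demo scale for drift estimation
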