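# Profile-scan calibration demo: 1.6 um sheet at 18 degrees.
# The field is wide enough to follow the stripe drift over the z scan.
simulate:
  tilt_deg: 18.0
  waist_fwhm_um: 1.6
  rayleigh_um: 13.2
  focus_xy_um: 65.3   # centre of the 832-px field
detection:
  fov_px: [16, 832]
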