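# Example run configuration for `retrogate run --config ...`.
# Every field is optional; omitted fields take the package defaults.

phantom:
  grid_n: 160
  pixel_mm: 0.2
  heart_rate_bpm: 400.0     # beats/min
  resp_rate_bpm: 80.0       # breaths/min
  inspiratory_fraction: 0.30
  cycle_jitter_cv: 0.05     # per-beat cycle-length CV
  contraction_factor: 0.632 # area-EF ~60%

geometry:
  n_angles_per_rotation: 720
  detector_pixels: 160
  detector_pitch_mm: 0.2
  frame_rate_hz: 40.0
  duration_s: 60.0
  photon_count_I0: 0        # >0 enables Poisson noise, e.g. 1.0e4

gating:
  cardiac_band_hz: [5.0, 12.0]   # 300-720 bpm
  resp_band_hz: [0.5, 4.0]       # 30-240 breaths/min
  insp_quantile: 0.70
  n_bins: 12
  search_radius_px: 10

recon_method: ositer   # or fbp
post_filter_fwhm_mm: 0.0
seed: 1
out_dir: run_output
log_level: info
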