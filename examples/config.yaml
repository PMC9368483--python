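# retphys pipeline configuration (defaults; field names carry units)
alpha: 0.05
cohort:
  calibrations:
  - group: WT
    means:
      abeta40_brain: 9.3
      abeta40_retina: 2.5
      abeta42_brain: 1.4
      abeta42_retina: 2.4
      d_a_um: 27.0
      d_v_um: 30.0
      inl: 31.0
      ipl: 36.7
      nfl_rgcl: 16.2
      o2a_ml_dl: 6.5
      o2av_ml_dl: 3.7
      o2v_ml_dl: 2.8
      onl: 44.3
      opl: 14.6
      prl: 29.1
      trbf_ul_min: 1.73
      trt_oct: 242.0
      v_v_mm_s: 10.5
    n_animals: 13
    sds:
      abeta40_brain: 3.0
      abeta40_retina: 0.2
      abeta42_brain: 0.5
      abeta42_retina: 0.8
      d_a_um: 2.0
      d_v_um: 3.0
      inl: 4.4
      ipl: 4.0
      nfl_rgcl: 4.2
      o2a_ml_dl: 1.4
      o2av_ml_dl: 1.3
      o2v_ml_dl: 1.9
      onl: 4.6
      opl: 2.0
      prl: 3.9
      trbf_ul_min: 0.52
      trt_oct: 11.0
      v_v_mm_s: 3.1
  - group: 5XFAD
    means:
      abeta40_brain: 8.2
      abeta40_retina: 4.9
      abeta42_brain: 6.1
      abeta42_retina: 5.4
      d_a_um: 27.0
      d_v_um: 33.0
      inl: 31.0
      ipl: 36.7
      nfl_rgcl: 15.1
      o2a_ml_dl: 7.8
      o2av_ml_dl: 3.5
      o2v_ml_dl: 4.3
      onl: 47.6
      opl: 17.2
      prl: 29.1
      trbf_ul_min: 1.63
      trt_oct: 235.0
      v_v_mm_s: 6.6
    n_animals: 13
    sds:
      abeta40_brain: 1.2
      abeta40_retina: 1.5
      abeta42_brain: 1.9
      abeta42_retina: 2.6
      d_a_um: 3.0
      d_v_um: 3.0
      inl: 4.4
      ipl: 4.0
      nfl_rgcl: 2.8
      o2a_ml_dl: 1.2
      o2av_ml_dl: 1.1
      o2v_ml_dl: 1.6
      onl: 2.7
      opl: 1.3
      prl: 3.9
      trbf_ul_min: 0.5
      trt_oct: 6.0
      v_v_mm_s: 1.4
  edge_width_um: 4.0
  frame_rate_hz: 104.0
  gaussian_blur_sigma_um: 0.0
  histology_shrinkage: 1.0
  modulation_frequency_hz: 250.0
  n_arteries_per_eye: 4
  n_spheres_per_vein: 5
  n_track_frames: 10
  n_veins_per_eye: 4
  oximetry:
    hb_capacity_ml_g: 1.39
    hb_g_dl: 15.0
    hill_n: 2.59
    kq_per_mmhg_s: 381.0
    p50_mmhg: 40.0
    solubility_ml_dl_mmhg: 0.003
    tau0_s: 0.000637
    tau_tolerance: 0.02
  phase_noise_sd_rad: 0.005
  pixel_pitch_um: 0.5
  pooled_correlation_o2a_nfl: -0.53
  pooled_correlation_o2a_vv: -0.57
  profile_noise_frac: 0.01
  region_asymmetry_sd: 0.03
  rng_seed: 1
  track_noise_um: 1.0
  within_eye_cv: 0.1
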