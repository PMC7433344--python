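{
  "line": "spasmodic",
  "comment": "Illustrative cohort parameters for the Glra1 A52S line: homozygotes show large, intensity-increasing startle transients and long, frequent freezing with on-back episodes; wt and het are unremarkable. Magnitudes mirror the ordinal structure of the reported group data, not fitted values.",
  "base": {
    "baseline_noise_sd": 1.0,
    "startle_latency_s": 0.02,
    "transient_decay_s": 0.05,
    "transient_freq_hz": 40.0,
    "peak_jitter_cv": 0.15,
    "response_prob": 1.0,
    "motion_move_level": 10.0,
    "motion_noise_sd": 1.0,
    "frame_rate_hz": 30.0
  },
  "genotypes": {
    "wt": {
      "startle_gain": {"70": 50, "80": 125, "90": 280, "100": 450},
      "state_entry_rates": {"grooming": 0.006667, "freezing": 0.002857, "rearing": 0.0125, "stretch_attend": 0.005, "on_back": 0.0},
      "state_dwell_s": {"grooming": 10.0, "freezing": 8.0, "rearing": 4.0, "stretch_attend": 5.0, "on_back": 4.0}
    },
    "het": {
      "startle_gain": {"70": 55, "80": 130, "90": 290, "100": 460},
      "state_entry_rates": {"grooming": 0.006667, "freezing": 0.002857, "rearing": 0.0125, "stretch_attend": 0.005, "on_back": 0.0},
      "state_dwell_s": {"grooming": 10.0, "freezing": 8.0, "rearing": 4.0, "stretch_attend": 5.0, "on_back": 4.0}
    },
    "hom": {
      "startle_gain": {"70": 570, "80": 920, "90": 1010, "100": 1130},
      "state_entry_rates": {"grooming": 0.001667, "freezing": 0.006667, "rearing": 0.001667, "stretch_attend": 0.004, "on_back": 0.003333},
      "state_dwell_s": {"grooming": 4.0, "freezing": 14.0, "rearing": 2.0, "stretch_attend": 4.0, "on_back": 8.0}
    }
  }
}
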