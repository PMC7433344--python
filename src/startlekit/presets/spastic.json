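{
  "line": "spastic",
  "comment": "Illustrative cohort parameters for the Glrb LINE-1 line: heterozygotes are behaviorally indistinguishable from wt (flat-ish startle gains, wt-like state process). Magnitudes mirror the ordinal structure of the reported group data, not fitted values.",
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
      "startle_gain": {"70": 67, "80": 90, "90": 199, "100": 230},
      "state_entry_rates": {"grooming": 0.006667, "freezing": 0.004, "rearing": 0.0125, "stretch_attend": 0.005, "on_back": 0.0},
      "state_dwell_s": {"grooming": 10.0, "freezing": 8.0, "rearing": 4.0, "stretch_attend": 5.0, "on_back": 4.0}
    },
    "het": {
      "startle_gain": {"70": 78, "80": 121, "90": 198, "100": 115},
      "state_entry_rates": {"grooming": 0.006667, "freezing": 0.003333, "rearing": 0.0143, "stretch_attend": 0.005, "on_back": 0.0},
      "state_dwell_s": {"grooming": 10.0, "freezing": 8.0, "rearing": 4.0, "stretch_attend": 5.0, "on_back": 4.0}
    }
  }
}
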