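# Default kinetic registry for relaxase-DNA co-translocational unfolding
# through a single alpha-hemolysin pore in 2 M KCl.
#
# Rates (s^-1) and residual currents (% of open-pore current) are the
# published +120 mV values for the TrwC relaxase domain pulled by a
# 30-mer ssDNA leader attached at tyrosine 18 (Y18) or tyrosine 26 (Y26).
# Steps 2->3 and 3->4 carry extra voltage anchors (printed endpoints of the
# +100..+140 mV series); all other steps showed no significant voltage
# dependence and keep their +120 mV value across the supported range.
schema_version: 1

open_pore:
  anchor_voltage_mv: 120
  anchor_current_pa: 230.0   # scales ohmically with applied voltage

voltage_range_mv: [100, 140]

capture_rate_per_min:        # linear in voltage between printed endpoints
  100: 12.0
  140: 55.0

wt_mixture_weights:          # Y18-like / Y26-like population split (k-means)
  Y18: 0.78
  Y26: 0.22

constructs:
  Y18:
    level_residual_pct: [50.5, 15.5, 9.5, 1.3, 14.2, 10.8, 2.6]
    level_residual_sd_pct: [0.1, 0.2, 0.2, 0.1, 0.04, 0.2, 0.4]
    steps:
      "1":
        rates: {120: 379.0}
        ci95: {120: [315.0, 443.0]}
      "2":
        voltage_dependent: true
        rates: {100: 28.0, 120: 37.0, 140: 36.0}
        ci95: {100: [25.0, 30.0], 120: [35.0, 39.0], 140: [31.0, 42.0]}
      "3":
        voltage_dependent: true
        rates: {100: 11.0, 120: 12.0, 140: 16.0}
        ci95: {100: [10.0, 13.0], 120: [10.0, 15.0], 140: [14.0, 18.0]}
      "4":
        rates: {120: 275.0}
        ci95: {120: [161.0, 389.0]}
      "5":
        rates: {120: 0.98}
        ci95: {120: [0.82, 1.1]}
      "6":
        rates: {120: 22.0}
        ci95: {120: [16.0, 27.0]}
      "7":
        rates: {120: 36.0}
        ci95: {120: [25.0, 47.0]}
  Y26:
    level_residual_pct: [48.7, 13.7, 15.0, 1.3, 15.1, 11.8, 2.8]
    level_residual_sd_pct: [0.5, 1.6, 0.4, 0.08, 0.3, 0.3, 0.6]
    steps:
      "1":
        rates: {120: 437.0}
        ci95: {120: [315.0, 559.0]}
      "2":
        voltage_dependent: true   # endpoints unpublished; single anchor
        rates: {120: 1051.0}
        ci95: {120: [985.0, 1116.0]}
      "3":
        voltage_dependent: true   # endpoints unpublished; single anchor
        rates: {120: 0.17}
        ci95: {120: [0.15, 0.20]}
      "4":
        rates: {120: 155.0}
        ci95: {120: [106.0, 204.0]}
      "5":
        rates: {120: 0.96}
        ci95: {120: [0.81, 1.1]}
      "6":
        rates: {120: 18.0}
        ci95: {120: [13.0, 23.0]}
      "7":
        rates: {120: 34.0}
        ci95: {120: [27.0, 41.0]}

# Observed rates for the wild-type mixture at +120 mV (double-exponential
# components for the bimodal steps 2->3 and 3->4); kept for cross-checks.
wt_observed_rates:
  "1": {rate: 422.0, ci95: [330.0, 514.0]}
  "2": {fast: 966.0, fast_ci95: [533.0, 1399.0], slow: 32.0, slow_ci95: [27.0, 36.0]}
  "3": {fast: 10.0, fast_ci95: [8.0, 12.0], slow: 0.19, slow_ci95: [0.10, 0.29]}
  "4": {rate: 244.0, ci95: [116.0, 371.0]}
  "5": {rate: 0.82, ci95: [0.66, 0.98]}
  "6": {rate: 25.0, ci95: [14.0, 36.0]}
  "7": {rate: 33.0, ci95: [21.0, 45.0]}

# Denaturant (GdnHCl in the trans chamber) regime: levels 1-4 keep their
# canonical kinetics, the post-level-4 tail is replaced by irregular
# blockades.  Distributions are synthetic; the dwell upper bound is
# calibrated once so that the median whole-event duration is ~2x the
# canonical Y18 median, matching the observed 1.93 s vs 0.99 s.
gdnhcl_blockades:
  n_segments: [3, 10]          # uniform integer, inclusive
  ires_pct: [1.0, 20.0]        # uniform
  dwell_s: [0.001, 2.3]        # log-uniform (upper bound calibrated)
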