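# Mature-plate preset: stable spontaneous activity around day 27 in vitro.
# Calibrated so active electrodes fire ~3.55 Hz on average (wide
# electrode-to-electrode dispersion) with mid-range well synchrony.
simulator:
  baseline_rate_hz: 1.0
  burst_rate_hz: 0.063
  burst_participation: 0.5
  intra_burst_rate_hz: 85.0
  burst_duration_s: 1.0
  fraction_active: 0.97
  rate_cv: 0.59
  noise_sd_uv: 1.5
  spike_amplitude_uv: 12.0
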