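# Inflammatory arm: 24 h incubation with 50 ng/ml TNF-alpha produces a
# hyperexcitable phenotype.  rate_factor 2.6 corresponds to a
# difference-over-sum MFR change of ~+0.45 versus vehicle.
effect:
  rate_factor: 2.6
  synchrony_delta: 0.0
  onset_tau_s: 10.0
  applies_to: 1.0
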