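# 15-compound synthetic screen (4 wells per compound at 10 µM bolus,
# plus vehicle / lidocaine / TNF-alpha arms).  Ten compounds carry a
# designed strong suppression (rate_factor 0.1, the scale of a full
# sodium-channel block); five are designed nulls.  onset_tau is the
# diffusion-delayed onset of the bolus, scaled with the demo epochs.
compounds:
  honokiol:            {rate_factor: 0.1, onset_tau_s: 10.0}
  nimodipine:          {rate_factor: 0.1, onset_tau_s: 10.0}
  nicardipine:         {rate_factor: 0.1, onset_tau_s: 10.0}
  rifampin:            {rate_factor: 0.1, onset_tau_s: 10.0}
  trametinib:          {rate_factor: 0.1, onset_tau_s: 10.0}
  everolimus:          {rate_factor: 0.1, onset_tau_s: 10.0}
  vx745:               {rate_factor: 0.1, onset_tau_s: 10.0}
  sorafenib:           {rate_factor: 0.1, onset_tau_s: 10.0}
  sorafenib_tosylate:  {rate_factor: 0.1, onset_tau_s: 10.0}
  phenytoin:           {rate_factor: 0.1, onset_tau_s: 10.0}
  levetiracetam:       {rate_factor: 1.0, onset_tau_s: 10.0}
  capecitabine:        {rate_factor: 1.0, onset_tau_s: 10.0}
  selumetinib:         {rate_factor: 1.0, onset_tau_s: 10.0}
  zonisamide:          {rate_factor: 1.0, onset_tau_s: 10.0}
  lamotrigine:         {rate_factor: 1.0, onset_tau_s: 10.0}
controls:
  vehicle:   {rate_factor: 1.0, onset_tau_s: 10.0}
  lidocaine: {rate_factor: 0.1, onset_tau_s: 10.0}
  tnf_alpha: {rate_factor: 2.6, onset_tau_s: 10.0}
wells_per_arm: 4
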