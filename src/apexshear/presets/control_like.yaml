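# Recovery-zone wall-shear preset: TAWSS peak just off the apex, so the
# high-WSS region lies on the decaying limb (negative dirWSSG).
zonal_field:
  tau_impingement: 85.0
  tau_peak: 90.0
  peak_distance: 1.0
  decay_length: 4.0
  pulsatility: 0.4
  reversal_fraction: 0.1
period: 0.9
n_times: 24
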