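# Acceleration-zone wall-shear preset: TAWSS peak beyond the apex patch,
# so the high-WSS region lies on the rising limb (positive dirWSSG).
zonal_field:
  tau_impingement: 25.0   # Pa, at the apex
  tau_peak: 100.0         # Pa
  peak_distance: 7.0      # mm of geodesic arclength
  decay_length: 5.0       # mm
  pulsatility: 0.4
  reversal_fraction: 0.08
period: 0.9               # s
n_times: 24
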