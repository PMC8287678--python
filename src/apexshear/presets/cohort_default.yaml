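# Default synthetic-cohort study conditions: 38 cases / 39 controls with the
# per-group median (q25, q75) calibration targets and dirWSSG proportions.
n_case: 38
n_control: 39
p_dir_pos_case: 0.6052631578947368    # 23/38
p_dir_pos_control: 0.358974358974359  # 14/39
seed: 0
targets:
  case:
    WSS: [69.36, 59.27, 89.96]        # Pa
    WSSG: [11.05, -14.88, 28.06]      # Pa/mm, signed
    absWSSG: [23.63, 12.29, 56.13]    # Pa/mm
    OSI: [0.175, 0.069, 0.319]
  control:
    WSS: [76.59, 61.92, 125.27]
    WSSG: [-14.76, -64.49, 18.14]
    absWSSG: [35.07, 15.29, 74.86]
    OSI: [0.185, 0.0, 0.353]
spearman:
  - [WSS, absWSSG, 0.488]
  - [absWSSG, OSI, -0.309]
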