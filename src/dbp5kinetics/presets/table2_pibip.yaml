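# Global-fit constants from transient phosphate-sensor data (uM, s).
rates:
  k_on_T: 0.92       # uM^-1 s^-1
  k_off_T: 3670.0    # s^-1
  k_hyd: 0.72        # s^-1
  k_resyn: 0.38      # s^-1
  k_rel_Pi: 0.04     # s^-1
  k_rebind_Pi: 0.0   # uM^-1 s^-1
  k_off_D: 64.0      # s^-1
  k_rebind_D: 0.2    # uM^-1 s^-1
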