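# Global-fit constants from steady-state NADH-coupled assay data (uM, s).
rates:
  k_on_T: 0.92       # uM^-1 s^-1
  k_off_T: 3670.0    # s^-1
  k_hyd: 0.16        # s^-1
  k_resyn: 6.0e-4    # s^-1
  k_rel_Pi: 0.062    # s^-1
  k_rebind_Pi: 0.0   # uM^-1 s^-1 (constrained near zero)
  k_off_D: 64.0      # s^-1
  k_rebind_D: 0.2    # uM^-1 s^-1
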