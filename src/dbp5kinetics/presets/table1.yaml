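# Experimentally determined transient-kinetics constants for the intrinsic
# Dbp5 ATPase cycle (uM, s units).  ATP binding is rapid-equilibrium: the
# on-rate is derived from the competition-assay affinity K_T = 6.4 mM with
# k_off_T = 3670 s^-1; ADP binding from K_D = 360 uM with k_off_D = 64 s^-1.
rates:
  k_on_T: 0.5734375      # uM^-1 s^-1  (= 3670 / 6400)
  k_off_T: 3670.0        # s^-1
  k_hyd: 2.2             # s^-1
  k_resyn: 2.0e-4        # s^-1
  k_rel_Pi: 0.02         # s^-1
  k_rebind_Pi: 0.0       # uM^-1 s^-1  (release effectively irreversible)
  k_off_D: 64.0          # s^-1
  k_rebind_D: 0.1777778  # uM^-1 s^-1  (= 64 / 360)
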