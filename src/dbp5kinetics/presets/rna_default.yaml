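# Default RNA-branch parameters.  The saturable engagement step (Kd_RNA,
# k_iso) and the RNA-bound phosphate release rate reproduce the observed
# 4-6 s^-1 lag at 10 mM RNA and ~3 mM half-saturation; resynthesis on the
# RNA branch is ~80-fold faster than in the intrinsic cycle and hydrolysis
# is scaled up so that it does not become rate limiting.
rna:
  Kd_RNA: 3000.0      # uM nucleotide
  k_iso: 5.0          # s^-1
  k_rel_Pi_RNA: 5.0   # s^-1
  hyd_scale: 10.0
  resyn_scale: 80.0
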