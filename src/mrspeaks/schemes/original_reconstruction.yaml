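name: original_reconstruction
steps:
  - label: PA
    conditions:
      - {ratio: naa_cr, op: ">", cutoff: 4.0}
      - {ratio: mins_naa, op: "<", cutoff: 1.35}
  - label: MB
    conditions:
      - {ratio: cr_tcho, op: "<", cutoff: 0.45}
else_class: EP
checks: []
notes: >
  RECONSTRUCTION of the original single-centre scheme.  Only its three
  ratios (NAA/Cr, mIns/NAA, Cr/tCho) and the original NAA/Cr cutoff of 4
  are on record; the mIns/NAA and Cr/tCho cutoffs here are the values
  from the later re-optimisation, the best available stand-ins.  Treat
  results from this config as indicative, not as the historical scheme.
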