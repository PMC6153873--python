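name: reoptimized_original
steps:
  - label: PA
    conditions:
      - {ratio: naa_cr, op: ">", cutoff: 2.22}
      - {ratio: mins_naa, op: "<", cutoff: 1.35}
  - label: MB
    conditions:
      - {ratio: cr_tcho, op: "<", cutoff: 0.45}
else_class: EP
checks: []
notes: >
  The original three-ratio scheme with cutoffs re-optimised on the
  combined 52-spectrum dataset: NAA/Cr 2.22, mIns/NAA 1.35 (step 1,
  pilocytic astrocytoma) and Cr/tCho 0.45 (step 2, medulloblastoma
  versus ependymoma).  Step structure as in the reconstruction.
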