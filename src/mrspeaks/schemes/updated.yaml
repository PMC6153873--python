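name: updated
steps:
  - label: PA
    conditions:
      - {ratio: naa_cr, op: ">", cutoff: 2.22}
      - {ratio: mins_naa, op: "<", cutoff: 0.65}
  - label: MB
    conditions:
      - {ratio: mins_tcho, op: "<", cutoff: 0.85}
else_class: EP
checks:
  - {ratio: cr_tcho, ranges: {}}
  - {ratio: naa_tcho, ranges: {}}
notes: >
  Updated two-step peak-height-ratio scheme derived from the combined
  53-case multicentre 1.5-T short-TE dataset.  Step 1 selects pilocytic
  astrocytoma, step 2 medulloblastoma, the remainder ependymoma.
  Cr/tCho and NAA/tCho verify but never override the assignment.
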