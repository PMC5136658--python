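chain_id: A
helices:
  TM1: [366, 391]
  TM2: [396, 422]
  TM3: [440, 471]
  TM4: [486, 509]
  TM5: [533, 560]
  TM6: [563, 592]
  TM7: [612, 634]
extracellular_end_of_TM1: first
anchor_overrides:
  "5.50": 549
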