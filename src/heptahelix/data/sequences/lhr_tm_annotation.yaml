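chain_id: A
helices:
  TM1: [362, 386]
  TM2: [393, 419]
  TM3: [437, 468]
  TM4: [483, 506]
  TM5: [523, 556]
  TM6: [560, 595]
  TM7: [610, 631]
extracellular_end_of_TM1: first
anchor_overrides:
  "5.50": 537
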