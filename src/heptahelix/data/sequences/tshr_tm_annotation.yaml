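# TSHR transmembrane-helix ranges (author numbering). The 5.50 anchor is an
# override: glycoprotein-hormone receptors carry Ala, not Pro, at 5.50.
chain_id: A
helices:
  TM1: [418, 441]
  TM2: [448, 474]
  TM3: [491, 523]
  TM4: [538, 561]
  TM5: [578, 611]
  TM6: [614, 649]
  TM7: [658, 681]
extracellular_end_of_TM1: first
anchor_overrides:
  "5.50": 593
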