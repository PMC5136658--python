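# Bovine rhodopsin, inactive. BW positions from canonical anchors
# (N55 1.50, P215 5.50, P303 7.50): 7.40 -> 293, 1.39 -> 44.
accession: 1U19
chain_id: A
positions:
  "7.40": 293
  "1.39": 44
  "7.53": 306
  "5.58": 223
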