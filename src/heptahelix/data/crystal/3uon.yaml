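# Human M2 muscarinic acetylcholine receptor, inactive.
# Anchors N41 1.50, P437 7.50: 7.40 -> 427, 1.39 -> 30.
accession: 3UON
chain_id: A
positions:
  "7.40": 427
  "1.39": 30
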