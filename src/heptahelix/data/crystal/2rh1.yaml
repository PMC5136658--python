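# Human beta2 adrenergic receptor, inactive (T4-lysozyme fusion retained;
# positions select receptor residues). Anchors N51 1.50, P323 7.50.
accession: 2RH1
chain_id: A
positions:
  "7.40": 313
  "1.39": 40
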