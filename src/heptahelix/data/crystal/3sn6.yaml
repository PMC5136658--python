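# Human beta2 adrenergic receptor-Gs complex, active. Receptor is chain R.
accession: 3SN6
chain_id: R
positions:
  "7.40": 313
  "1.39": 40
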