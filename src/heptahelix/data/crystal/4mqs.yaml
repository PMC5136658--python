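# Human M2 muscarinic acetylcholine receptor, active; numbering as 3UON.
accession: 4MQS
chain_id: A
positions:
  "7.40": 427
  "1.39": 30
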