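# Metarhodopsin II (active bovine rhodopsin); same numbering as 1U19.
accession: 3PQR
chain_id: A
positions:
  "7.40": 293
  "1.39": 44
  "7.53": 306
  "5.58": 223
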