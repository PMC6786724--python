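{
  "name": "butyrate_producers",
  "genera": [
    "Anaerostipes",
    "Butyricicoccus",
    "Butyrivibrio",
    "Coprococcus",
    "Faecalibacterium",
    "Odoribacter",
    "Oscillibacter",
    "Roseburia",
    "Subdoligranulum"
  ]
}
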