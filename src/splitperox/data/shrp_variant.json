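{
  "name": "sHRP",
  "mutations": [
    "T21I",
    "P78S",
    "R93G",
    "N175S",
    "N255D",
    "L299R"
  ],
  "split_after": 213
}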