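{
  "name": "sAPEX2",
  "mutations": [
    "K22R",
    "R24G",
    "G50R",
    "K61R",
    "H62Y",
    "N72S",
    "P125L",
    "I165L",
    "I185V"
  ],
  "split_after": 200
}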