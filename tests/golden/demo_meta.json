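{
  "seed": 12345,
  "version": "0.1.0",
  "tables": [
    "cysts",
    "fibers",
    "frap",
    "transport"
  ]
}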