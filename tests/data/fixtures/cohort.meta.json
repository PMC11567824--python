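{
  "seed": 20240,
  "n": 50,
  "spec_hash": "f6bd7d801cda1f4e"
}
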