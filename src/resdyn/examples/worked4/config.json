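{
  "schema_version": 1,
  "targets": [7.0],
  "blm": 0.0,
  "spf": [1000000.0],
  "alpha": 8.0,
  "initial_reserve": [],
  "budget": {"constant": 1.0}
}
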