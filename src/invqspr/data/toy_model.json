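{
 "names": [
  "n_heavy",
  "elt_ext:O"
 ],
 "weights": {
  "n_heavy": -0.42,
  "elt_ext:O": 1.15
 },
 "intercept": 1.0
}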