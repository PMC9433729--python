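{
  "loss": {
    "1": [-0.6, 0.0],
    "2": [-1.0, 1.0],
    "3": [0.0, 0.45],
    "4": [-0.9, 0.9],
    "5": [-0.45, 0.45]
  },
  "gain": {
    "1": [-0.6, 0.0],
    "2": [-1.0, 1.0],
    "3": [0.0, 0.45],
    "4": [-0.9, 0.9],
    "5": [-0.45, 0.45]
  }
}
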