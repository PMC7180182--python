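{
  "overall_positives": {"d": 56, "e": 68, "f": 76, "g": 93},
  "overall_true_positives": {"d": 39, "e": 42, "f": 48, "g": 54},
  "within186_positives": {"h": 19, "i": 25, "j": 32, "k": 39},
  "within186_true_positives": {"h": 15, "i": 17, "j": 21, "k": 24},
  "ph_among_detected": {
    "a": 34, "b": 16, "c": 16,
    "d": 23, "e": 24, "f": 28, "g": 29,
    "h": 22, "i": 22, "j": 25, "k": 25
  }
}
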