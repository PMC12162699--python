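{
  "version": 1,
  "description": "Published per-patient classification counts of the three stenosis/plaque rules against the PET-based ischemic-CAD reference label.",
  "matrices": {
    "model1": {"tp": 278, "fp": 208, "fn": 95, "tn": 1564},
    "model2": {"tp": 153, "fp": 52, "fn": 220, "tn": 1720},
    "model3": {"tp": 285, "fp": 164, "fn": 88, "tn": 1608}
  }
}
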