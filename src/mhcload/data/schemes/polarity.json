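{
  "name": "polarity",
  "class_labels": [
    "low",
    "medium",
    "high"
  ],
  "classes": {
    "1": "CFILMVWY",
    "2": "AGPST",
    "3": "DEHKNQR"
  }
}
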