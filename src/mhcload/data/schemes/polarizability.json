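{
  "name": "polarizability",
  "class_labels": [
    "low",
    "medium",
    "high"
  ],
  "classes": {
    "1": "ADGST",
    "2": "CEILNPQV",
    "3": "FHKMRWY"
  }
}
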