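{
  "name": "structure",
  "class_labels": [
    "helix",
    "strand",
    "coil"
  ],
  "classes": {
    "1": "AEHKLMQR",
    "2": "CFITVWY",
    "3": "DGNPS"
  }
}
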