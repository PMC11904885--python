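{
  "name": "hydrophobicity",
  "class_labels": [
    "polar",
    "neutral",
    "hydrophobic"
  ],
  "classes": {
    "1": "DEKNQR",
    "2": "AGHPSTY",
    "3": "CFILMVW"
  }
}
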