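{
  "name": "solvent",
  "class_labels": [
    "buried",
    "exposed",
    "intermediate"
  ],
  "classes": {
    "1": "ACFGILVW",
    "2": "DEKNQR",
    "3": "HMPSTY"
  }
}
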