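{
  "name": "van_der_waals",
  "class_labels": [
    "small",
    "medium",
    "large"
  ],
  "classes": {
    "1": "ACDGPST",
    "2": "EILNQV",
    "3": "FHKMRWY"
  }
}
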