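{
  "name": "charge",
  "class_labels": [
    "positive",
    "neutral",
    "negative"
  ],
  "classes": {
    "1": "KR",
    "2": "ACFGHILMNPQSTVWY",
    "3": "DE"
  }
}
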