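{
 "overrides": [
  {
   "code": "P26",
   "primary": "X6",
   "score": "67/100",
   "note": "printed per-dimension value not representable as k/5; stored verbatim from the source table"
  }
 ]
}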