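{
 "reference_id": "at_reference_synthetic",
 "provenance": "synthetic stand-in: 24 active-site columns chosen deterministically for the packaged synthetic reference; real analyses should supply a structurally derived profile",
 "columns": [
  31,
  53,
  61,
  79,
  99,
  110,
  113,
  115,
  116,
  129,
  137,
  147,
  160,
  163,
  165,
  175,
  182,
  187,
  217,
  226,
  251,
  254,
  255,
  266
 ]
}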