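{
 "description": "Required catalytic-residue patterns (Python regular expressions) per reductive domain kind. A domain whose sequence lacks its pattern is flagged inactive. KR: Rossmann NADPH-binding glycine-rich motif; DH: HxxxGxxxxP active-site histidine motif; ER: NADPH-binding motif. Editable; absence of a pattern for a kind leaves the domain active.",
 "motifs": {
  "KR": "G.G..G",
  "DH": "H...G....P",
  "ER": "GGVG"
 }
}
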