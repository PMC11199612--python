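{
 "description": "Extender building blocks keyed by AT substrate label. Each block is the two-carbon unit in its unreduced (beta-keto) form written as a free aldehyde-like fragment; alpha_atom_index marks the alpha carbon (carries the branch), carbonyl_atom_index marks the thioester-carbonyl carbon whose oxidation state the module's KR/DH/ER domains set.",
 "monomers": {
  "mal": {"smiles": "O=CC", "carbonyl_atom_index": 1, "alpha_atom_index": 2},
  "mmal": {"smiles": "O=CC(C)", "carbonyl_atom_index": 1, "alpha_atom_index": 2},
  "emal": {"smiles": "O=CC(CC)", "carbonyl_atom_index": 1, "alpha_atom_index": 2},
  "mxmal": {"smiles": "O=CC(OC)", "carbonyl_atom_index": 1, "alpha_atom_index": 2}
 }
}
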