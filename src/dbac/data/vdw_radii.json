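{
  "comment": "Element-keyed van der Waals radii in Angstrom (Chothia-style, NACCESS lineage). 'OW' is the water oxygen.",
  "radii": {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "OW": 1.40
  }
}
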