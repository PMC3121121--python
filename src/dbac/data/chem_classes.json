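{
  "comment": "Atom chemistry classes for contact typing. Keys are 3-letter residue names mapping to lists of PDB atom names; '*' applies to every amino-acid residue (backbone atoms). 'donor_exceptions' removes donors chemically unable to donate (proline backbone N carries no hydrogen). Water oxygen is handled separately in code (both donor and acceptor). Edit this file to swap in an alternative classification without code changes.",
  "positive": {
    "ARG": ["NH1", "NH2", "NE"],
    "LYS": ["NZ"],
    "HIS": ["ND1", "NE2"]
  },
  "negative": {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "*": ["OXT"]
  },
  "donor": {
    "*": ["N"],
    "ARG": ["NE", "NH1", "NH2"],
    "LYS": ["NZ"],
    "HIS": ["ND1", "NE2"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "TRP": ["NE1"],
    "ASN": ["ND2"],
    "GLN": ["NE2"],
    "CYS": ["SG"]
  },
  "donor_exceptions": {
    "PRO": ["N"]
  },
  "acceptor": {
    "*": ["O", "OXT"],
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "ASN": ["OD1"],
    "GLN": ["OE1"],
    "HIS": ["ND1", "NE2"],
    "MET": ["SD"]
  }
}
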