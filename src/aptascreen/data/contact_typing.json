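{
  "_comment": [
    "Hydrogen-bond donor/acceptor and apolar-carbon typing tables for heavy-atom",
    "contact detection between protein and RNA chains (Ligplot/Nucplot-style",
    "conventions). Donors/acceptors are N/O/S atoms that can carry or receive a",
    "proton; apolar carbons are carbons with no bonded N or O (for nucleotides,",
    "sugar CH/CH2 carbons other than C1' are kept, by convention, despite their",
    "ether/hydroxyl oxygen neighbours). Editable: detection reads these tables."
  ],
  "protein": {
    "backbone_donors": ["N"],
    "backbone_acceptors": ["O", "OXT"],
    "sidechain_donors": {
      "ARG": ["NE", "NH1", "NH2"],
      "ASN": ["ND2"],
      "GLN": ["NE2"],
      "HIS": ["ND1", "NE2"],
      "LYS": ["NZ"],
      "SER": ["OG"],
      "THR": ["OG1"],
      "TRP": ["NE1"],
      "TYR": ["OH"],
      "CYS": ["SG"]
    },
    "sidechain_acceptors": {
      "ASP": ["OD1", "OD2"],
      "GLU": ["OE1", "OE2"],
      "ASN": ["OD1"],
      "GLN": ["OE1"],
      "HIS": ["ND1", "NE2"],
      "SER": ["OG"],
      "THR": ["OG1"],
      "TYR": ["OH"],
      "MET": ["SD"]
    },
    "apolar_carbons": {
      "ALA": ["CB"],
      "ARG": ["CB", "CG"],
      "ASN": ["CB"],
      "ASP": ["CB"],
      "CYS": ["CB"],
      "GLN": ["CB", "CG"],
      "GLU": ["CB", "CG"],
      "HIS": ["CB"],
      "ILE": ["CB", "CG1", "CG2", "CD1"],
      "LEU": ["CB", "CG", "CD1", "CD2"],
      "LYS": ["CB", "CG", "CD"],
      "MET": ["CB", "CG", "CE"],
      "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
      "PRO": ["CB", "CG"],
      "THR": ["CG2"],
      "TRP": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
      "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
      "VAL": ["CB", "CG1", "CG2"]
    }
  },
  "nucleotide": {
    "donors": {
      "A": ["N6", "O2'"],
      "G": ["N1", "N2", "O2'"],
      "C": ["N4", "O2'"],
      "U": ["N3", "O2'"]
    },
    "acceptors": {
      "A": ["N1", "N3", "N7", "O2'", "O3'", "O4'", "O5'", "OP1", "OP2"],
      "G": ["N3", "N7", "O6", "O2'", "O3'", "O4'", "O5'", "OP1", "OP2"],
      "C": ["O2", "N3", "O2'", "O3'", "O4'", "O5'", "OP1", "OP2"],
      "U": ["O2", "O4", "O2'", "O3'", "O4'", "O5'", "OP1", "OP2"]
    },
    "apolar_carbons": {
      "A": ["C2'", "C3'", "C4'", "C5'", "C2", "C8"],
      "G": ["C2'", "C3'", "C4'", "C5'", "C8"],
      "C": ["C2'", "C3'", "C4'", "C5'", "C5"],
      "U": ["C2'", "C3'", "C4'", "C5'", "C5"]
    }
  }
}
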