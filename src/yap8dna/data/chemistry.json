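{
  "comment": "Geometric interaction chemistry for protein and B-DNA residues. Side-chain and base atoms only; backbone donors/acceptors and the phosphate charge are added programmatically for every residue of the matching kind. Edit and load with ChemistryTables.from_json to change the chemistry.",
  "donors": {
    "ARG": [["NE", ["HE"]], ["NH1", ["HH11", "HH12"]], ["NH2", ["HH21", "HH22"]]],
    "LYS": [["NZ", ["HZ1", "HZ2", "HZ3"]]],
    "ASN": [["ND2", ["HD21", "HD22"]]],
    "GLN": [["NE2", ["HE21", "HE22"]]],
    "HIS": [["ND1", ["HD1"]], ["NE2", ["HE2"]]],
    "SER": [["OG", ["HG"]]],
    "THR": [["OG1", ["HG1"]]],
    "TYR": [["OH", ["HH"]]],
    "TRP": [["NE1", ["HE1"]]],
    "CYS": [["SG", ["HG"]]],
    "DA": [["N6", ["H61", "H62"]]],
    "DC": [["N4", ["H41", "H42"]]],
    "DG": [["N1", ["H1"]], ["N2", ["H21", "H22"]]],
    "DT": [["N3", ["H3"]]]
  },
  "acceptors": {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"],
    "GLN": ["OE1"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "HIS": ["ND1", "NE2"],
    "MET": ["SD"],
    "DA": ["N1", "N3", "N7"],
    "DG": ["O6", "N3", "N7"],
    "DC": ["O2", "N3"],
    "DT": ["O2", "O4"]
  },
  "charged": {
    "ARG": {"sign": 1, "atoms": ["NE", "NH1", "NH2"]},
    "LYS": {"sign": 1, "atoms": ["NZ"]},
    "ASP": {"sign": -1, "atoms": ["OD1", "OD2"]},
    "GLU": {"sign": -1, "atoms": ["OE1", "OE2"]}
  },
  "hydrophobic": {
    "ALA": ["CB"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "PRO": ["CB", "CG", "CD"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "DA": ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"],
    "DG": ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"],
    "DT": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"],
    "DC": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"]
  }
}
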