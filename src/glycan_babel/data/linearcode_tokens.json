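{
  "comment": "LinearCode residue letters (longest codes matched first). Curated for the common glycomics alphabet.",
  "residues": {
    "GN": "GlcNAc",
    "AN": "GalNAc",
    "MN": "ManNAc",
    "NN": "Neu5Ac",
    "NJ": "Neu5Gc",
    "A": "Gal",
    "G": "Glc",
    "M": "Man",
    "F": "Fuc",
    "X": "Xyl",
    "U": "GlcA",
    "H": "Rha",
    "K": "Kdn",
    "B": "Rib",
    "R": "Ara",
    "I": "IdoA",
    "L": "GalA"
  }
}
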