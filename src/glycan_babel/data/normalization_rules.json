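{
  "comment": "Token-stage rewrite table. 'synonyms' are applied with token boundaries; 'characters' are unconditional character substitutions. Extending dialect coverage is a data change, not a code change.",
  "characters": {
    "α": "a",
    "β": "b",
    "Α": "a",
    "Β": "b",
    "→": "-",
    "⟶": "-",
    "–": "-",
    "—": "-",
    "−": "-",
    " ": " "
  },
  "synonyms": {
    "NeuAc": "Neu5Ac",
    "NeuNAc": "Neu5Ac",
    "Neu5NAc": "Neu5Ac",
    "NANA": "Neu5Ac",
    "NeuGc": "Neu5Gc",
    "NeuNGc": "Neu5Gc",
    "NGNA": "Neu5Gc",
    "KDN": "Kdn",
    "KDO": "Kdo",
    "GlcUA": "GlcA",
    "GalUA": "GalA",
    "IdoUA": "IdoA",
    "GlcNac": "GlcNAc",
    "GalNac": "GalNAc",
    "ManNac": "ManNAc",
    "Glucose": "Glc",
    "Galactose": "Gal",
    "Mannose": "Man",
    "Fucose": "Fuc",
    "Xylose": "Xyl",
    "Rhamnose": "Rha",
    "Sulfo": "S",
    "Sulf": "S",
    "Phospho": "P"
  }
}
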