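{
  "comment": "Curated mapping of common WURCS 2.0 residue descriptors. 'skeletons' maps the backbone code (anomer-agnostic) to a base token; 'substituents' maps MAP-string substituent codes to modification tags. NAc/N/NGc at C2 fuse into the residue name (GlcNAc, GlcN, ...); NAc/NGc at C5 of the sialic skeleton select Neu5Ac/Neu5Gc.",
  "skeletons": {
    "a2122h": "Glc",
    "a2112h": "Gal",
    "a1122h": "Man",
    "a2222h": "All",
    "a2212h": "Tal",
    "a1221m": "Fuc",
    "a2211m": "Rha",
    "a1222m": "Qui",
    "a212h": "Xyl",
    "a222h": "Rib",
    "a122h": "Lyx",
    "a211h": "Ara",
    "a2122A": "GlcA",
    "a2112A": "GalA",
    "a1122A": "ManA",
    "a2121A": "IdoA",
    "Aad21122h": "Neu",
    "Aad1122h": "Kdo",
    "axxxxh": "Hex",
    "uxxxxh": "Hex"
  },
  "substituents": {
    "NCC/3=O": "NAc",
    "NCCO/3=O": "NGc",
    "N": "N",
    "OCC/3=O": "Ac",
    "OSO/3=O/3=O": "S",
    "OPO/3O/3=O": "P",
    "OC": "Me"
  }
}
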