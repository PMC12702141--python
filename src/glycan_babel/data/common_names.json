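{
  "comment": "Common/trivial glycan names. Lookup ignores capitalization and spaces; values are IUPAC-condensed (canonicalized downstream, so conventional branch order is fine here).",
  "names": {
    "LacNAc": "Gal(b1-4)GlcNAc",
    "LacdiNAc": "GalNAc(b1-4)GlcNAc",
    "Lactose": "Gal(b1-4)Glc",
    "Lac": "Gal(b1-4)Glc",
    "Chitobiose": "GlcNAc(b1-4)GlcNAc",
    "Chitotriose": "GlcNAc(b1-4)GlcNAc(b1-4)GlcNAc",
    "Maltose": "Glc(a1-4)Glc",
    "Maltotriose": "Glc(a1-4)Glc(a1-4)Glc",
    "Cellobiose": "Glc(b1-4)Glc",
    "Isomaltose": "Glc(a1-6)Glc",
    "LewisA": "Gal(b1-3)[Fuc(a1-4)]GlcNAc",
    "LeA": "Gal(b1-3)[Fuc(a1-4)]GlcNAc",
    "LewisX": "Gal(b1-4)[Fuc(a1-3)]GlcNAc",
    "LeX": "Gal(b1-4)[Fuc(a1-3)]GlcNAc",
    "LewisB": "Fuc(a1-2)Gal(b1-3)[Fuc(a1-4)]GlcNAc",
    "LeB": "Fuc(a1-2)Gal(b1-3)[Fuc(a1-4)]GlcNAc",
    "LewisY": "Fuc(a1-2)Gal(b1-4)[Fuc(a1-3)]GlcNAc",
    "LeY": "Fuc(a1-2)Gal(b1-4)[Fuc(a1-3)]GlcNAc",
    "SialylLewisX": "Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc",
    "sLeX": "Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc",
    "SialylLewisA": "Neu5Ac(a2-3)Gal(b1-3)[Fuc(a1-4)]GlcNAc",
    "sLeA": "Neu5Ac(a2-3)Gal(b1-3)[Fuc(a1-4)]GlcNAc",
    "2'-FL": "Fuc(a1-2)Gal(b1-4)Glc",
    "2'-Fucosyllactose": "Fuc(a1-2)Gal(b1-4)Glc",
    "3-FL": "Gal(b1-4)[Fuc(a1-3)]Glc",
    "3-Fucosyllactose": "Gal(b1-4)[Fuc(a1-3)]Glc",
    "3'-SL": "Neu5Ac(a2-3)Gal(b1-4)Glc",
    "3'-Sialyllactose": "Neu5Ac(a2-3)Gal(b1-4)Glc",
    "6'-SL": "Neu5Ac(a2-6)Gal(b1-4)Glc",
    "6'-Sialyllactose": "Neu5Ac(a2-6)Gal(b1-4)Glc",
    "LNT": "Gal(b1-3)GlcNAc(b1-3)Gal(b1-4)Glc",
    "LNnT": "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc",
    "LNFPI": "Fuc(a1-2)Gal(b1-3)GlcNAc(b1-3)Gal(b1-4)Glc",
    "LNFPII": "Gal(b1-3)[Fuc(a1-4)]GlcNAc(b1-3)Gal(b1-4)Glc",
    "LNFPIII": "Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-3)Gal(b1-4)Glc",
    "GM3": "Neu5Ac(a2-3)Gal(b1-4)Glc",
    "GM2": "GalNAc(b1-4)[Neu5Ac(a2-3)]Gal(b1-4)Glc",
    "GM1": "Gal(b1-3)GalNAc(b1-4)[Neu5Ac(a2-3)]Gal(b1-4)Glc",
    "GD3": "Neu5Ac(a2-8)Neu5Ac(a2-3)Gal(b1-4)Glc",
    "GD1a": "Neu5Ac(a2-3)Gal(b1-3)GalNAc(b1-4)[Neu5Ac(a2-3)]Gal(b1-4)Glc",
    "GD1b": "Gal(b1-3)GalNAc(b1-4)[Neu5Ac(a2-8)Neu5Ac(a2-3)]Gal(b1-4)Glc",
    "GA1": "Gal(b1-3)GalNAc(b1-4)Gal(b1-4)Glc",
    "Tantigen": "Gal(b1-3)GalNAc",
    "TFantigen": "Gal(b1-3)GalNAc",
    "Tnantigen": "GalNAc",
    "SialylTn": "Neu5Ac(a2-6)GalNAc",
    "STn": "Neu5Ac(a2-6)GalNAc",
    "Globotriose": "Gal(a1-4)Gal(b1-4)Glc",
    "Gb3": "Gal(a1-4)Gal(b1-4)Glc",
    "Globoside": "GalNAc(b1-3)Gal(a1-4)Gal(b1-4)Glc",
    "Gb4": "GalNAc(b1-3)Gal(a1-4)Gal(b1-4)Glc",
    "Isoglobotriose": "Gal(a1-3)Gal(b1-4)Glc",
    "BloodGroupA": "GalNAc(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc",
    "BloodGroupB": "Gal(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc",
    "BloodGroupH": "Fuc(a1-2)Gal(b1-4)GlcNAc",
    "HAntigen": "Fuc(a1-2)Gal(b1-4)GlcNAc"
  }
}
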