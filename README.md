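# glycan-babel

Universal glycan input: take a glycan string in **any** common nomenclature —
without declaring which one — and convert it to a single, canonicalized
IUPAC-condensed representation.

Supported inputs:

| family | examples |
| --- | --- |
| IUPAC-condensed dialects | `Gal(b1-4)Glc`, `Galb1-4Glc`, `Galb4Glc`, `Galβ1-4Glc`, CarbBank-style `D-Glcp` |
| CSDB-linear style | `bDGalp(1-4)bDGlcp` |
| WURCS 2.0 | `WURCS=2.0/2,2,1/[a2122h-1x_1-5][a2112h-1b_1-5]/1-2/a4-b1` |
| GlycoCT (condensed) | multi-line `RES`/`LIN` blocks |
| LinearCode | `Ab4GN;` |
| GLYCAM | `DGalpb1-4DGlcpb1-OH` |
| Oxford N-glycan codes | `M3`, `FA2G2S2` |
| KCF (KEGG) | multi-line `NODE`/`EDGE` blocks |
| IUPAC-extended | `β-D-Galp-(1→4)-D-Glcp` |
| GlycoWorkbench | `freeEnd--?b1D-GlcNAc,p--4b1D-GlcNAc,p...` |
| common names | `LacNAc`, `2'-FL`, `GM1` (case/space-insensitive) |
| compositions | `H5N4F1A2`, `Hex5HexNAc4Fuc1Neu5Ac2`, `(Hex)3 (HexNAc)1 (NeuAc)1 + (Man)3(GlcNAc)2` |

The pipeline is: nomenclature detection via string hooks → a rudimentary
per-format parser (emitting anything resembling IUPAC-condensed) → a common
stem that homogenizes tokens, linkages, brackets, modifications and floating
substituents and repairs chemically impossible linkage assignments → a
deterministic branch-ordering step that yields exactly one string per
molecule (longest chain continues the main chain; ties break on lower
linkage numbers, integers before wildcards, then alphabetically).

## Python API

```python
from glycan_babel import canonicalize_any, rescue_glycans

canonicalize_any("Galb4Glc")                 # 'Gal(b1-4)Glc'
canonicalize_any("Ab4GN;")                   # 'Gal(b1-4)GlcNAc'
canonicalize_any("H5N4F1A2")                 # 'Hex5HexNAc4dHex1Neu5Ac2'

@rescue_glycans                               # any function gains universal input
def analyze(glycan):
    return glycan

analyze("DGalpb1-4DGlcpb1-OH")               # 'Gal(b1-4)Glc'
```

Lower-level pieces (`parse_iupac_to_tree`, `tree_to_string`,
`canonicalize_branches`, `common_stem`, `parse_composition`,
`generate_dialect_variants`, the per-format parsers) are all exported.

## CLI

```bash
# one record per line; GlycoCT/KCF blocks are blank-line separated
glycan-babel convert glycans.txt            # TSV: input, detected, canonical, status, message
echo "Galb4Glc" | glycan-babel convert --out plain
glycan-babel convert --format glycoct blocks.txt
glycan-babel convert --compositions comps.txt

# seeded dialect-variant generation (test fixtures)
glycan-babel fixtures generate "Gal(b1-4)Glc" --seed 1 --n 5
```

Exit code is 0 when every record converts, 1 otherwise; errors are reported
per record and never abort a batch.

## Repository layout

- `src/glycan_babel/model.py` — glycan tree model, residue namespace, IUPAC parsing/serialization
- `src/glycan_babel/detection.py` — hooks, common-name dictionary, rejection of unsupported languages
- `src/glycan_babel/parsers.py` — WURCS/GlycoCT/LinearCode/GLYCAM/Oxford/KCF/IUPAC-extended/GWS parsers
- `src/glycan_babel/stem.py` — the common stem (dialect normalization + feasibility repair)
- `src/glycan_babel/canonicalize.py` — deterministic branch ordering
- `src/glycan_babel/composition.py` — composition parsing/canonicalization
- `src/glycan_babel/pipeline.py` — `canonicalize_any`, rescue decorators, variant generator
- `src/glycan_babel/fixtures.py` — corpus of canonical glycans + per-nomenclature encoders
- `src/glycan_babel/data/*.json` — token synonym, common-name, WURCS and LinearCode tables
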