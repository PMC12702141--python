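import pytest

from glycan_babel.errors import (
    GlycanParseError,
    StructureError,
    UnsupportedTokenError,
)
from glycan_babel.parsers import (
    ResidueLinkTable,
    _wurcs_token,
    parse_glycam,
    parse_glycoct,
    parse_gws,
    parse_iupac_extended,
    parse_kcf,
    parse_linearcode,
    parse_oxford,
    parse_wurcs,
)
from glycan_babel.pipeline import canonicalize_any
from glycan_babel.stem import common_stem


def canon(raw: str) -> str:
    """Finish a parser's raw output the way the pipeline would."""
    return canonicalize_any(common_stem(raw))


class TestResidueLinkTable:
    def test_dangling_link(self):
        t = ResidueLinkTable({0: "Glc"}, [(1, "b", "1", 0, "4")])
        with pytest.raises(StructureError):
            t.serialize()

    def test_multiple_parents(self):
        t = ResidueLinkTable(
            {0: "Glc", 1: "Gal", 2: "Man"},
            [(1, "b", "1", 0, "4"), (1, "b", "1", 2, "3")],
        )
        with pytest.raises(StructureError):
            t.serialize()

    def test_disconnected(self):
        t = ResidueLinkTable({0: "Glc", 1: "Gal"}, [])
        with pytest.raises(StructureError):
            t.serialize()


class TestWurcs:
    def test_lactose(self):
        raw = parse_wurcs(
            "WURCS=2.0/2,2,1/[a2122h-1x_1-5][a2112h-1b_1-5]/1-2/a4-b1"
        )
        assert canon(raw) == "Gal(b1-4)Glc"

    def test_single_residue(self):
        assert canon(parse_wurcs("WURCS=2.0/1,1,0/[a2122h-1x_1-5]/1/")) == "Glc"

    def test_nacetyl_descriptor(self):
        token, anomer, apos = _wurcs_token("a2122h-1b_1-5_2*NCC/3=O")
        assert token == "GlcNAc"
        assert (anomer, apos) == ("b", "1")

    def test_sialic_descriptor(self):
        token, anomer, apos = _wurcs_token("Aad21122h-2a_2-6_5*NCC/3=O")
        assert token == "Neu5Ac"
        assert (anomer, apos) == ("a", "2")

    def test_unknown_descriptor_carries_token(self):
        bad = "zzz9h-1b_1-5"
        with pytest.raises(UnsupportedTokenError, match="zzz9h"):
            parse_wurcs(f"WURCS=2.0/1,1,0/[{bad}]/1/")


class TestGlycoct:
    def test_lactose(self):
        raw = parse_glycoct(
            "RES\n1b:b-dglc-HEX-1:5\n2b:b-dgal-HEX-1:5\nLIN\n1:1o(4+1)2d"
        )
        assert canon(raw) == "Gal(b1-4)Glc"

    def test_single_residue(self):
        assert canon(parse_glycoct("RES\n1b:b-dglc-HEX-1:5")) == "Glc"

    def test_sulfate_substituent(self):
        raw = parse_glycoct(
            "RES\n1b:b-dgal-HEX-1:5\n2s:sulfate\nLIN\n1:1o(6+1)2n"
        )
        assert canon(raw) == "Gal6S"

    def test_dangling_lin_reference(self):
        with pytest.raises((StructureError, GlycanParseError)):
            parse_glycoct("RES\n1b:b-dglc-HEX-1:5\nLIN\n1:1o(4+1)9d")


class TestLinearCode:
    def test_lacnac(self):
        assert canon(parse_linearcode("Ab4GN;")) == "Gal(b1-4)GlcNAc"

    def test_single(self):
        assert canon(parse_linearcode("M")) == "Man"

    def test_sialic_donor_carbon(self):
        assert canon(parse_linearcode("NNa3Ab4GN")) == "Neu5Ac(a2-3)Gal(b1-4)GlcNAc"

    def test_branches(self):
        assert (
            canon(parse_linearcode("Ma3(Ma6)Mb4GNb4GN;"))
            == "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"
        )

    def test_unknown_letter(self):
        with pytest.raises(UnsupportedTokenError):
            parse_linearcode("Qb4GN")


class TestGlycam:
    def test_lactose(self):
        assert canon(parse_glycam("DGalpb1-4DGlcpb1-OH")) == "Gal(b1-4)Glc"

    def test_single(self):
        assert canon(parse_glycam("DGlcpb1-OH")) == "Glc"

    def test_branches_pass_through(self):
        assert (
            canon(parse_glycam("DManpa1-3[DManpa1-6]DManpb1-OH"))
            == "Man(a1-3)[Man(a1-6)]Man"
        )

    def test_nondefault_enantiomer_kept(self):
        assert canon(parse_glycam("LGalpb1-4DGlcpb1-OH")) == "L-Gal(b1-4)Glc"

    def test_ome_terminus_annotated(self):
        assert canon(parse_glycam("DGlcpb1-OME")) == "Glc1Me"

    def test_missing_terminus(self):
        with pytest.raises(GlycanParseError):
            parse_glycam("DGalpb1-4DGlcpb1")


class TestOxford:
    def test_bare_core(self):
        assert (
            canon(parse_oxford("M3"))
            == "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"
        )

    def test_fa2(self):
        assert canon(parse_oxford("FA2")) == (
            "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]"
            "Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc"
        )

    def test_fa2g2s2(self):
        out = canon(parse_oxford("FA2G2S2"))
        assert out.count("Neu5Ac(a2-?)") == 2
        assert "[Fuc(a1-6)]GlcNAc" in out

    def test_unknown_token(self):
        with pytest.raises(UnsupportedTokenError):
            parse_oxford("FA2Z9")

    def test_oxford_cases_table(self):
        from glycan_babel.fixtures import OXFORD_CASES

        for code, expected in OXFORD_CASES:
            assert canon(parse_oxford(code)) == expected, code


class TestKcf:
    def test_two_nodes(self):
        kcf = (
            "ENTRY     G00001   Glycan\n"
            "NODE      2\n"
            "            1   Glc   0   0\n"
            "            2   Gal   -10   0\n"
            "EDGE      1\n"
            "            1   2:b1   1:4\n"
            "///"
        )
        assert canon(parse_kcf(kcf)) == "Gal(b1-4)Glc"

    def test_single_node(self):
        kcf = "NODE 1\n  1 Man 0 0\nEDGE 0\n///"
        assert canon(parse_kcf(kcf)) == "Man"

    def test_branched_core(self):
        kcf = (
            "NODE 5\n"
            "  1 GlcNAc 0 0\n"
            "  2 GlcNAc -10 0\n"
            "  3 Man -20 0\n"
            "  4 Man -30 5\n"
            "  5 Man -30 -5\n"
            "EDGE 4\n"
            "  1 2:b1 1:4\n"
            "  2 3:b1 2:4\n"
            "  3 4:a1 3:3\n"
            "  4 5:a1 3:6\n"
            "///"
        )
        assert canon(parse_kcf(kcf)) == (
            "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"
        )

    def test_disconnected_nodes(self):
        kcf = "NODE 2\n  1 Glc 0 0\n  2 Gal -10 0\nEDGE 0\n///"
        with pytest.raises(StructureError):
            parse_kcf(kcf)


class TestIupacExtended:
    def test_lactose(self):
        assert canon(parse_iupac_extended("β-D-Galp-(1→4)-D-Glcp")) == "Gal(b1-4)Glc"

    def test_single(self):
        assert canon(parse_iupac_extended("D-Glcp")) == "Glc"

    def test_l_default_stripping(self):
        assert (
            canon(parse_iupac_extended("α-L-Fucp-(1→2)-β-D-Galp-(1→4)-D-Glcp"))
            == "Fuc(a1-2)Gal(b1-4)Glc"
        )


class TestGws:
    def test_chitobiose(self):
        assert (
            canon(parse_gws("freeEnd--?b1D-GlcNAc,p--4b1D-GlcNAc,p"))
            == "GlcNAc(b1-4)GlcNAc"
        )

    def test_single(self):
        assert canon(parse_gws("freeEnd--?b1D-Glc,p")) == "Glc"

    def test_branched_core(self):
        gws = (
            "freeEnd--?b1D-GlcNAc,p--4b1D-GlcNAc,p--4b1D-Man,p"
            "((--3a1D-Man,p)--6a1D-Man,p)$MONO,Und,-H,0,redEnd"
        )
        assert canon(parse_gws(gws)) == (
            "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"
        )

    def test_malformed_segment(self):
        with pytest.raises(GlycanParseError):
            parse_gws("freeEnd--?b1D-GlcNAc")


class TestParserContracts:
    def test_outputs_survive_common_stem(self, corpus):
        # every non-IUPAC variant in the corpus must pass the stem without error
        from glycan_babel.pipeline import _PARSERS

        for case in corpus:
            for variant, kind in case.variants:
                if kind in _PARSERS:
                    raw = _PARSERS[kind](variant)
                    common_stem(raw)  # must not raise

    def test_unsupported_token_errors_carry_token(self):
        with pytest.raises(UnsupportedTokenError) as exc:
            parse_linearcode("Zb4GN")
        assert "Z" in str(exc.value)
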