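"""Vector naming system and the level/Pro/Del/Int assembly planners."""

import pytest

from yalicraft.grammar import (
    AssemblyError,
    JunctionMismatchError,
    NameParseError,
    VectorName,
    assemble_del,
    assemble_lvl1,
    assemble_lvl2,
    assemble_pro,
    dropout_check,
    enumerate_empty_vectors,
    exchange_has,
    format_name,
    parse_name,
    transfer_to_del,
)
from yalicraft.fixtures import make_ha_amplicon, make_promoter_amplicon
from yalicraft.model import canonical_key, molecules_equal
from yalicraft.typeiis import golden_gate

from oracles import aari_sections, lvl1_concatenation_oracle


class TestNaming:
    def test_parse_standard_name(self):
        name = parse_name("pE8US1.1")
        assert name.chromosome == "E"
        assert name.locus_number == 8
        assert name.yeast_marker == "U"        # URA3
        assert name.bacterial_resistance == "S"  # spectinomycin
        assert (name.level, name.sublevel) == (1, 1)

    def test_parse_zeta_name(self):
        name = parse_name("pZUA2.3")
        assert name.chromosome == "Z"
        assert name.locus_number is None
        assert name.yeast_marker == "U"
        assert name.bacterial_resistance == "A"  # ampicillin
        assert (name.level, name.sublevel) == (2, 3)

    def test_suffix_carried(self):
        name = parse_name("pZUA2.3-HPD1-ARO4-ARO7")
        assert name.suffix == "HPD1-ARO4-ARO7"
        assert format_name(name) == "pZUA2.3-HPD1-ARO4-ARO7"

    def test_round_trip_on_generated_names(self):
        loci = [f"Int{c}{i}" for c in "ABCDEF" for i in (1, 2, 3)]
        names = enumerate_empty_vectors(loci[:16] + ["Zeta"],
                                        marker="U", resistance="S")
        assert len(names) == 5 * 17
        names += enumerate_empty_vectors(["Zeta"], marker="L", resistance="K")
        for name in names:
            assert parse_name(format_name(name)) == name

    @pytest.mark.parametrize("bad, field", [
        ("pE8US2.1", "sublevel"),      # Lvl2 has no sublevel 1
        ("pE8US1.4", "sublevel"),
        ("pE8US3.1", "level"),
        ("pG8US1.1", "chromosome"),    # chromosomes run A-F (or Z)
        ("pZ3UA1.1", "locus"),         # Zeta vectors carry no locus number
        ("pEUS1.1", "locus"),          # non-Zeta needs a locus number
        ("E8US1.1", "name"),
        ("pE8US11", "name"),
    ])
    def test_malformed_names_name_the_failing_field(self, bad, field):
        with pytest.raises(NameParseError) as err:
            parse_name(bad)
        assert field.lower() in str(err.value).lower()

    def test_enumerate_counts(self):
        sixteen = [f"Int{c}{i}" for c in "ABCD" for i in (1, 2, 3, 4)]
        assert len(enumerate_empty_vectors(sixteen)) == 80
        assert len(enumerate_empty_vectors(["IntE8"])) == 5
        assert enumerate_empty_vectors([]) == []


class TestLvl1Assembly:
    def test_product_matches_concatenation_oracle(self, toolkit, cfg,
                                                  lvl1_hrgfp):
        expected = lvl1_concatenation_oracle(
            toolkit["pA1US1.1"].seq, toolkit["pL0-TEF1"].seq,
            toolkit["pL0-hrGFP"].seq, toolkit["pL0-Tsyn1"].seq)
        assert canonical_key(lvl1_hrgfp) == expected

    def test_product_structure(self, toolkit, cfg, lvl1_hrgfp):
        assert lvl1_hrgfp.id == "pA1US1.1-hrGFP"
        assert dropout_check(lvl1_hrgfp, cfg)
        labels = {f.label for f in lvl1_hrgfp.features}
        assert {"TEF1", "hrGFP", "Tsyn1", "URA3", "spectinomycin",
                "IntA1_up", "IntA1_dn", "lox66", "lox71"} <= labels
        assert "sfGFP" not in labels

    def test_junction_mismatch_is_an_error(self, toolkit, cfg):
        with pytest.raises(JunctionMismatchError):
            assemble_lvl1(toolkit["pA1US1.1"], toolkit.entry("hrGFP"),
                          toolkit.entry("TEF1"), toolkit.entry("Tsyn1"), cfg)

    def test_all_sublevels_assemble(self, toolkit, cfg):
        for sub in (1, 2, 3):
            product = assemble_lvl1(
                toolkit[f"pB1US1.{sub}"], toolkit.entry("TEF1"),
                toolkit.entry("ARO4"), toolkit.entry("Tsyn1"), cfg)
            assert product.id == f"pB1US1.{sub}-ARO4"


class TestLvl2Assembly:
    def test_three_tu_product(self, lvl2_zeta):
        assert lvl2_zeta.id == "pZUA2.3-HPD1-ARO4-ARO7"
        starts = {}
        for f in lvl2_zeta.features:
            if f.label in ("HPD1", "ARO4", "ARO7"):
                starts[f.label] = f.interval.start
        assert len(starts) == 3

    def test_order_independent_of_donor_input_order(self, toolkit, cfg,
                                                    lvl2_zeta):
        donors = [
            assemble_lvl1(toolkit["pZUA1.1"], toolkit.entry("TEF1"),
                          toolkit.entry("HPD1"), toolkit.entry("Tsyn1"), cfg),
            assemble_lvl1(toolkit["pZUA1.2"], toolkit.entry("ALK1"),
                          toolkit.entry("ARO4"), toolkit.entry("Tsyn2"), cfg),
            assemble_lvl1(toolkit["pZUA1.3"], toolkit.entry("RPL25"),
                          toolkit.entry("ARO7"), toolkit.entry("Tsyn1"), cfg),
        ]
        shuffled = assemble_lvl2(toolkit["pZUA2.3"],
                                 [donors[2], donors[0], donors[1]], cfg)
        assert molecules_equal(shuffled, lvl2_zeta)

    def test_two_tu_product(self, toolkit, cfg):
        donors = [
            assemble_lvl1(toolkit["pC1US1.1"], toolkit.entry("TEF1"),
                          toolkit.entry("hrGFP"), toolkit.entry("Tsyn1"), cfg),
            assemble_lvl1(toolkit["pC1US1.2"], toolkit.entry("ALK1"),
                          toolkit.entry("ARO4"), toolkit.entry("Tsyn2"), cfg),
        ]
        product = assemble_lvl2(toolkit["pC2US2.2"], donors, cfg)
        assert product.id == "pC2US2.2-hrGFP-ARO4"

    def test_duplicate_position_rejected_before_digestion(self, toolkit, cfg):
        donor1 = assemble_lvl1(toolkit["pC1US1.1"], toolkit.entry("TEF1"),
                               toolkit.entry("hrGFP"), toolkit.entry("Tsyn1"),
                               cfg)
        with pytest.raises(AssemblyError, match="duplicate or missing"):
            assemble_lvl2(toolkit["pC2US2.2"], [donor1, donor1], cfg)

    def test_wrong_donor_count_rejected(self, toolkit, cfg):
        donor1 = assemble_lvl1(toolkit["pC1US1.1"], toolkit.entry("TEF1"),
                               toolkit.entry("hrGFP"), toolkit.entry("Tsyn1"),
                               cfg)
        with pytest.raises(AssemblyError, match="takes 3 TUs"):
            assemble_lvl2(toolkit["pZUA2.3"], [donor1], cfg)


class TestProAssembly:
    def test_promoter_sits_upstream_of_hrgfp(self, toolkit, cfg):
        product = assemble_pro(toolkit["pProUA-mScarlet"],
                               make_promoter_amplicon(toolkit, "ALK1"), cfg)
        assert product.id == "pProUA-ALK1"
        labels = {f.label for f in product.features}
        assert "mScarlet" not in labels and "hrGFP" in labels

    def test_no_insert_religation_rejected(self, toolkit, cfg):
        # without an insert the only circles retain the RFP dropout
        report = golden_gate([toolkit["pProUA-mScarlet"]], cfg.entry_enzyme)
        assert report.stable == []

    def test_product_matches_string_oracle(self, toolkit, cfg):
        from oracles import acceptor_backbone_slice
        amplicon = make_promoter_amplicon(toolkit, "TEF1")
        product = assemble_pro(toolkit["pProUA-mScarlet"], amplicon, cfg)
        backbone = acceptor_backbone_slice(toolkit["pProUA-mScarlet"].seq)
        # insert slice between the amplicon's two hand-computed cut windows
        p = amplicon.seq.find("GGTCTC") + 6 + 1
        q = amplicon.seq.rfind("GAGACC") - 1 - 4
        insert = amplicon.seq[p:q + 4]
        expected = canonical_key(backbone[:-4] + insert[:-4])
        assert canonical_key(product) == expected


class TestDelAssembly:
    def test_product_carries_arms_and_marker(self, toolkit, cfg):
        product = assemble_del(toolkit["pDelUK-RG"],
                               make_ha_amplicon(toolkit, "AAT1", "up"),
                               make_ha_amplicon(toolkit, "AAT1", "down"), cfg)
        assert product.id == "pDelUK-AAT1"
        labels = {f.label for f in product.features}
        assert {"AAT1_up", "AAT1_dn", "URA3"} <= labels
        assert not labels & {"mScarlet", "sfGFP"}

    def test_swapped_arms_raise_junction_mismatch(self, toolkit, cfg):
        with pytest.raises(JunctionMismatchError):
            assemble_del(toolkit["pDelUK-RG"],
                         make_ha_amplicon(toolkit, "AAT1", "down"),
                         make_ha_amplicon(toolkit, "AAT1", "up"), cfg)


class TestExchange:
    def test_three_tu_transfer_to_new_locus(self, toolkit, cfg, lvl2_zeta):
        result = exchange_has(lvl2_zeta, toolkit["pE1US1.1"], cfg)
        product = result.product
        assert product.id == "pE1US-HPD1-ARO4-ARO7"
        labels = {f.label for f in product.features}
        assert {"HPD1", "ARO4", "ARO7", "IntE1_up", "IntE1_dn",
                "spectinomycin"} <= labels
        assert "sfGFP" not in labels and "Zeta_up" not in labels
        assert result.reciprocal is not None
        recip_labels = {f.label for f in result.reciprocal.features}
        assert "sfGFP" in recip_labels and "ampicillin" in recip_labels

    def test_exchange_is_reversible(self, toolkit, cfg, lvl2_zeta):
        moved = exchange_has(lvl2_zeta, toolkit["pE1US1.1"], cfg).product
        back = exchange_has(moved, toolkit["pZUA2.3"], cfg).product
        assert molecules_equal(back, lvl2_zeta)

    def test_self_exchange_is_identity(self, cfg, lvl2_zeta):
        result = exchange_has(lvl2_zeta, lvl2_zeta, cfg)
        assert molecules_equal(result.product, lvl2_zeta)

    def test_central_section_conservation_oracle(self, toolkit, cfg,
                                                 lvl2_zeta):
        product = exchange_has(lvl2_zeta, toolkit["pE1US1.1"], cfg).product
        bb_empty, _ = aari_sections(toolkit["pE1US1.1"].seq)
        _, central_assembled = aari_sections(lvl2_zeta.seq)
        # each section includes both 4-nt windows; the joined circle counts
        # each window once
        assert len(product.seq) == len(bb_empty) + len(central_assembled) - 8
        expected = canonical_key(bb_empty[:-4] + central_assembled[:-4])
        assert canonical_key(product) == expected

    def test_wrong_site_count_rejected(self, toolkit, cfg):
        with pytest.raises(AssemblyError, match="exactly 2 AarI"):
            exchange_has(toolkit["pL0-TEF1"], toolkit["pE1US1.1"], cfg)


class TestTransferToDel:
    def test_irreversible_transfer(self, toolkit, cfg, lvl2_zeta):
        moved = exchange_has(lvl2_zeta, toolkit["pE1US1.1"], cfg).product
        pdel = assemble_del(toolkit["pDelUK-RG"],
                            make_ha_amplicon(toolkit, "AAT1", "up"),
                            make_ha_amplicon(toolkit, "AAT1", "down"), cfg)
        product = transfer_to_del(moved, pdel, cfg)
        assert product.id == "pDelUK-AAT1::HPD1-ARO4-ARO7"
        labels = {f.label for f in product.features}
        assert {"AAT1_up", "AAT1_dn", "HPD1", "ARO4", "ARO7"} <= labels
        # stable: the product has lost both AarI sites
        from yalicraft.model import find_sites
        assert find_sites(product, cfg.exchange_enzyme.recognition) == []

    def test_missing_aari_flank_rejected(self, toolkit, cfg, lvl1_hrgfp):
        with pytest.raises(AssemblyError, match="exactly 2 AarI"):
            transfer_to_del(lvl1_hrgfp, toolkit["pL0-TEF1"], cfg)
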