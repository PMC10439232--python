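"""Cre-lox marker excision and lambda-Red single-oligo recombineering."""

import pytest

from yalicraft.config import LoxConfig
from yalicraft.model import DnaMolecule, Interval, SeqFeature, molecules_equal, revcomp
from yalicraft.recomb import (
    AmbiguousTargetError,
    CreError,
    NoTargetError,
    Oligo90,
    OrientationError,
    counterselect_check,
    cre_excise,
    lambda_red_replace,
    marker_free_pair,
)

LOX = LoxConfig()


def toy_lox_circle():
    """lox71 - marker - lox66 - backbone, with annotated ori."""
    marker = "ATGCATGCATGCATGCATGCATGC"          # 24 bp stand-in marker
    backbone = "GGCCGGTTAACCGGCCAAGGCCTTGGCCAAGGCCAACCGGTT"  # 42 bp
    seq = LOX.lox71_seq + marker + LOX.lox66_seq + backbone
    feats = [
        SeqFeature("lox_site", "lox71", Interval(0, 34)),
        SeqFeature("marker", "MARK", Interval(34, 58)),
        SeqFeature("lox_site", "lox66", Interval(58, 92)),
        SeqFeature("origin", "ori", Interval(100, 120)),
    ]
    return DnaMolecule("toy-lox", seq, "circular", feats), marker, backbone


class TestCreExcise:
    def test_toy_circle_products_by_string_surgery(self):
        mol, marker, backbone = toy_lox_circle()
        report = cre_excise(mol, LOX)
        # retained: lox72 hybrid + backbone (left arm of lox71, spacer,
        # right arm of lox66)
        assert report.retained.seq == LOX.lox72_seq + backbone
        # excised: loxP-like hybrid + marker
        assert report.excised.seq == LOX.loxP_seq + marker
        # DNA conserved exactly
        assert len(report.retained.seq) + len(report.excised.seq) == \
            len(mol.seq)

    def test_retained_carries_lox72_and_loses_marker(self, lvl1_hrgfp, cfg):
        report = cre_excise(lvl1_hrgfp, cfg.lox)
        labels = {f.label for f in report.retained.features}
        assert "lox72" in labels and "URA3" not in labels
        assert "hrGFP" in labels  # the TU stays on the backbone circle
        excised_labels = {f.label for f in report.excised.features}
        assert "URA3" in excised_labels

    def test_length_conservation_on_fixture_plasmids(self, toolkit, cfg,
                                                     lvl1_hrgfp, lvl2_zeta):
        for mol in (lvl1_hrgfp, lvl2_zeta, toolkit["pProUA-mScarlet"]):
            report = cre_excise(mol, cfg.lox)
            assert len(report.retained.seq) + len(report.excised.seq) == \
                len(mol.seq), mol.id

    def test_idempotent_on_retained_product(self, lvl1_hrgfp, cfg):
        retained = cre_excise(lvl1_hrgfp, cfg.lox).retained
        with pytest.raises(CreError, match="no substrate"):
            cre_excise(retained, cfg.lox)

    def test_no_lox_sites_is_no_substrate(self):
        mol = DnaMolecule("m", "ACGT" * 30, "circular")
        with pytest.raises(CreError, match="no substrate"):
            cre_excise(mol, LOX)

    def test_inverted_sites_not_modeled(self):
        seq = LOX.lox71_seq + "ATGC" * 10 + revcomp(LOX.lox66_seq) + "GG" * 20
        mol = DnaMolecule("m", seq, "circular")
        with pytest.raises(CreError, match="inver"):
            cre_excise(mol, LOX)

    def test_more_than_two_sites_ambiguous(self):
        seq = (LOX.lox71_seq + "ATGC" * 5 + LOX.lox66_seq + "GGCC" * 5
               + LOX.lox66_seq + "TT" * 10)
        mol = DnaMolecule("m", seq, "circular")
        with pytest.raises(CreError, match="ambiguous"):
            cre_excise(mol, LOX)

    def test_minus_strand_pair_handled(self):
        mol, _, _ = toy_lox_circle()
        flipped = mol.reverse_complement()
        fwd = cre_excise(mol, LOX)
        rev = cre_excise(flipped, LOX)
        assert molecules_equal(fwd.retained, rev.retained)
        assert molecules_equal(fwd.excised, rev.excised)


class TestMarkerFreePair:
    def test_pair_differs_by_the_lox_flanked_marker(self, toolkit, cfg):
        pair = marker_free_pair(
            [toolkit["pA2US1.1"], toolkit["pL0-TEF1"], toolkit["pL0-hrGFP"],
             toolkit["pL0-Tsyn1"]], cfg.entry_enzyme, cfg)
        assert pair.marker_free is not None and not pair.warnings
        mb_labels = {f.label for f in pair.marker_based.features}
        mf_labels = {f.label for f in pair.marker_free.features}
        assert "URA3" in mb_labels and "URA3" not in mf_labels
        # diff oracle: the versions differ by the excised circle minus the
        # one lox site that remains as the lox72 scar
        assert len(pair.marker_based.seq) - len(pair.marker_free.seq) > 0

    def test_marker_without_lox_flanks_warns(self):
        # a minimal assembly whose product has no lox sites at all
        acc = DnaMolecule(
            "acc", "CCGGAAGGCCAACCAAGGAA" + "GGAG" + "A" + revcomp("GGTCTC")
            + "ATATATATAT" + "GGTCTC" + "A" + "CGCT"
            + "CCAACCAAGGCCAAGGCCAA", "circular")
        part = DnaMolecule(
            "part", "CCTTGGCCTTAAGGCATCAT" + "GGTCTC" + "A" + "GGAG"
            + "TTTTCCCCGG" + "CGCT" + "A" + revcomp("GGTCTC"), "circular")
        from yalicraft.typeiis import BSAI
        pair = marker_free_pair([acc, part], BSAI)
        assert pair.marker_free is None
        assert pair.warnings and "marker-free" in pair.warnings[0]

    def test_excision_commutes_with_ha_exchange(self, toolkit, cfg,
                                                lvl2_zeta):
        from yalicraft.grammar import exchange_has
        empty = toolkit["pE1US1.1"]
        ex_then_mex = cre_excise(
            exchange_has(lvl2_zeta, empty, cfg).product, cfg.lox).retained
        mex_then_ex = exchange_has(
            cre_excise(lvl2_zeta, cfg.lox).retained, empty, cfg).product
        assert molecules_equal(ex_then_mex, mex_then_ex)


class TestOligo90:
    def test_decomposition(self):
        oligo = Oligo90.from_parts("A" * 35, "C" * 20, "G" * 35)
        assert len(oligo.seq) == 90
        assert oligo.left_homology == "A" * 35
        assert oligo.spacer == "C" * 20
        assert oligo.right_homology == "G" * 35

    @pytest.mark.parametrize("left, spacer, right", [
        ("A" * 35, "C" * 19, "G" * 35),
        ("A" * 34, "C" * 20, "G" * 35),
        ("A" * 35, "C" * 20, "G" * 36),
    ])
    def test_bad_geometry_rejected(self, left, spacer, right):
        with pytest.raises(ValueError):
            Oligo90.from_parts(left, spacer, right)


class TestLambdaRed:
    @pytest.fixture()
    def helper(self, toolkit):
        return toolkit["pCasNA-RK"]

    @pytest.fixture()
    def oligo(self, helper, cfg):
        from yalicraft.cas import design_oligo
        return design_oligo("ACGTACGTTGCATGCATGCA", helper, cfg)

    def test_product_length_arithmetic(self, helper, oligo):
        product = lambda_red_replace(helper, oligo)
        cassette = helper.find_feature("rpsL-kanR").interval
        expected = len(helper.seq) - cassette.length(len(helper.seq)) + 20
        assert len(product.seq) == expected

    def test_locality_outside_homology_bounds(self, helper, oligo):
        product = lambda_red_replace(helper, oligo)
        # everything from the right-homology start around to the
        # left-homology end is untouched
        cassette = helper.find_feature("rpsL-kanR").interval
        n = len(helper.seq)
        kept = helper.region(cassette.end, cassette.end
                             + (cassette.start - cassette.end) % n)
        assert kept in (product.seq + product.seq)

    def test_counterselection(self, helper, oligo, cfg):
        assert not counterselect_check(helper, cfg)
        product = lambda_red_replace(helper, oligo)
        assert counterselect_check(product, cfg)
        cassette_seq = helper.feature_seq(helper.find_feature("rpsL-kanR"))
        assert not counterselect_check(helper, cfg, cassette_seq)
        assert counterselect_check(product, cfg, cassette_seq)

    def test_strand_of_oligo_is_irrelevant(self, helper, oligo):
        fwd = lambda_red_replace(helper, oligo)
        rev = lambda_red_replace(helper, oligo.reverse_complement())
        assert molecules_equal(fwd, rev)

    def test_successive_replacements_round_trip(self, helper, cfg):
        from yalicraft.cas import design_oligo
        spacer1, spacer2 = "ACGTACGTTGCATGCATGCA", "TTGGCCAAGGTTCCAAGGTT"
        h1 = lambda_red_replace(helper, design_oligo(spacer1, helper, cfg))
        flanks_left = h1.region(h1.find_feature("crRNA_spacer").interval.start
                                - 35,
                                h1.find_feature("crRNA_spacer").interval.start)
        iv = h1.find_feature("crRNA_spacer").interval
        flanks_right = h1.region(iv.end, iv.end + 35)
        h2 = lambda_red_replace(
            h1, Oligo90.from_parts(flanks_left, spacer2, flanks_right))
        h1_again = lambda_red_replace(
            h2, Oligo90.from_parts(flanks_left, spacer1, flanks_right))
        assert molecules_equal(h1_again, h1)

    def test_no_target(self, helper):
        oligo = Oligo90.from_parts("ACGT" * 8 + "ACG", "C" * 20, "TGCA" * 8
                                   + "TGC")
        with pytest.raises(NoTargetError):
            lambda_red_replace(helper, oligo)

    def test_ambiguous_homology(self, helper, oligo):
        # duplicate the left homology elsewhere on the helper
        dup = DnaMolecule(helper.id, helper.seq + "AA"
                          + oligo.left_homology + "AA",
                          "circular", list(helper.features))
        with pytest.raises(AmbiguousTargetError):
            lambda_red_replace(dup, oligo)

    def test_inconsistent_orientation(self, helper, oligo):
        mixed = Oligo90.from_parts(oligo.left_homology, oligo.spacer,
                                   revcomp(oligo.right_homology))
        with pytest.raises((OrientationError, NoTargetError,
                            AmbiguousTargetError)):
            lambda_red_replace(helper, mixed)
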