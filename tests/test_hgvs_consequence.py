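"""HGVS parsing and mutation-class assignment."""

import pytest

from aortapanel.hgvs_consequence import (
    CdnaKind,
    CysteineInvolvement,
    HgvsParseError,
    MutationClass,
    classify_consequence,
    cysteine_involvement,
    parse_cdna,
    parse_protein,
)


class TestParseCdna:
    def test_intronic_substitution(self):
        c = parse_cdna("c.6740-1G>A")
        assert c.kind is CdnaKind.INTRONIC
        assert c.offset == -1
        assert c.operation is CdnaKind.SUBSTITUTION
        assert (c.ref, c.alt) == ("G", "A")

    def test_multi_base_deletion(self):
        c = parse_cdna("c.8525_8529del")
        assert c.kind is CdnaKind.DELETION
        assert (c.start, c.end) == (8525, 8529)
        assert c.span == 5
        assert c.net_length_change() == -5
        assert not c.is_intronic

    def test_simple_substitution(self):
        c = parse_cdna("c.3G>A")
        assert c.kind is CdnaKind.SUBSTITUTION
        assert c.start == 3

    @pytest.mark.parametrize(
        "raw, net",
        [
            ("c.3440_3441insTTCAGCTGTC", 10),
            ("c.4527dupT", 1),
            ("c.1968_1969dupCA", 2),
            ("c.7010_7011delinsCAC", 1),
            ("c.678_680del", -3),
            ("c.3995delA", -1),
        ],
    )
    def test_net_length_change(self, raw, net):
        assert parse_cdna(raw).net_length_change() == net

    def test_unparseable_lenient_vs_strict(self):
        assert parse_cdna("c.(100_200)del").kind is CdnaKind.OTHER
        with pytest.raises(HgvsParseError):
            parse_cdna("c.(100_200)del", strict=True)
        with pytest.raises(HgvsParseError):
            parse_cdna("g.123A>G")


class TestParseProtein:
    def test_termination_flag(self):
        p = parse_protein("p.Gln2493Ter")
        assert p.termination and not p.frameshift

    def test_start_loss_flag(self):
        p = parse_protein("p.Met1Ile")
        assert p.startloss

    def test_plain_missense(self):
        p = parse_protein("p.Cys1791Tyr")
        assert (p.ref, p.position, p.alt) == ("Cys", 1791, "Tyr")
        assert not (p.frameshift or p.termination or p.startloss)

    def test_absent_protein_change(self):
        assert parse_protein("") is None
        assert parse_protein(".") is None
        assert parse_protein(None) is None

    def test_frameshift_flag_iff_fs_suffix(self):
        assert parse_protein("p.Ser1147fs").frameshift
        assert not parse_protein("p.Ser1147Cys").frameshift

    def test_malformed_string_lenient_keeps_fs_semantics(self):
        p = parse_protein("p.HisiSer656fs")
        assert p.anomaly and p.frameshift
        with pytest.raises(HgvsParseError):
            parse_protein("p.HisiSer656fs", strict=True)


class TestClassifyConsequence:
    @pytest.mark.parametrize(
        "cdna, protein, expected",
        [
            ("c.3440_3441insTTCAGCTGTC", "p.Ser1147fs", MutationClass.FRAMESHIFT_INSERTION),
            ("c.2540-2A>G", None, MutationClass.SPLICING),
            ("c.678_680del", "p.226_227del", MutationClass.NONFRAMESHIFT_INDEL),
            ("c.7477C>T", "p.Gln2493Ter", MutationClass.STOPGAIN),
            ("c.3G>A", "p.Met1Ile", MutationClass.STARTLOSS),
            ("c.5372G>A", "p.Cys1791Tyr", MutationClass.MISSENSE),
            ("c.8525_8529del", "p.Leu2842fs", MutationClass.FRAMESHIFT_DELETION),
            ("c.4527dupT", "p.Ile1510fs", MutationClass.FRAMESHIFT_INSERTION),
            ("c.7010_7011delinsCAC", "p.Gly2337fs", MutationClass.FRAMESHIFT_INSERTION),
            ("c.4081_4082delinsAA", "p.Cys1361Asn", MutationClass.MISSENSE),
            ("c.1960+1delG", None, MutationClass.SPLICING),
            ("c.100+5G>A", None, MutationClass.OTHER),  # deep intronic
            ("c.1968_1969dupCA", "p.HisiSer656fs", MutationClass.FRAMESHIFT_INSERTION),
        ],
    )
    def test_examples(self, cdna, protein, expected):
        c = parse_cdna(cdna)
        p = parse_protein(protein)
        assert classify_consequence(c, p) is expected

    def test_truncating_flags(self):
        assert MutationClass.STOPGAIN.truncating
        assert MutationClass.SPLICING.truncating_or_splicing
        assert not MutationClass.SPLICING.truncating
        assert not MutationClass.MISSENSE.truncating_or_splicing

    def test_classification_is_pure(self):
        c, p = parse_cdna("c.7477C>T"), parse_protein("p.Gln2493Ter")
        assert classify_consequence(c, p) is classify_consequence(c, p)


class TestCysteineInvolvement:
    @pytest.mark.parametrize(
        "protein, expected",
        [
            ("p.Cys1791Tyr", CysteineInvolvement.DESTROYS_CYS),
            ("p.Tyr2149Cys", CysteineInvolvement.CREATES_CYS),
            ("p.Asn1341Ser", CysteineInvolvement.NONE),
            ("p.Ser1147fs", CysteineInvolvement.NONE),  # not a substitution
            (None, CysteineInvolvement.NONE),
        ],
    )
    def test_examples(self, protein, expected):
        assert cysteine_involvement(parse_protein(protein)) is expected


class TestFixtureWide:
    def test_fbn1_rows_classify_without_falling_to_other(self, bundle):
        fbn1 = bundle.mutations[bundle.mutations["gene"] == "FBN1"]
        seen = set()
        for _, row in fbn1.iterrows():
            c = parse_cdna(row["cdna"])
            p = parse_protein(row["protein"])
            mc = classify_consequence(c, p)
            assert mc is not MutationClass.OTHER, row["cdna"]
            seen.add(mc)
        assert seen == {
            MutationClass.MISSENSE,
            MutationClass.STOPGAIN,
            MutationClass.FRAMESHIFT_INSERTION,
            MutationClass.FRAMESHIFT_DELETION,
            MutationClass.SPLICING,
            MutationClass.STARTLOSS,
        }

    def test_cdna_round_trip_on_whole_fixture(self, bundle):
        for raw in bundle.mutations["cdna"]:
            assert parse_cdna(raw).to_hgvs() == raw
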