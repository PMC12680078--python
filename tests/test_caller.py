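"""Peptide calling: miscleavage extension, filters, dedup, tiers, FASTA."""

import io

import pytest

from pepgraph.caller import (
    CallParams,
    call_alt_translation,
    call_backbone,
    canonical_digest,
    dedupe_and_annotate,
    entries_from_fasta,
    entries_to_fasta,
    filter_canonical,
    split_tiers,
    RawPeptide,
)
from pepgraph.reference import translate

from conftest import make_snv


def _src(gene="G1", backbone="T1", vids=(), orf="ORF0", kind="coding_tx"):
    return (gene, backbone, tuple(vids), orf, kind)


class TestCalling:
    def test_mid_cds_snv_peptides_annotated_with_exactly_that_variant(self):
        # MKTA YIEL K... with an SNV turning Y->F inside the second peptide
        seq = "ATGAAAACGGCTAAATATATTGAGCTGAAAGGGTAA"
        v = make_snv(15, "T", "ic"[0].upper() * 0 + "T", vid="dummy")  # placeholder
        v = make_snv(16, "A", "T", vid="yf")  # TAT -> TTT: Y -> F
        params = CallParams(min_length=1)
        canon = canonical_digest({"T1": translate(seq)}, params)
        peptides = call_backbone(seq, [v], params, coding=True, cds_start=0,
                                 canonical_set=canon)
        with_var = {p.seq for p in peptides}
        assert any("F" in p for p in with_var)
        for p in peptides:
            if "FIELK" in p.seq:
                assert p.variant_ids == frozenset({"yf"})

    def test_frameshift_variant_carried_to_downstream_peptides(self):
        seq = "ATGAAAACGGCTAAATATATTGAGCTGAAAGGGCCCTTTAAGTAA"
        from conftest import make_indel

        fs = make_indel(7, "C", "CT", vid="fs1")
        params = CallParams(min_length=1)
        canon = canonical_digest({"T1": translate(seq)}, params)
        peptides = call_backbone(seq, [fs], params, coding=True, cds_start=0,
                                 canonical_set=canon)
        downstream = [p for p in peptides if p.variant_ids and "fs1" in p.variant_ids]
        assert downstream, "frameshift produced no annotated peptides"
        # every non-canonical peptide in the shifted frame carries fs1
        for p in peptides:
            assert "fs1" in p.variant_ids

    def test_node_upstream_of_start_emits_nothing(self):
        # variants 5' of the ORF cannot produce peptides
        seq = "AAAAAAATGAAAACGGCTTAA"
        params = CallParams(min_length=1)
        canon = canonical_digest({"T1": translate(seq[6:])}, params)
        peptides = call_backbone(seq, [], params, coding=True, cds_start=6,
                                 canonical_set=canon)
        assert peptides == []


class TestMiscleavageExtension:
    def test_linear_chain_enumeration(self):
        # protein AK BK CK with cuts after each K
        seq = "ATGGCTAAAGGTAAATGTAAATAA"  # M A K G K C K *
        params = CallParams(min_length=1, max_miscleavage=2)
        peptides = call_backbone(seq, [], params, coding=True, cds_start=0)
        seqs = {p.seq for p in peptides}
        assert seqs == {"MAK", "MAKGK", "MAKGKCK", "GK", "GKCK", "CK"}

    def test_zero_miscleavage_single_nodes_only(self):
        seq = "ATGGCTAAAGGTAAATGTAAATAA"
        params = CallParams(min_length=1, max_miscleavage=0)
        peptides = call_backbone(seq, [], params, coding=True, cds_start=0)
        assert {p.seq for p in peptides} == {"MAK", "GK", "CK"}

    def test_branching_after_cut_emits_both_concatenations(self):
        seq = "ATGGCTAAAGATATTGAGTAA"  # M A K | D I E *
        v = make_snv(13, "T", "C", vid="b")  # ATT -> ACT: D I E -> D T E
        params = CallParams(min_length=1, max_miscleavage=1)
        peptides = call_backbone(seq, [v], params, coding=True, cds_start=0)
        seqs = {p.seq for p in peptides}
        assert {"MAKDIE", "MAKDTE"} <= seqs


class TestFilters:
    def test_canonical_peptides_removed(self):
        stream = [
            RawPeptide("AAAK", frozenset(), (-1, "CDS"), 0),
            RawPeptide("CCCK", frozenset({"v"}), (-1, "CDS"), 0),
        ]
        assert [p.seq for p in filter_canonical(stream, {"AAAK"})] == ["CCCK"]

    def test_variant_peptide_matching_canonical_elsewhere_removed(self):
        # two-protein proteome: the variant recreates a peptide of protein 2
        params = CallParams(min_length=3, max_length=30)
        seq = "ATGGCTGCTAAAGATATTGAGAAATAA"  # MAAK DIEK
        v = make_snv(13, "A", "C", vid="x")  # DIEK -> HIEK? (GAT->CAT = H)
        proteome = {"P1": translate(seq), "P2": "MHHHKHIEKGGG"}
        canon = canonical_digest(proteome, params)
        peptides = call_backbone(seq, [v], params, coding=True, cds_start=0,
                                 canonical_set=canon)
        assert "HIEK" not in {p.seq for p in peptides}

    def test_empty_stream(self):
        assert filter_canonical([], {"AAAK"}) == []


class TestDedupeAndTiers:
    def test_same_sequence_from_two_sources_one_entry(self):
        called = [
            ("PEPTIDEK", _src(vids=("snv1",))),
            ("PEPTIDEK", _src(vids=("edit1",), kind="coding_tx")),
        ]
        entries = dedupe_and_annotate(called)
        assert len(entries) == 1
        assert len(entries["PEPTIDEK"].sources) == 2

    def test_identical_sources_collapse(self):
        called = [("PEPK", _src()), ("PEPK", _src())]
        assert len(dedupe_and_annotate(called)["PEPK"].sources) == 1

    @pytest.mark.parametrize(
        "kinds_vids,expected",
        [
            ([("coding_tx", ("v",))], "Variant"),
            ([("noncoding_tx", ())], "Noncoding"),
            ([("noncoding_tx", ("v",))], "NoncodingVariant"),
            ([("circ", ())], "CircularRNA"),
            ([("alt_translation", ())], "AltTranslation"),
            # multi-source: highest-priority tier wins
            ([("coding_tx", ("v",)), ("circ", ())], "Variant"),
            ([("noncoding_tx", ()), ("circ", ())], "Noncoding"),
        ],
    )
    def test_tier_assignment(self, kinds_vids, expected):
        called = [("PEPK", _src(vids=v, kind=k)) for k, v in kinds_vids]
        entries = dedupe_and_annotate(called)
        assert entries["PEPK"].tier == expected

    def test_split_tiers_partition_is_disjoint(self):
        called = [
            ("AAAAK", _src(vids=("v",))),
            ("CCCCK", _src(kind="noncoding_tx", vids=())),
            ("DDDDK", _src(kind="circ")),
        ]
        tiers = split_tiers(dedupe_and_annotate(called))
        seqs = [e.aa_seq for es in tiers.values() for e in es]
        assert sorted(seqs) == ["AAAAK", "CCCCK", "DDDDK"]
        assert len(tiers["Variant"]) == 1
        assert len(tiers["Noncoding"]) == 1
        assert len(tiers["CircularRNA"]) == 1


class TestAltTranslation:
    def test_w_to_f_substitutant(self):
        params = CallParams(min_length=4, max_length=25)
        proteome = {"P1": "MMMKXWZKGGG".replace("X", "A").replace("Z", "C")}
        canon = canonical_digest(proteome, params)
        out = call_alt_translation(proteome, "w_to_f", params, canon)
        assert ("AFCK", "P1", "w_to_f") in out

    def test_peptide_without_w_emits_nothing(self):
        params = CallParams(min_length=4)
        proteome = {"P1": "MMMKAACKGGG"}
        canon = canonical_digest(proteome, params)
        assert call_alt_translation(proteome, "w_to_f", params, canon) == []

    def test_selenocysteine_termination_truncates(self):
        params = CallParams(min_length=2, max_length=25)
        proteome = {"P1": "MAKGGUGGKLLL"}
        canon = canonical_digest(proteome, params)
        out = call_alt_translation(
            proteome, "selenocysteine_termination", params, canon
        )
        assert ("GG", "P1", "selenocysteine_termination") in out

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            call_alt_translation({}, "bogus", CallParams(), set())


class TestFasta:
    def test_round_trip_and_determinism(self):
        called = [
            ("AAAAK", _src(vids=("v1", "v2"))),
            ("CCCCK", _src(kind="noncoding_tx", vids=(), orf="ORF12")),
        ]
        entries = dedupe_and_annotate(called)
        buf1 = io.StringIO()
        entries_to_fasta(list(entries.values()), buf1)
        buf1.seek(0)
        back = entries_from_fasta(buf1)
        assert {s for s in back} == {"AAAAK", "CCCCK"}
        assert back["AAAAK"].sources == entries["AAAAK"].sources
        buf2 = io.StringIO()
        entries_to_fasta(list(back.values()), buf2)
        assert buf1.getvalue() == buf2.getvalue()
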