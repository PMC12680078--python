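"""Fusion and circRNA backbone construction."""

import pytest

from pepgraph.backbones import (
    build_circ_backbone,
    build_fusion_backbone,
    map_tx_variants_to_circ,
)
from pepgraph.caller import CallParams, call_transcript
from pepgraph.gvf import CircRNAModel, FusionEvent
from pepgraph.reference import GenomeAssembly, TranscriptModel, translate

from conftest import make_snv


def _single_exon_tx(name, gene, chrom, seq_len, cds=None, strand="+"):
    tx = TranscriptModel(name, gene, chrom, strand, [(0, seq_len)])
    if cds is not None:
        tx.cds_start_tx, tx.cds_end_tx = cds
    return tx


class TestFusion:
    def test_coding_donor_junction_peptide(self):
        donor_seq = "ATGGCTGCTAAAGATATTGAG"  # M A A K D I E
        acceptor_seq = "GGGTTTAAGCCGTAA"
        genome = GenomeAssembly({"cD": donor_seq, "cA": acceptor_seq})
        ann = {
            "TXD": _single_exon_tx("TXD", "GD", "cD", len(donor_seq), cds=(0, 21)),
            "TXA": _single_exon_tx("TXA", "GA", "cA", len(acceptor_seq)),
        }
        event = FusionEvent("F1", "GD", "TXD", "GA", "TXA",
                            donor_breakpoint=15, acceptor_breakpoint=3)
        backbone = build_fusion_backbone(event, ann, genome)
        assert backbone.coding and backbone.cds_start == 0
        assert backbone.seq == donor_seq[:15] + acceptor_seq[3:]
        # chimeric peptide across the junction, verified by direct translation
        expected_protein = translate(backbone.seq)
        peptides = call_transcript(
            backbone.seq, [], CallParams(min_length=1), coding=True, cds_start=0
        )
        junction_peps = {p.seq for p in peptides}
        assert "DFKP" in junction_peps  # GAT|TTT AAG CCG spans the junction
        assert expected_protein.startswith("MAAKD")

    def test_intronic_donor_breakpoint_retains_intron_with_variant(self):
        # donor: exon1 [0,9), intron [9,15), exon2 [15,21)
        genome_seq = "ATGGCTAAA" + "GTCGAT" + "GATTAG" + "X".replace("X", "A")
        genome = GenomeAssembly({"cD": genome_seq, "cA": "GGGTTTAAGTAA"})
        donor = TranscriptModel("TXD", "GD", "cD", "+", [(0, 9), (15, 21)])
        donor.cds_start_tx, donor.cds_end_tx = 0, 12
        ann = {
            "TXD": donor,
            "TXA": _single_exon_tx("TXA", "GA", "cA", 12),
        }
        event = FusionEvent(
            "F1", "GD", "TXD", "GA", "TXA",
            donor_breakpoint=4,  # keep 4 intron bases: GTCG
            acceptor_breakpoint=0,
            donor_intronic=True,
            donor_intron_idx=0,
        )
        backbone = build_fusion_backbone(event, ann, genome)
        assert backbone.seq == "ATGGCTAAA" + "GTCG" + "GGGTTTAAGTAA"

    def test_noncoding_donor_treated_as_noncoding(self):
        genome = GenomeAssembly({"cD": "AAACCCGGGTTT", "cA": "GGGTTTAAG"})
        ann = {
            "TXD": _single_exon_tx("TXD", "GD", "cD", 12),
            "TXA": _single_exon_tx("TXA", "GA", "cA", 9),
        }
        event = FusionEvent("F1", "GD", "TXD", "GA", "TXA", 6, 0)
        backbone = build_fusion_backbone(event, ann, genome)
        assert not backbone.coding and backbone.kind == "fusion_noncoding"

    def test_breakpoint_outside_gene_body_rejected(self):
        genome = GenomeAssembly({"cD": "AAACCC", "cA": "GGGTTT"})
        ann = {
            "TXD": _single_exon_tx("TXD", "GD", "cD", 6),
            "TXA": _single_exon_tx("TXA", "GA", "cA", 6),
        }
        event = FusionEvent("F1", "GD", "TXD", "GA", "TXA", 99, 0)
        with pytest.raises(ValueError, match="outside gene body"):
            build_fusion_backbone(event, ann, genome)

    def test_variant_overlapping_breakpoint_dropped(self):
        genome = GenomeAssembly({"cD": "AAACCCGGGTTT", "cA": "GGGTTTAAG"})
        ann = {
            "TXD": _single_exon_tx("TXD", "GD", "cD", 12),
            "TXA": _single_exon_tx("TXA", "GA", "cA", 9),
        }
        event = FusionEvent("F1", "GD", "TXD", "GA", "TXA", 6, 3)
        backbone = build_fusion_backbone(
            event, ann, genome,
            donor_variants=[make_snv(7, "G", "A", vid="late")],
            acceptor_variants=[make_snv(1, "G", "A", vid="early")],
        )
        assert backbone.variants == []


class TestCirc:
    def test_linearization_is_three_copies(self):
        genome = GenomeAssembly({"c": "AAACCCGGGTTTAAACCC"})
        ann = {"TXH": _single_exon_tx("TXH", "GH", "c", 18)}
        circ = CircRNAModel("C1", "GH", "TXH", ((3, 12),))
        backbone = build_circ_backbone(circ, genome, ann)
        assert backbone.seq == "CCCGGGTTT" * 3
        assert backbone.junctions == (9, 18)
        assert not backbone.coding and backbone.kind == "circ"

    def test_variants_replicated_per_copy(self):
        genome = GenomeAssembly({"c": "AAACCCGGGTTTAAACCC"})
        ann = {"TXH": _single_exon_tx("TXH", "GH", "c", 18)}
        circ = CircRNAModel("C1", "GH", "TXH", ((3, 12),))
        v = make_snv(4, "G", "A", vid="cv")  # circle-local coordinates
        backbone = build_circ_backbone(circ, genome, ann, variants=[v])
        starts = sorted(r.start_tx for r in backbone.variants)
        assert starts == [4, 13, 22]
        assert all(r.variant_id == "cv" for r in backbone.variants)

    def test_junction_crossing_variant_dropped(self):
        genome = GenomeAssembly({"c": "AAACCCGGGTTTAAACCC"})
        ann = {"TXH": _single_exon_tx("TXH", "GH", "c", 18)}
        circ = CircRNAModel("C1", "GH", "TXH", ((3, 9),))
        bad = make_snv(8, "G", "A", vid="bad")
        bad = bad.__class__(**{**bad.__dict__})
        from conftest import make_indel

        crossing = make_indel(5, "CGGG", "C", vid="x")  # end 9 > circle len 6
        backbone = build_circ_backbone(circ, genome, ann, variants=[crossing])
        assert backbone.variants == []

    def test_map_tx_variants_into_circle_coordinates(self):
        circ = CircRNAModel("C1", "GH", "TXH", ((10, 16), (20, 26)))
        inside = make_snv(21, "A", "C", vid="in")
        outside = make_snv(5, "A", "C", vid="out")
        mapped = map_tx_variants_to_circ(circ, [inside, outside])
        assert len(mapped) == 1
        assert mapped[0].start_tx == 7  # 6 segment-1 bases + offset 1


def test_circ_rolling_translation_matches_string_oracle():
    """Peptides from the circular backbone equal the (circ x 3) oracle."""
    import random

    from pepgraph.fuzz import _brute_noncoding_peptides
    from pepgraph.enzymes import get_enzyme

    rng = random.Random(9)
    params = CallParams(min_length=4)
    for _ in range(20):
        L = rng.randint(9, 60)
        host = "".join(rng.choice("ACGT") for _ in range(L + 10))
        genome = GenomeAssembly({"c": host})
        ann = {"TXH": _single_exon_tx("TXH", "GH", "c", len(host))}
        circ = CircRNAModel("C1", "GH", "TXH", ((0, L),))
        backbone = build_circ_backbone(circ, genome, ann)
        got = {
            p.seq
            for p in call_transcript(backbone.seq, [], params, coding=False)
        }
        lin = host[:L] * 3
        expected = _brute_noncoding_peptides(
            lin, list(range(len(lin))), frozenset(), get_enzyme("trypsin"),
            2, 4, 25,
        )
        assert got == {p for p in expected if "X" not in p}
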