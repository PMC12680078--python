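"""Upstream caller output parsing into GVF records."""

import pandas as pd
import pytest

from pepgraph.parsers import (
    parse_alt_splicing,
    parse_circrna,
    parse_fusion,
    parse_rna_editing,
    parse_vep,
)
from pepgraph.reference import GenomeAssembly, TranscriptModel


@pytest.fixture
def genome():
    #           0         1         2         3
    #           0123456789012345678901234567890123456789
    chrom1 = "AAAAAAAAAACCTTGGCCAAGGTTCCAAGGTTAAGGCCAA"
    return GenomeAssembly({"chr1": chrom1})


@pytest.fixture
def annotation(genome):
    plus = TranscriptModel("T1", "G1", "chr1", "+", [(10, 40)])
    minus = TranscriptModel("T2", "G1", "chr1", "-", [(10, 40)])
    return {"T1": plus, "T2": minus}


def vep_df(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "#Uploaded_variation", "Location", "Allele", "Gene", "Feature",
            "Consequence",
        ],
    )


class TestParseVEP:
    def test_plus_strand_snv(self, genome, annotation):
        # genomic 1-based 18 = 0-based 17 ('C'); exon starts at 10
        df = vep_df([["var1", "chr1:18", "T", "G1", "T1", "missense_variant"]])
        (rec,) = parse_vep(df, annotation, genome)
        assert rec.start_tx == 7
        assert (rec.ref_seq, rec.alt_seq) == ("C", "T")
        assert rec.type == "SNV"

    def test_minus_strand_snv_reverse_complemented(self, genome, annotation):
        df = vep_df([["var1", "chr1:18", "T", "G1", "T2", "missense_variant"]])
        (rec,) = parse_vep(df, annotation, genome)
        # 0-based 17 maps to transcript position 39 - 17 = 22 on the - strand
        assert rec.start_tx == 22
        assert (rec.ref_seq, rec.alt_seq) == ("G", "A")

    def test_deletion_left_anchored_against_transcript(self, genome, annotation):
        # delete 0-based [17, 19) = 'CA'... genome: pos 17='C', 18='A'
        df = vep_df([["del1", "chr1:18-19", "-", "G1", "T1", "deletion"]])
        (rec,) = parse_vep(df, annotation, genome)
        assert rec.type == "DELETION"
        assert rec.end_tx - rec.start_tx == len(rec.ref_seq)
        assert len(rec.ref_seq) == 3 and len(rec.alt_seq) == 1
        assert rec.ref_seq[0] == rec.alt_seq  # retained anchor base
        # strand reconstruction: the deleted transcript span matches genome
        assert rec.ref_seq[1:] == genome.fetch("chr1", 17, 19)

    def test_unknown_transcript_skipped(self, genome, annotation):
        df = vep_df([["v", "chr1:18", "T", "G1", "TX_NOPE", "missense_variant"]])
        assert parse_vep(df, annotation, genome) == []

    def test_splice_consequence_dropped(self, genome, annotation):
        df = vep_df([["v", "chr1:18", "T", "G1", "T1", "splice_donor_variant"]])
        assert parse_vep(df, annotation, genome) == []

    def test_intronic_position_dropped(self, genome, annotation):
        df = vep_df([["v", "chr1:5", "T", "G1", "T1", "intron_variant"]])
        assert parse_vep(df, annotation, genome) == []

    def test_emitted_record_revalidates_against_transcript(self, genome, annotation):
        from pepgraph.reference import transcript_sequence

        df = vep_df([
            ["a", "chr1:18", "T", "G1", "T1", "missense_variant"],
            ["b", "chr1:18", "T", "G1", "T2", "missense_variant"],
        ])
        for rec in parse_vep(df, annotation, genome):
            tx = annotation[rec.transcript_ids[0]]
            rec.validate_against(transcript_sequence(genome, tx))


class TestParseFusion:
    def _annotation(self):
        g = {"chrA": "A" * 50 + "C" * 50, "chrB": "G" * 40 + "T" * 60}
        genome = GenomeAssembly(g)
        ann = {}
        # donor gene GA: 2 transcripts; acceptor gene GB: 3 transcripts
        ann["TA1"] = TranscriptModel("TA1", "GA", "chrA", "+", [(0, 30)])
        ann["TA2"] = TranscriptModel("TA2", "GA", "chrA", "+", [(0, 10), (20, 30)])
        for i in range(3):
            ann[f"TB{i}"] = TranscriptModel(
                f"TB{i}", "GB", "chrB", "+", [(5 + i, 35 + i)]
            )
        return genome, ann

    def test_cartesian_product_of_transcript_pairs(self):
        _, ann = self._annotation()
        df = pd.DataFrame(
            [["F1--x", "SYM^GA", "chrA:6:+", "SYM2^GB", "chrB:10:+"]],
            columns=["#FusionName", "LeftGene", "LeftBreakpoint", "RightGene",
                     "RightBreakpoint"],
        )
        events = parse_fusion(df, ann)
        assert len(events) == 6  # 2 donor x 3 acceptor transcripts

    def test_intronic_breakpoint_flagged(self):
        _, ann = self._annotation()
        # genomic 0-based 14 sits in TA2's intron [10, 20)
        df = pd.DataFrame(
            [["F2--y", "GA", "chrA:15:+", "GB", "chrB:10:+"]],
            columns=["#FusionName", "LeftGene", "LeftBreakpoint", "RightGene",
                     "RightBreakpoint"],
        )
        events = parse_fusion(df, ann)
        ta2 = [e for e in events if e.donor_transcript_id == "TA2"]
        assert ta2 and all(e.donor_intronic for e in ta2)
        assert ta2[0].donor_intron_idx == 0
        assert ta2[0].donor_breakpoint == 5  # retain 5 intron bases
        ta1 = [e for e in events if e.donor_transcript_id == "TA1"]
        assert ta1 and not ta1[0].donor_intronic

    def test_absent_gene_dropped(self):
        _, ann = self._annotation()
        df = pd.DataFrame(
            [["F3--z", "GA", "chrA:6:+", "NOPE", "chrB:10:+"]],
            columns=["#FusionName", "LeftGene", "LeftBreakpoint", "RightGene",
                     "RightBreakpoint"],
        )
        assert parse_fusion(df, ann) == []


class TestParseAltSplicing:
    def _setup(self):
        # + strand transcript with 3 exons: [10,20) [30,40) [50,60)
        chrom = "".join("ACGT"[i % 4] for i in range(80))
        genome = GenomeAssembly({"chr1": chrom})
        tx = TranscriptModel("T1", "G1", "chr1", "+", [(10, 20), (30, 40), (50, 60)])
        return genome, {"T1": tx}

    def test_retained_intron_insertion(self):
        genome, ann = self._setup()
        df = pd.DataFrame(
            [["G1", "chr1", "+", 10, 20, 30, 40]],
            columns=["GeneID", "chr", "strand", "upstreamES", "upstreamEE",
                     "downstreamES", "downstreamEE"],
        )
        (rec,) = parse_alt_splicing(df, "RI", ann, genome)
        assert rec.type == "ALT_SPLICE_RI"
        assert rec.start_tx == rec.end_tx == 10
        assert rec.alt_seq == genome.fetch("chr1", 20, 30)
        assert len(rec.alt_seq) == 10

    def test_skipped_exon_deletion(self):
        genome, ann = self._setup()
        df = pd.DataFrame(
            [["G1", "chr1", "+", 30, 40, 10, 20, 50, 60]],
            columns=["GeneID", "chr", "strand", "exonStart_0base", "exonEnd",
                     "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"],
        )
        (rec,) = parse_alt_splicing(df, "SE", ann, genome)
        assert rec.type == "ALT_SPLICE_SE"
        assert (rec.start_tx, rec.end_tx) == (10, 20)
        assert rec.alt_seq == "" and len(rec.ref_seq) == 10

    def test_a5ss_extension_insertion(self):
        genome, ann = self._setup()
        # long exon extends [30,40) to [30,45): 5 extra nucleotides
        df = pd.DataFrame(
            [["G1", "chr1", "+", 30, 45, 30, 40, 50, 60]],
            columns=["GeneID", "chr", "strand", "longExonStart_0base",
                     "longExonEnd", "shortES", "shortEE", "flankingES",
                     "flankingEE"],
        )
        (rec,) = parse_alt_splicing(df, "A5SS", ann, genome)
        assert rec.type == "ALT_SPLICE_A5SS"
        assert rec.start_tx == rec.end_tx == 20  # after the short exon
        assert rec.alt_seq == genome.fetch("chr1", 40, 45)

    def test_mxe_substitution(self):
        genome, ann = self._setup()
        df = pd.DataFrame(
            [["G1", "chr1", "+", 30, 40, 62, 70, 10, 20, 50, 60]],
            columns=["GeneID", "chr", "strand", "1stExonStart_0base",
                     "1stExonEnd", "2ndExonStart_0base", "2ndExonEnd",
                     "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"],
        )
        (rec,) = parse_alt_splicing(df, "MXE", ann, genome)
        assert rec.type == "ALT_SPLICE_MXE"
        assert (rec.start_tx, rec.end_tx) == (10, 20)
        assert rec.alt_seq == genome.fetch("chr1", 62, 70)

    def test_unreconcilable_event_dropped(self):
        genome, ann = self._setup()
        df = pd.DataFrame(
            [["G1", "chr1", "+", 11, 19, 30, 40, 50, 60]],
            columns=["GeneID", "chr", "strand", "exonStart_0base", "exonEnd",
                     "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"],
        )
        assert parse_alt_splicing(df, "SE", ann, genome) == []


class TestParseRNAEditing:
    def _setup(self):
        chrom = "AAAAAAAAAACCTTGGCCAAGGTTCCAAGG"
        genome = GenomeAssembly({"chr1": chrom})
        tx = TranscriptModel("T1", "G1", "chr1", "+", [(10, 30)])
        return genome, {"T1": tx}

    def test_exonic_site_becomes_snv(self):
        genome, ann = self._setup()
        df = pd.DataFrame(
            [["chr1", 19, "A", "AG"]],
            columns=["Region", "Position", "Reference", "AllSubs"],
        )
        (rec,) = parse_rna_editing(df, ann, genome)
        assert rec.type == "SNV" and rec.source == "RNAEditing"
        assert rec.start_tx == 8
        assert (rec.ref_seq, rec.alt_seq) == ("A", "G")

    def test_intronic_site_dropped(self):
        genome, ann = self._setup()
        df = pd.DataFrame(
            [["chr1", 5, "A", "AG"]],
            columns=["Region", "Position", "Reference", "AllSubs"],
        )
        assert parse_rna_editing(df, ann, genome) == []

    def test_reference_mismatch_rejected(self):
        genome, ann = self._setup()
        df = pd.DataFrame(
            [["chr1", 19, "C", "CG"]],
            columns=["Region", "Position", "Reference", "AllSubs"],
        )
        assert parse_rna_editing(df, ann, genome) == []


class TestParseCircRNA:
    def test_exonic_circle_segments(self):
        chrom = "".join("ACGT"[i % 4] for i in range(80))
        genome = GenomeAssembly({"chr1": chrom})
        tx = TranscriptModel("T1", "G1", "chr1", "+", [(10, 20), (30, 40), (50, 60)])
        df = pd.DataFrame(
            [["chr1", 30, 60, "+", "T1"]],
            columns=["chrom", "start", "end", "strand", "isoformName"],
        )
        (circ,) = parse_circrna(df, {"T1": tx})
        assert circ.segments == ((10, 20), (20, 30))  # exons 2 and 3 in tx coords
        assert circ.transcript_id == "T1"

    def test_unknown_transcript_dropped(self):
        df = pd.DataFrame(
            [["chr1", 30, 60, "+", "NOPE"]],
            columns=["chrom", "start", "end", "strand", "isoformName"],
        )
        assert parse_circrna(df, {}) == []
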