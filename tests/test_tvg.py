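"""Transcript variant graph construction and edge-case rules."""

import pytest

from pepgraph.tvg import (
    TVG,
    apply_alt_splice,
    apply_variant,
    exclude_edge_case_variants,
    init_tvg,
    outgoing_frame,
)

from conftest import make_alt_splice, make_indel, make_snv


class TestInit:
    def test_three_frame_offsets(self):
        tvg = init_tvg("ATGAAA", has_known_orf=False)
        assert tvg.roots[0].seq == "ATGAAA"
        assert tvg.roots[1].seq == "TGAAA"
        assert tvg.roots[2].seq == "GAAA"

    def test_length_one_sequence_degenerate_frames(self):
        tvg = init_tvg("A", has_known_orf=False)
        assert tvg.roots[0].seq == "A"
        assert tvg.roots[1].seq == ""
        assert tvg.roots[2].seq == ""

    def test_known_orf_flag(self):
        tvg = init_tvg("ATGAAATAA", has_known_orf=True, cds_start=0)
        assert tvg.has_known_orf

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            init_tvg("", has_known_orf=False)


class TestOutgoingFrame:
    @pytest.mark.parametrize(
        "s_ref,s_alt,frame,expected",
        [
            (1, 1, 0, 0),  # in-frame SNV
            (2, 1, 0, 1),  # 1-nt deletion
            (1, 3, 1, 2),  # floor-mod for insertions: (1 + 1 - 3) mod 3
        ],
    )
    def test_examples(self, s_ref, s_alt, frame, expected):
        assert outgoing_frame(s_ref, s_alt, frame) == expected

    def test_in_frame_when_lengths_congruent(self):
        for d in range(0, 10, 3):
            assert outgoing_frame(d, 0, 1) == (1 + d) % 3

    def test_negative_lengths_rejected(self):
        with pytest.raises(ValueError):
            outgoing_frame(-1, 0, 0)


class TestApplyVariant:
    def test_snv_splits_reference_node(self):
        tvg = init_tvg("ATGAAAGGG", has_known_orf=True, cds_start=0)
        apply_variant(tvg, make_snv(3, "A", "C"))
        chain = tvg._chain_nodes[0]
        assert [n.seq for n in chain] == ["ATG", "A", "AAGGG"]
        ref_mid = chain[1]
        alts = [n for n in ref_mid.in_nodes[0].out_nodes if n.variants]
        assert len(alts) == 1 and alts[0].seq == "C"
        assert alts[0].variants[0].variant_id == "v1"

    def test_frameshift_close_edge_lands_in_shifted_frame(self):
        tvg = init_tvg("ATGAAAGGGTTTCCC", has_known_orf=True, cds_start=0)
        ins = make_indel(5, "A", "AC", vid="fs")  # 1-nt insertion: frame 2
        apply_variant(tvg, ins)
        assert 2 in tvg.active_from
        assert tvg.active_from[2] == ins.end_tx
        # a downstream variant is now incorporated into frames 0 and 2
        snv = make_snv(9, "T", "A", vid="down")
        apply_variant(tvg, snv)
        for frame in (0, 2):
            alt_nodes = [
                n
                for chain_node in tvg._chain_nodes[frame]
                for n in chain_node.out_nodes
                if n.variants and n.variants[0].variant_id == "down"
            ]
            assert alt_nodes, f"downstream SNV missing from frame {frame}"

    def test_noncoding_variant_in_all_three_frames(self):
        tvg = init_tvg("ATGAAAGGGTTT", has_known_orf=False)
        apply_variant(tvg, make_snv(6, "G", "T"))
        for frame in (0, 1, 2):
            alts = [
                n
                for chain_node in tvg._chain_nodes[frame]
                for n in chain_node.out_nodes
                if n.variants
            ]
            assert len(alts) == 1

    def test_span_outside_transcript_rejected(self):
        tvg = init_tvg("ATGAAA", has_known_orf=False)
        with pytest.raises(Exception):
            apply_variant(tvg, make_snv(10, "A", "C"))

    def test_reference_path_reconstruction_after_variants(self):
        seq = "ATGAAAGGGTTTCCCAAATTTGGG"
        tvg = init_tvg(seq, has_known_orf=False)
        apply_variant(tvg, make_snv(4, "A", "C", vid="a"))
        apply_variant(tvg, make_indel(9, "T", "TAA", vid="b"))
        apply_variant(tvg, make_indel(15, "AAAT", "A", vid="c"))
        for k in (0, 1, 2):
            assert tvg.reference_path_sequence(k) == seq[k:]


class TestApplyAltSplice:
    def test_retained_intron_subgraph_with_nested_snv(self):
        seq = "ATGAAAGGGTTTCCC"
        tvg = init_tvg(seq, has_known_orf=False)
        parent = make_alt_splice(6, "", "CCCTTTGGG", vid="ri")
        nested = make_snv(4, "T", "A", vid="n0", parent_id="ri")
        apply_alt_splice(tvg, parent, [nested])
        sg = [
            n
            for chain_node in tvg._chain_nodes[0]
            for n in chain_node.out_nodes
            if n.subgraph_id == "ri"
        ]
        assert sg, "subgraph entry node missing"
        # entry node chains to nested alternative and reference segments
        entry = sg[0]
        assert entry.seq == "CCCT"  # split at the nested SNV
        kinds = {n.seq for n in entry.out_nodes}
        assert kinds == {"T", "A"}

    def test_exon_skip_is_plain_deletion_node(self):
        seq = "ATGAAAGGGTTTCCC"
        tvg = init_tvg(seq, has_known_orf=False)
        skip = make_alt_splice(3, "AAAGGG", "", vid="se", vtype="ALT_SPLICE_SE")
        apply_alt_splice(tvg, skip, [])
        alts = [
            n
            for chain_node in tvg._chain_nodes[0]
            for n in chain_node.out_nodes
            if n.variants
        ]
        assert alts[0].seq == ""

    def test_nested_with_wrong_parent_rejected(self):
        tvg = init_tvg("ATGAAAGGG", has_known_orf=False)
        parent = make_alt_splice(3, "", "TTT", vid="ri")
        bad_nested = make_snv(0, "T", "A", vid="n0", parent_id="other")
        with pytest.raises(ValueError, match="parent_id"):
            apply_alt_splice(tvg, parent, [bad_nested])


class TestEdgeCaseExclusion:
    def test_start_codon_altering_excluded(self):
        kept, excluded = exclude_edge_case_variants(
            [make_snv(11, "A", "C")], cds_start=10, cds_end=40
        )
        assert not kept
        assert excluded[0][1] == "start-codon-altering"

    def test_mid_cds_kept(self):
        kept, excluded = exclude_edge_case_variants(
            [make_snv(20, "A", "C")], cds_start=10, cds_end=40
        )
        assert len(kept) == 1 and not excluded

    def test_stop_codon_altering_kept(self):
        # destroying the stop is allowed; translation later truncates at
        # the last complete peptide
        kept, _ = exclude_edge_case_variants(
            [make_snv(41, "A", "C")], cds_start=10, cds_end=40
        )
        assert len(kept) == 1

    def test_five_prime_of_orf_dropped(self):
        kept, excluded = exclude_edge_case_variants(
            [make_snv(2, "A", "C")], cds_start=10, cds_end=40
        )
        assert not kept and excluded[0][1] == "5'-of-ORF"

    def test_three_prime_of_stop_dropped(self):
        kept, excluded = exclude_edge_case_variants(
            [make_snv(50, "A", "C")], cds_start=10, cds_end=40
        )
        assert not kept and excluded[0][1] == "3'-of-stop"

    def test_splice_consequence_excluded(self):
        kept, excluded = exclude_edge_case_variants(
            [make_snv(20, "A", "C")],
            cds_start=10,
            cds_end=40,
            consequences={"v1": ("splice_acceptor_variant",)},
        )
        assert not kept and excluded[0][1] == "splice-site-altering"


def test_apply_order_independence_for_disjoint_variants():
    seq = "ATGAAAGGGTTTCCCAAATTTGGGCCCAAA"
    va = make_snv(4, "A", "C", vid="a")
    vb = make_indel(12, "C", "CTT", vid="b")
    vc = make_indel(20, "TGG", "T", vid="c")

    def build(order):
        tvg = init_tvg(seq, has_known_orf=False)
        for v in order:
            apply_variant(tvg, v)
        return tvg

    t1 = build([va, vb, vc])
    t2 = build([vc, va, vb])

    def shape(tvg):
        out = []
        for k in (0, 1, 2):
            for node in tvg._chain_nodes[k]:
                alts = sorted(
                    (a.seq, a.frame, a.variants[0].variant_id)
                    for a in node.out_nodes
                    if a.variants
                )
                out.append((k, node.seq, tuple(alts)))
        return out

    assert shape(t1) == shape(t2)
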