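"""Transcript variant graph (TVG).

The TVG holds three reading-frame subgraphs over one transcript (or
fusion/circRNA backbone) sequence.  Each subgraph ``k`` starts from a
root covering the transcript sequence with its first ``k`` nucleotides
trimmed, so that subgraph-local codon boundaries fall at transcript
positions ``≡ k (mod 3)``.  A variant is spliced in by breaking the
reference chain at its start and end and attaching an alternative node;
an in-frame variant closes back into the same subgraph, a frameshifting
variant closes into the subgraph given by :func:`outgoing_frame`, which
is exactly codon-phase bookkeeping:

    outgoing = (incoming + S_ref - S_alt) mod 3

For transcripts with a known ORF, variants are incorporated into the
canonical frame's subgraph and into any subgraph already entered by an
upstream frameshift; for unknown-ORF transcripts they go into all three.

Alternative-splicing insertions and substitutions become depth-1
subgraphs of reference-typed nodes (tagged with a ``subgraph_id``) that
can carry their own nested small variants.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .gvf import VariantRecord

__all__ = [
    "TVGNode",
    "TVG",
    "AppliedVariant",
    "init_tvg",
    "outgoing_frame",
    "apply_variant",
    "apply_alt_splice",
    "exclude_edge_case_variants",
]


def outgoing_frame(s_ref: int, s_alt: int, incoming_frame: int) -> int:
    """Reading-frame subgraph index downstream of a variant.

    Floor-mod keeps the result in {0, 1, 2} also for insertions, where
    ``S_ref - S_alt`` is negative.
    """
    if s_ref < 0 or s_alt < 0:
        raise ValueError("sequence lengths must be non-negative")
    if incoming_frame not in (0, 1, 2):
        raise ValueError(f"invalid frame {incoming_frame}")
    return (incoming_frame + s_ref - s_alt) % 3


class TVGNode:
    """A transcript fragment with a reference or alternative sequence."""

    __slots__ = (
        "seq",
        "frame",
        "ref_start",
        "variants",
        "subgraph_id",
        "out_nodes",
        "in_nodes",
    )

    def __init__(
        self,
        seq: str,
        frame: int,
        ref_start: int | None = None,
        variants: tuple[VariantRecord, ...] = (),
        subgraph_id: str | None = None,
    ):
        self.seq = seq
        self.frame = frame
        self.ref_start = ref_start
        self.variants = variants
        self.subgraph_id = subgraph_id
        self.out_nodes: list[TVGNode] = []
        self.in_nodes: list[TVGNode] = []

    @property
    def is_reference(self) -> bool:
        return not self.variants

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        kind = "ref" if self.is_reference else "alt"
        return f"<TVGNode {kind} f{self.frame} {self.seq[:12]!r} @{self.ref_start}>"


def _link(a: TVGNode, b: TVGNode) -> None:
    if b not in a.out_nodes:
        a.out_nodes.append(b)
        b.in_nodes.append(a)


def edge_type(a: TVGNode, b: TVGNode) -> str:
    """Edge classification: variant_open / variant_close / reference_elongation."""
    if b.variants:
        return "variant_open"
    if a.variants:
        return "variant_close"
    return "reference_elongation"


@dataclass(frozen=True)
class AppliedVariant:
    """A top-level variant plus any variants nested in its insertion."""

    record: VariantRecord
    nested: tuple[VariantRecord, ...] = ()

    @property
    def start(self) -> int:
        return self.record.start_tx

    @property
    def end(self) -> int:
        return self.record.end_tx


class TVG:
    """Three reading-frame subgraphs over one backbone sequence."""

    def __init__(self, tx_seq: str, has_known_orf: bool, cds_start: int | None = None):
        if not tx_seq:
            raise ValueError("empty transcript sequence")
        self.tx_seq = tx_seq
        self.has_known_orf = has_known_orf
        self.cds_start = cds_start
        self.applied: list[AppliedVariant] = []
        # per-frame reference chain: sorted starts + nodes
        self._chain_starts: dict[int, list[int]] = {}
        self._chain_nodes: dict[int, list[TVGNode]] = {}
        self.roots: dict[int, TVGNode] = {}
        for k in (0, 1, 2):
            node = TVGNode(tx_seq[k:], frame=k, ref_start=k if len(tx_seq) > k else None)
            self.roots[k] = node
            self._chain_starts[k] = [k]
            self._chain_nodes[k] = [node]
        # frames where variants are incorporated; position from which active
        if has_known_orf:
            if cds_start is None:
                raise ValueError("known-ORF graph requires cds_start")
            self.active_from: dict[int, int] = {cds_start % 3: 0}
        else:
            self.active_from = {0: 0, 1: 0, 2: 0}

    # -- reference chain surgery ------------------------------------------

    def _node_at(self, frame: int, pos: int) -> TVGNode:
        starts = self._chain_starts[frame]
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            raise ValueError(f"position {pos} precedes frame {frame} root")
        return self._chain_nodes[frame][i]

    def split_chain(self, frame: int, pos: int) -> None:
        """Ensure a reference-node boundary at transcript position ``pos``."""
        if pos >= len(self.tx_seq) or pos <= frame:
            return
        starts = self._chain_starts[frame]
        i = bisect.bisect_right(starts, pos) - 1
        node = self._chain_nodes[frame][i]
        if starts[i] == pos:
            return
        off = pos - starts[i]
        left = TVGNode(node.seq[:off], frame, ref_start=starts[i])
        node.seq = node.seq[off:]
        node.ref_start = pos
        for p in list(node.in_nodes):
            p.out_nodes[p.out_nodes.index(node)] = left
            left.in_nodes.append(p)
        node.in_nodes = []
        _link(left, node)
        if self.roots[frame] is node:
            self.roots[frame] = left
        starts.insert(i + 1, pos)
        self._chain_nodes[frame].insert(i + 1, node)
        self._chain_nodes[frame][i] = left

    def reference_path_sequence(self, frame: int) -> str:
        """Concatenation of the reference chain of one frame subgraph."""
        return "".join(n.seq for n in self._chain_nodes[frame])

    def frames_active_at(self, pos: int) -> list[int]:
        return sorted(k for k, p in self.active_from.items() if p <= pos)

    def _activate(self, frame: int, pos: int) -> None:
        if frame not in self.active_from:
            self.active_from[frame] = pos

    # -- variant incorporation --------------------------------------------

    def _splice_alt(
        self, frame: int, applied: AppliedVariant
    ) -> None:
        v = applied.record
        if v.start_tx < frame:
            return  # not representable in a subgraph rooted downstream
        self.split_chain(frame, v.start_tx)
        self.split_chain(frame, v.end_tx)
        k_out = outgoing_frame(v.s_ref, v.s_alt, frame)
        if k_out != frame:
            self.split_chain(k_out, v.end_tx)
            self._activate(k_out, v.end_tx)
        upstream = (
            self._node_at(frame, v.start_tx - 1) if v.start_tx > frame else None
        )
        if v.end_tx < len(self.tx_seq):
            downstream = self._node_at(k_out, max(v.end_tx, k_out))
        else:
            downstream = None

        entry, exit_ = self._build_alt_nodes(frame, applied)
        if upstream is not None:
            _link(upstream, entry)
        if downstream is not None:
            _link(exit_, downstream)

    def _build_alt_nodes(
        self, frame: int, applied: AppliedVariant
    ) -> tuple[TVGNode, TVGNode]:
        """Alt node, or a depth-1 subgraph chain for alt-splice insertions."""
        v = applied.record
        if not applied.nested:
            node = TVGNode(v.alt_seq, frame, variants=(v,),
                           subgraph_id=v.variant_id if v.is_alt_splice else None)
            return node, node
        # reference-typed subgraph over the inserted sequence
        sg = v.variant_id
        cuts = {0, len(v.alt_seq)}
        for n in applied.nested:
            cuts.add(n.start_tx)
            cuts.add(n.end_tx)
        bounds = sorted(cuts)
        seg_nodes: dict[int, TVGNode] = {}
        prev = None
        for a, b in zip(bounds, bounds[1:]):
            node = TVGNode(v.alt_seq[a:b], frame, variants=(v,), subgraph_id=sg)
            seg_nodes[a] = node
            if prev is not None:
                _link(prev, node)
            prev = node
        entry = seg_nodes[bounds[0]]
        exit_ = seg_nodes[bounds[-2]] if len(bounds) > 1 else entry
        for n in applied.nested:
            alt = TVGNode(n.alt_seq, frame, variants=(v, n), subgraph_id=sg)
            if n.start_tx > 0:
                up = seg_nodes[
                    bounds[bisect.bisect_left(bounds, n.start_tx) - 1]
                ]
                _link(up, alt)
            if n.end_tx < len(v.alt_seq):
                _link(alt, seg_nodes[n.end_tx])
        return entry, exit_


def init_tvg(tx_seq: str, tx_model=None, has_known_orf: bool | None = None,
             cds_start: int | None = None) -> TVG:
    """Instantiate the three-frame graph for a backbone sequence."""
    if tx_model is not None:
        has_known_orf = tx_model.is_coding
        cds_start = tx_model.cds_start_tx
    if has_known_orf is None:
        has_known_orf = False
    return TVG(tx_seq, has_known_orf=has_known_orf, cds_start=cds_start)


def apply_variant(tvg: TVG, v: VariantRecord) -> TVG:
    """Splice one small variant into every applicable frame subgraph."""
    if v.parent_id is not None:
        raise ValueError(
            f"{v.variant_id}: nested variant must be applied with its parent "
            "via apply_alt_splice"
        )
    v.validate_against(tvg.tx_seq)
    applied = AppliedVariant(record=v)
    for frame in tvg.frames_active_at(v.start_tx):
        tvg._splice_alt(frame, applied)
    tvg.applied.append(applied)
    return tvg


def apply_alt_splice(
    tvg: TVG, v: VariantRecord, nested: list[VariantRecord] | None = None
) -> TVG:
    """Splice an alternative-splicing variant, optionally with nested variants.

    Nested variants use offsets into ``v.alt_seq``; deeper nesting is
    rejected.
    """
    if not v.is_alt_splice:
        raise ValueError(f"{v.variant_id}: not an alternative-splicing variant")
    v.validate_against(tvg.tx_seq)
    nested = sorted(nested or [], key=lambda n: (n.start_tx, n.end_tx))
    for n in nested:
        if n.parent_id != v.variant_id:
            raise ValueError(f"{n.variant_id}: parent_id does not match {v.variant_id}")
        n.validate_against(v.alt_seq)
    applied = AppliedVariant(record=v, nested=tuple(nested))
    for frame in tvg.frames_active_at(v.start_tx):
        tvg._splice_alt(frame, applied)
    tvg.applied.append(applied)
    return tvg


_SPLICE_CONSEQUENCES = ("splice_acceptor", "splice_donor")


def exclude_edge_case_variants(
    variants: list[VariantRecord],
    tx_model=None,
    cds_start: int | None = None,
    cds_end: int | None = None,
    consequences: dict[str, tuple[str, ...]] | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Apply the biological edge-case exclusion rules.

    For known-ORF transcripts: variants overlapping the annotated start
    codon are excluded (translation-start uncertainty), as are variants
    wholly 5' of the ORF or 3' of the annotated stop codon (they cannot
    change the protein, since translation never extends beyond the
    transcript).  Stop-codon-altering variants are kept; the caller later
    truncates at the last complete peptide.  Splice-site-altering
    variants are excluded via their annotated consequence strings; the
    geometric part of that rule lives in the genomic parsers, which only
    admit fully exonic variants.
    """
    if tx_model is not None and tx_model.is_coding:
        cds_start = tx_model.cds_start_tx
        cds_end = tx_model.cds_end_tx
    kept: list[VariantRecord] = []
    excluded: list[tuple[VariantRecord, str]] = []
    for v in variants:
        csq = (consequences or {}).get(v.variant_id, ())
        if any(s in c for c in csq for s in _SPLICE_CONSEQUENCES):
            excluded.append((v, "splice-site-altering"))
            continue
        if cds_start is not None and v.parent_id is None:
            if v.end_tx <= cds_start:
                excluded.append((v, "5'-of-ORF"))
                continue
            if v.start_tx < cds_start + 3:
                excluded.append((v, "start-codon-altering"))
                continue
            if cds_end is not None and v.start_tx >= cds_end + 3:
                excluded.append((v, "3'-of-stop"))
                continue
        kept.append(v)
    return kept, excluded
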