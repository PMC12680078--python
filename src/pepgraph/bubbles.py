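"""Variant bubble alignment.

Variants whose transcript spans overlap, or sit closer than one
connection node's worth of reference sequence (five nucleotides), are
aligned into a *variant bubble*: all pairwise-compatible variant
combinations between two shared reference anchors, each combination
merged into a single node.  Member node lengths are then adjusted to
multiples of three by taking nucleotides from the anchors, so that every
aligned node translates as whole codons on its frame subgraph's codon
grid.

A frameshifting member re-anchors in the frame subgraph given by the
frame formula; anchors are therefore built per frame, and the aligned
result is a three-chain lattice: ``anchor(k, j) -> members(cluster j+1
entered in frame k) -> anchor(k', j+1)``.

Path enumeration over a bubble is the graph-route counterpart of the
brute-force subset enumeration: compatibility is encoded structurally
(a path can only visit variants with non-overlapping spans, and nested
variants only inside their parent's inserted sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gvf import VariantRecord
from .tvg import TVG, AppliedVariant

__all__ = [
    "PathOption",
    "Cluster",
    "VariantBubble",
    "AlignedNode",
    "AlignedGraph",
    "compute_clusters",
    "cluster_paths",
    "find_next_connection_node",
    "align_bubble",
    "adjust_to_codon_boundary",
    "build_aligned_graph",
    "MIN_ANCHOR_LEN",
]

MIN_ANCHOR_LEN = 5  # connection nodes must be at least this many nucleotides


@dataclass(frozen=True)
class PathOption:
    """One variant combination through a bubble, merged to a single node."""

    seq: str
    origins: tuple  # per-base reference transcript position or None
    base_vars: tuple  # per-base frozenset of variant ids
    var_ids: frozenset

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Cluster:
    """A maximal group of variants closer than MIN_ANCHOR_LEN apart."""

    items: list[AppliedVariant]
    start: int
    end: int


@dataclass
class VariantBubble:
    upstream: object
    downstream: object
    frame: int
    cluster: Cluster
    members: list[PathOption]
    tx_seq: str = ""
    d_up: int = 0
    d_down_by_outframe: dict = field(default_factory=dict)


def compute_clusters(
    applied: list[AppliedVariant], min_anchor_len: int = MIN_ANCHOR_LEN
) -> list[Cluster]:
    """Group variants into bubbles separated by >= min_anchor_len reference nt."""
    clusters: list[Cluster] = []
    for av in sorted(applied, key=lambda a: (a.start, a.end)):
        if clusters and av.start - clusters[-1].end < min_anchor_len:
            clusters[-1].items.append(av)
            clusters[-1].end = max(clusters[-1].end, av.end)
        else:
            clusters.append(Cluster(items=[av], start=av.start, end=av.end))
    return clusters


def _alt_options(av: AppliedVariant) -> list[tuple[str, tuple, tuple, frozenset]]:
    """Alternative-sequence pieces for one applied variant.

    A plain variant yields one option; an alternative-splicing variant
    with nested small variants yields one option per compatible nested
    subset, enumerated over the inserted sequence.
    """
    v = av.record
    base = frozenset({v.variant_id})
    if not av.nested:
        n = len(v.alt_seq)
        return [(v.alt_seq, (None,) * n, (base,) * n, base)]
    options = []
    for sub in _paths(
        [AppliedVariant(n) for n in av.nested], 0, len(v.alt_seq), v.alt_seq,
        track_origins=False,
    ):
        ids = base | sub.var_ids
        bvars = tuple(bv | base for bv in sub.base_vars)
        options.append((sub.seq, (None,) * len(sub.seq), bvars, ids))
    return options


def _paths(
    items: list[AppliedVariant],
    a: int,
    b: int,
    refseq: str,
    track_origins: bool = True,
) -> list[PathOption]:
    """All compatible variant combinations over ``refseq[a:b]``.

    Items must be sorted by (start, end).  Compatibility is positional:
    a path visits items left to right and an item is reachable only if
    its span starts at or after the current position; two zero-length
    insertions at the same point are mutually exclusive.
    """
    items = sorted(items, key=lambda x: (x.start, x.end))
    out: list[PathOption] = []

    def ref_piece(x: int, y: int):
        seq = refseq[x:y]
        origins = tuple(range(x, y)) if track_origins else (None,) * (y - x)
        return (seq, origins, (frozenset(),) * (y - x), frozenset())

    def rec(i: int, p: int, pieces: list, ids: frozenset, zero_pt):
        if i == len(items):
            out.append(_merge_pieces(pieces + [ref_piece(p, b)], ids))
            return
        av = items[i]
        rec(i + 1, p, pieces, ids, zero_pt)  # exclude
        if av.start < p:
            return
        if av.start == av.end == zero_pt:
            return  # two insertions at the same point are disjoint
        lead = ref_piece(p, av.start)
        for alt in _alt_options(av):
            rec(
                i + 1,
                av.end,
                pieces + [lead, alt],
                ids | alt[3],
                av.end if av.start == av.end else None,
            )

    rec(0, a, [], frozenset(), None)
    return out


def _merge_pieces(pieces: list, ids: frozenset) -> PathOption:
    seq_parts: list[str] = []
    origins: list = []
    base_vars: list = []
    pending: frozenset = frozenset()
    for seq, orig, bvars, piece_ids in pieces:
        if not seq:
            # a pure deletion annotates the next emitted base
            pending = pending | piece_ids
            continue
        seq_parts.append(seq)
        origins.extend(orig)
        if pending:
            base_vars.append(bvars[0] | pending)
            base_vars.extend(bvars[1:])
            pending = frozenset()
        else:
            base_vars.extend(bvars)
    if pending and base_vars:
        base_vars[-1] = base_vars[-1] | pending
    return PathOption(
        seq="".join(seq_parts),
        origins=tuple(origins),
        base_vars=tuple(base_vars),
        var_ids=ids,
    )


def cluster_paths(cluster: Cluster, tx_seq: str) -> list[PathOption]:
    """All member paths (reference included) through one bubble's span."""
    return _paths(cluster.items, cluster.start, cluster.end, tx_seq)


# -- spec-shaped graph operations -----------------------------------------


def find_next_connection_node(tvg: TVG, from_node):
    """First common downstream reference node of length >= 5 nt.

    ``from_node`` must be a connection node (the frame root qualifies).
    The chain sink terminates the search and is itself returned as the
    terminal connection node.
    """
    frame = from_node.frame
    pos = from_node.ref_start if from_node.ref_start is not None else frame
    clusters = compute_clusters(tvg.applied)
    nxt = None
    for c in clusters:
        if c.start >= pos + max(1, len(from_node.seq)):
            nxt = c
            break
    chain = tvg._chain_nodes[frame]
    if nxt is None:
        return chain[-1]
    tvg.split_chain(frame, nxt.end)
    node = tvg._node_at(frame, max(nxt.end, frame))
    # by cluster construction the node reaches the next bubble or the sink;
    # a short trailing run only occurs at the sink, which qualifies anyway
    return node


def align_bubble(tvg: TVG, upstream, downstream) -> VariantBubble:
    """Merge all variant combinations between two connection nodes."""
    up_end = (upstream.ref_start or 0) + len(upstream.seq)
    down_start = downstream.ref_start if downstream.ref_start is not None else len(
        tvg.tx_seq
    )
    items = [
        av
        for av in tvg.applied
        if av.start >= upstream.ref_start and av.end <= down_start
    ]
    if not items:
        cluster = Cluster(items=[], start=up_end, end=up_end)
    else:
        cluster = Cluster(
            items=items,
            start=min(av.start for av in items),
            end=max(av.end for av in items),
        )
    members = cluster_paths(cluster, tvg.tx_seq)
    return VariantBubble(
        upstream=upstream,
        downstream=downstream,
        frame=upstream.frame,
        cluster=cluster,
        members=members,
        tx_seq=tvg.tx_seq,
    )


def adjust_to_codon_boundary(bubble: VariantBubble) -> VariantBubble:
    """Extend members with anchor nucleotides to whole-codon lengths.

    The upstream boundary snaps down to the incoming frame's codon grid
    and each member's downstream boundary snaps up to its own outgoing
    frame's grid, so frameshifting members resolve in their own frame
    subgraphs with no cross-frame merging.
    """
    k = bubble.frame
    cs, ce = bubble.cluster.start, bubble.cluster.end
    d_up = (cs - k) % 3
    tx_seq = bubble.tx_seq
    if not tx_seq:
        raise ValueError("bubble carries no transcript context")
    adjusted: list[PathOption] = []
    d_down_by_outframe: dict[int, int] = {}
    for m in bubble.members:
        shift = (ce - cs) - len(m.seq)
        k_out = (k + shift) % 3
        d_down = (k_out - ce) % 3
        d_down_by_outframe[k_out] = d_down
        lead = tx_seq[cs - d_up : cs]
        tail = tx_seq[ce : ce + d_down]
        adjusted.append(
            PathOption(
                seq=lead + m.seq + tail,
                origins=tuple(range(cs - d_up, cs)) + m.origins
                + tuple(range(ce, ce + len(tail))),
                base_vars=(frozenset(),) * len(lead)
                + m.base_vars
                + (frozenset(),) * len(tail),
                var_ids=m.var_ids,
            )
        )
    return VariantBubble(
        upstream=bubble.upstream,
        downstream=bubble.downstream,
        frame=k,
        cluster=bubble.cluster,
        members=adjusted,
        tx_seq=tx_seq,
        d_up=d_up,
        d_down_by_outframe=d_down_by_outframe,
    )


# -- aligned lattice graph -------------------------------------------------


class AlignedNode:
    """A whole-codon nucleotide node of the aligned (bubble-merged) graph."""

    __slots__ = (
        "seq",
        "origins",
        "base_vars",
        "chain",
        "out_chain",
        "var_ids",
        "kind",
        "ends_transcript",
        "tx_start",
        "succ",
    )

    def __init__(self, seq, origins, base_vars, chain, out_chain, var_ids, kind,
                 ends_transcript=False, tx_start=None):
        self.seq = seq
        self.origins = origins
        self.base_vars = base_vars
        self.chain = chain
        self.out_chain = out_chain
        self.var_ids = var_ids
        self.kind = kind
        self.ends_transcript = ends_transcript
        self.tx_start = tx_start
        self.succ: list[AlignedNode] = []

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<{self.kind} c{self.chain}->{self.out_chain} {self.seq[:15]!r}"
            f"{' $' if self.ends_transcript else ''}>"
        )


class AlignedGraph:
    def __init__(self, entries: list[AlignedNode], nodes: list[AlignedNode],
                 known_orf: bool):
        self.entries = entries
        self.nodes = nodes
        self.known_orf = known_orf


def build_aligned_graph(tvg: TVG, sec_positions=frozenset()) -> AlignedGraph:
    """Collapse the TVG's bubbles into the three-chain aligned lattice."""
    L = len(tvg.tx_seq)
    clusters = compute_clusters(tvg.applied)
    k0 = (tvg.cds_start % 3) if tvg.has_known_orf else None
    m = len(clusters)

    def chain_start(k: int) -> int:
        if tvg.has_known_orf and k == k0:
            return tvg.cds_start
        return k

    # anchor spans per (chain, slot); slot j is the anchor after cluster j
    anchors: dict[tuple[int, int], AlignedNode] = {}
    nodes: list[AlignedNode] = []
    for k in (0, 1, 2):
        for j in range(m + 1):
            if j == 0:
                a = chain_start(k)
            else:
                ce = clusters[j - 1].end
                a = ce + ((k - ce) % 3)
            if j < m:
                cs = clusters[j].start
                b = cs - ((cs - k) % 3)
            else:
                b = L
            if a > b:
                # the cluster reaches past this chain's grid point; only
                # possible at the transcript end
                a = b
            node = AlignedNode(
                seq=tvg.tx_seq[a:b],
                origins=tuple(range(a, b)),
                base_vars=(frozenset(),) * (b - a),
                chain=k,
                out_chain=k,
                var_ids=frozenset(),
                kind="anchor",
                ends_transcript=(j == m),
                tx_start=a,
            )
            anchors[(k, j)] = node
            nodes.append(node)

    for j, cluster in enumerate(clusters):
        cs, ce = cluster.start, cluster.end
        paths = cluster_paths(cluster, tvg.tx_seq)
        for k in (0, 1, 2):
            d_up = (cs - k) % 3
            lead = tvg.tx_seq[cs - d_up : cs]
            for p in paths:
                shift = (ce - cs) - len(p.seq)
                k_out = (k + shift) % 3
                d_down = (k_out - ce) % 3
                me = ce + d_down
                terminal = me > L
                tail = tvg.tx_seq[ce : min(me, L)]
                member = AlignedNode(
                    seq=lead + p.seq + tail,
                    origins=tuple(range(cs - d_up, cs)) + p.origins
                    + tuple(range(ce, ce + len(tail))),
                    base_vars=(frozenset(),) * len(lead)
                    + p.base_vars
                    + (frozenset(),) * len(tail),
                    chain=k,
                    out_chain=k_out,
                    var_ids=p.var_ids,
                    kind="member",
                    ends_transcript=terminal,
                    tx_start=cs - d_up,
                )
                nodes.append(member)
                anchors[(k, j)].succ.append(member)
                if not terminal:
                    member.succ.append(anchors[(k_out, j + 1)])

    if tvg.has_known_orf:
        entries = [anchors[(k0, 0)]]
    else:
        entries = [anchors[(k, 0)] for k in (0, 1, 2) if chain_start(k) < L]
    return AlignedGraph(entries=entries, nodes=nodes, known_orf=tvg.has_known_orf)
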