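"""Peptide variant graph (PVG) and peptide cleavage graph (PCG).

``translate_graph`` turns the aligned nucleotide lattice into amino-acid
nodes (the PVG): every aligned node is whole-codon on its frame
subgraph's grid, so codons never straddle node boundaries and stop
codons are detectable node-locally.  TGA codons whose first base
originates from an annotated selenocysteine position read as ``U``;
codons containing ``N`` read as ``X``.

``to_cleavage_graph`` converts the PVG into the PCG, in which every edge
is an enzymatic cleavage site and node interiors contain no site.  The
conversion is a stage-and-call forward pass in topological order: each
PVG node is visited after all its predecessors, carrying

* the open peptide segment(s) since the last cleavage site (node
  boundaries with no site between them merge into one PCG node, which is
  how cleavage motifs spanning node boundaries — e.g. trypsin's K/P
  suppression and WK/P override — are resolved with up to two residues
  of upstream context);
* the residue context for cut decisions;
* ORF state: for known-ORF graphs a single ORF open from the annotated
  start; for unknown-ORF graphs every methionine in every frame subgraph
  opens a candidate ORF, with peptides attributed to the 5'-most
  compatible start and N-terminal peptides of nested starts emitted as
  their own segments;
* carried-over upstream frameshift variant annotations and
  cleavage-gain context.

Paths that end without a stop codon close their final segment with an
*open* C-terminus, which is never emitted: translation terminates at the
last complete peptide when the stop codon is unknown.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .bubbles import AlignedGraph, AlignedNode
from .enzymes import EnzymeSpec
from .reference import STANDARD_TABLE

__all__ = [
    "PVGNode",
    "PVG",
    "PCGNode",
    "PCG",
    "translate_graph",
    "to_cleavage_graph",
    "pop_and_collapse",
]


class PVGNode:
    __slots__ = (
        "aa",
        "res_vars",
        "res_orig",
        "var_ids",
        "fs_ids",
        "chain",
        "out_chain",
        "kind",
        "ends_transcript",
        "stop_terminated",
        "tx_start",
        "succ",
        "node_id",
    )

    def __init__(self, aa, res_vars, res_orig, var_ids, fs_ids, chain, out_chain,
                 kind, ends_transcript, stop_terminated, tx_start, node_id):
        self.aa = aa
        self.res_vars = res_vars
        self.res_orig = res_orig
        self.var_ids = var_ids
        self.fs_ids = fs_ids
        self.chain = chain
        self.out_chain = out_chain
        self.kind = kind
        self.ends_transcript = ends_transcript
        self.stop_terminated = stop_terminated
        self.tx_start = tx_start
        self.node_id = node_id
        self.succ: list[PVGNode] = []

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PVG {self.kind} c{self.chain} {self.aa[:12]!r}>"


class PVG:
    def __init__(self, entries, nodes, known_orf):
        self.entries = entries
        self.nodes = nodes
        self.known_orf = known_orf


def translate_graph(
    aligned: AlignedGraph, sec_positions=frozenset(), table=STANDARD_TABLE
) -> PVG:
    """Node-wise codon translation of the aligned lattice.

    In known-ORF graphs a stop codon truncates its node and severs the
    node's outgoing edges (every path through the node passes the stop);
    in unknown-ORF graphs ``*`` residues are kept so that downstream
    methionines can still open new ORFs.
    """
    mapping: dict[int, PVGNode] = {}
    nodes: list[PVGNode] = []
    for idx, an in enumerate(aligned.nodes):
        n_codons = len(an.seq) // 3
        aa_chars: list[str] = []
        res_vars: list[frozenset] = []
        res_orig: list = []
        stop_terminated = False
        for c in range(n_codons):
            i = 3 * c
            codon = an.seq[i : i + 3]
            orig = an.origins[i]
            if codon == "TGA" and orig is not None and orig in sec_positions:
                aa = "U"
            else:
                aa = table.amino_acid(codon)
            if aa == "*" and aligned.known_orf:
                stop_terminated = True
                aa_chars.append("*")
                res_vars.append(an.base_vars[i] | an.base_vars[i + 1] | an.base_vars[i + 2])
                res_orig.append(orig)
                break
            aa_chars.append(aa)
            res_vars.append(an.base_vars[i] | an.base_vars[i + 1] | an.base_vars[i + 2])
            res_orig.append(orig)
        fs = getattr(an, "fs_ids", frozenset())
        node = PVGNode(
            aa="".join(aa_chars),
            res_vars=tuple(res_vars),
            res_orig=tuple(res_orig),
            var_ids=an.var_ids,
            fs_ids=fs,
            chain=an.chain,
            out_chain=an.out_chain,
            kind=an.kind,
            ends_transcript=an.ends_transcript,
            stop_terminated=stop_terminated,
            tx_start=an.tx_start,
            node_id=idx,
        )
        if stop_terminated:
            node.aa = node.aa[:-1]  # '*' itself is not a residue
        mapping[id(an)] = node
        nodes.append(node)
    for an in aligned.nodes:
        node = mapping[id(an)]
        if node.stop_terminated:
            continue  # translation ends here for every path
        node.succ = [mapping[id(s)] for s in an.succ]
    entries = [mapping[id(e)] for e in aligned.entries]
    return PVG(entries=entries, nodes=nodes, known_orf=aligned.known_orf)


# -- PCG -------------------------------------------------------------------


class PCGNode:
    """One fully cleaved peptide segment; edges are cleavage sites."""

    __slots__ = ("seq", "n_term", "c_term", "orf", "sources", "succ", "node_id")

    def __init__(self, seq, n_term, c_term, orf, node_id):
        self.seq = seq
        self.n_term = n_term  # 'cut' | 'orf'
        self.c_term = c_term  # 'cut' | 'stop' | 'open'
        self.orf = orf  # (sort_key, label)
        self.sources: set[frozenset] = set()  # variant-id classes
        self.succ: set[int] = set()
        self.node_id = node_id

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PCG {self.seq!r} {self.n_term}->{self.c_term}>"


class PCG:
    def __init__(self):
        self.nodes: list[PCGNode] = []
        self._index: dict[tuple, int] = {}

    def get_or_create(self, key, seq, n_term, c_term, orf) -> PCGNode:
        idx = self._index.get(key)
        if idx is None:
            node = PCGNode(seq, n_term, c_term, orf, node_id=len(self.nodes))
            self.nodes.append(node)
            self._index[key] = node.node_id
            return node
        return self.nodes[idx]


@dataclass(frozen=True)
class _SegKey:
    seq: str
    n_term: str
    orf: tuple


@dataclass
class _SegAnn:
    classes: frozenset  # frozenset of frozensets of variant ids
    preds: frozenset  # pcg node ids


@dataclass(frozen=True)
class _StateKey:
    orf_open: bool
    ctx: str
    prev_vars: frozenset
    primary: _SegKey | None
    secondaries: tuple


@dataclass
class _StateAnn:
    carried: frozenset
    primary: _SegAnn | None
    secondaries: tuple


def _merge_ann(a: _StateAnn, b: _StateAnn) -> _StateAnn:
    def seg(x: _SegAnn | None, y: _SegAnn | None) -> _SegAnn | None:
        if x is None:
            return y
        if y is None:
            return x
        return _SegAnn(classes=x.classes | y.classes, preds=x.preds | y.preds)

    return _StateAnn(
        carried=a.carried | b.carried,
        primary=seg(a.primary, b.primary),
        secondaries=tuple(seg(x, y) for x, y in zip(a.secondaries, b.secondaries)),
    )


def _topo_order(pvg: PVG) -> list[PVGNode]:
    indeg: dict[int, int] = {n.node_id: 0 for n in pvg.nodes}
    for n in pvg.nodes:
        for s in n.succ:
            indeg[s.node_id] += 1
    by_id = {n.node_id: n for n in pvg.nodes}
    queue = deque(sorted(nid for nid, d in indeg.items() if d == 0))
    order = []
    while queue:
        nid = queue.popleft()
        node = by_id[nid]
        order.append(node)
        for s in node.succ:
            indeg[s.node_id] -= 1
            if indeg[s.node_id] == 0:
                queue.append(s.node_id)
    if len(order) != len(pvg.nodes):
        raise ValueError("cycle in peptide variant graph")
    return order


def to_cleavage_graph(
    pvg: PVG, enzyme: EnzymeSpec, max_segment_length: int | None = 25
) -> PCG:
    """Stage-and-call conversion of the PVG into the cleavage graph.

    ``max_segment_length`` prunes open segments longer than the maximum
    peptide length: such a segment can never be emitted (every peptide
    contains each of its cleavage segments entirely), so its content is
    replaced by an oversized sentinel.  This also merges traversal
    states in long cleavage-free stretches, bounding state growth.
    """
    pcg = PCG()
    entry_tables: dict[int, dict[_StateKey, _StateAnn]] = {
        n.node_id: {} for n in pvg.nodes
    }

    def add_state(node: PVGNode, key: _StateKey, ann: _StateAnn) -> None:
        table = entry_tables[node.node_id]
        if key in table:
            table[key] = _merge_ann(table[key], ann)
        else:
            table[key] = ann

    for e in pvg.entries:
        if pvg.known_orf:
            key = _StateKey(
                orf_open=True,
                ctx="",
                prev_vars=frozenset(),
                primary=_SegKey(seq="", n_term="orf", orf=(-1, "CDS")),
                secondaries=(),
            )
            ann = _StateAnn(
                carried=frozenset(),
                primary=_SegAnn(classes=frozenset({frozenset()}), preds=frozenset()),
                secondaries=(),
            )
        else:
            key = _StateKey(
                orf_open=False, ctx="", prev_vars=frozenset(),
                primary=None, secondaries=(),
            )
            ann = _StateAnn(carried=frozenset(), primary=None, secondaries=())
        add_state(e, key, ann)

    for node in _topo_order(pvg):
        for key, ann in sorted(
            entry_tables[node.node_id].items(), key=lambda kv: repr(kv[0])
        ):
            _scan_node(node, key, ann, pcg, enzyme, pvg.known_orf, add_state,
                       max_segment_length)
    return pcg


def _close_segment(
    pcg: PCG,
    node: PVGNode,
    idx: int,
    seg: _SegKey,
    seg_ann: _SegAnn,
    c_term: str,
) -> PCGNode:
    key = (node.node_id, idx, seg.seq, seg.n_term, c_term, seg.orf)
    pnode = pcg.get_or_create(key, seg.seq, seg.n_term, c_term, seg.orf)
    pnode.sources |= set(seg_ann.classes)
    for pid in seg_ann.preds:
        pcg.nodes[pid].succ.add(pnode.node_id)
    return pnode


_OVERSIZED = None  # sentinel segment content: too long to ever be a peptide


def _scan_node(
    node: PVGNode,
    key: _StateKey,
    ann: _StateAnn,
    pcg: PCG,
    enzyme: EnzymeSpec,
    known_orf: bool,
    add_state,
    max_segment_length: int | None = 25,
) -> None:
    orf_open = key.orf_open
    ctx = key.ctx
    prev_vars = key.prev_vars
    primary, primary_ann = key.primary, ann.primary
    secondaries = list(key.secondaries)
    sec_anns = list(ann.secondaries)
    carried = ann.carried

    if node.kind == "member" and node.chain != node.out_chain:
        carried = carried | node.fs_ids

    for i, r in enumerate(node.aa):
        if r == "*":
            # stop codon: every open segment ends here with a known C-terminus
            if orf_open and primary is not None and primary.seq:
                _close_segment(pcg, node, i, primary, primary_ann, "stop")
            for s, sa in zip(secondaries, sec_anns):
                if s.seq:
                    _close_segment(pcg, node, i, s, sa, "stop")
            orf_open = False
            primary, primary_ann = None, None
            secondaries, sec_anns = [], []
            ctx = ""
            prev_vars = frozenset()
            carried = frozenset()
            continue

        if (
            orf_open
            and primary is not None
            and (primary.seq is _OVERSIZED or primary.seq)
            and enzyme.is_cut(ctx, r)
        ):
            closed = []
            if primary.seq is not _OVERSIZED:
                closed.append(
                    _close_segment(pcg, node, i, primary, primary_ann, "cut")
                )
            for s, sa in zip(secondaries, sec_anns):
                closed.append(_close_segment(pcg, node, i, s, sa, "cut"))
            preds = frozenset(p.node_id for p in closed)
            # a fresh segment carries only upstream-frameshift and
            # cleavage-gain context, not the whole path's variant history
            gain = prev_vars | carried
            primary = _SegKey(seq="", n_term="cut", orf=primary.orf)
            primary_ann = _SegAnn(classes=frozenset({gain}), preds=preds)
            secondaries, sec_anns = [], []

        if not known_orf and r == "M":
            orf_key = node.res_orig[i]
            if orf_key is None:
                orf_key = (node.tx_start or 0)
            orf = (orf_key, f"ORF{orf_key}:{node.chain}")
            if not orf_open:
                orf_open = True
                primary = _SegKey(seq="", n_term="orf", orf=orf)
                primary_ann = _SegAnn(
                    classes=frozenset({carried}), preds=frozenset()
                )
                ctx = ""
            else:
                secondaries.append(_SegKey(seq="", n_term="orf", orf=orf))
                sec_anns.append(
                    _SegAnn(classes=frozenset({carried}), preds=frozenset())
                )

        if orf_open:
            rv = node.res_vars[i]
            new_seq = (
                _OVERSIZED
                if primary.seq is _OVERSIZED
                or (max_segment_length is not None
                    and len(primary.seq) >= max_segment_length)
                else primary.seq + r
            )
            primary = _SegKey(seq=new_seq, n_term=primary.n_term, orf=primary.orf)
            if new_seq is _OVERSIZED:
                primary_ann = _SegAnn(classes=frozenset(), preds=frozenset())
            else:
                primary_ann = _SegAnn(
                    classes=frozenset(
                        {cls | rv | carried for cls in primary_ann.classes}
                    ),
                    preds=primary_ann.preds,
                )
            kept_secondaries, kept_anns = [], []
            for s, sa in zip(secondaries, sec_anns):
                if max_segment_length is not None and len(s.seq) >= max_segment_length:
                    continue  # the nested ORF's first peptide is over-long
                kept_secondaries.append(
                    _SegKey(seq=s.seq + r, n_term=s.n_term, orf=s.orf)
                )
                kept_anns.append(
                    _SegAnn(
                        classes=frozenset(
                            {cls | rv | carried for cls in sa.classes}
                        ),
                        preds=sa.preds,
                    )
                )
            secondaries, sec_anns = kept_secondaries, kept_anns
            ctx = (ctx + r)[-2:]
            prev_vars = rv

    if not node.succ:
        # path ends: a stop-terminated node closed above via '*', unless the
        # known-ORF truncation removed the '*' residue itself
        c_term = "stop" if node.stop_terminated else "open"
        end = len(node.aa)
        if orf_open and primary is not None and primary.seq:
            _close_segment(pcg, node, end, primary, primary_ann, c_term)
        for s, sa in zip(secondaries, sec_anns):
            if s.seq:
                _close_segment(pcg, node, end, s, sa, c_term)
        return

    out_key = _StateKey(
        orf_open=orf_open,
        ctx=ctx,
        prev_vars=prev_vars,
        primary=primary,
        secondaries=tuple(secondaries),
    )
    out_ann = _StateAnn(
        carried=carried, primary=primary_ann, secondaries=tuple(sec_anns)
    )
    for s in node.succ:
        add_state(s, out_key, out_ann)


# -- pop-and-collapse ------------------------------------------------------


def pop_and_collapse(
    members: list[PVGNode], x: int, cutoff: int
) -> list[PVGNode]:
    """Bound bubble blowup by sharing identical member suffixes.

    When more than ``cutoff`` member nodes sit between two anchors, the
    last ``x`` residues of each member are split into suffix nodes and
    suffix nodes with identical sequence (and identical continuation)
    are merged, unioning their variant annotations.  The peptide
    multiset callable from the graph is unchanged: prefix and suffix
    concatenate to the original member along the only path through them.

    Returns the replacement member (prefix) nodes; the shared suffix
    nodes are reachable through their successors.
    """
    if len(members) <= cutoff:
        return members
    shortest = min(len(m.aa) for m in members)
    if x >= shortest:
        x = max(shortest - 1, 0)
    if x == 0:
        return members
    suffixes: dict[tuple, PVGNode] = {}
    out: list[PVGNode] = []
    next_id = max(m.node_id for m in members) + 1
    for m in members:
        cut = len(m.aa) - x
        skey = (
            m.aa[cut:],
            m.out_chain,
            tuple(sorted(s.node_id for s in m.succ)),
            m.ends_transcript,
            m.stop_terminated,
        )
        if skey not in suffixes:
            suffix = PVGNode(
                aa=m.aa[cut:],
                res_vars=m.res_vars[cut:],
                res_orig=tuple([None] * x),
                var_ids=m.var_ids,
                fs_ids=frozenset(),
                chain=m.out_chain,
                out_chain=m.out_chain,
                kind="member",
                ends_transcript=m.ends_transcript,
                stop_terminated=m.stop_terminated,
                tx_start=None,
                node_id=next_id,
            )
            next_id += 1
            suffix.succ = list(m.succ)
            suffixes[skey] = suffix
        else:
            suffix = suffixes[skey]
            suffix.res_vars = tuple(
                a | b for a, b in zip(suffix.res_vars, m.res_vars[cut:])
            )
            suffix.var_ids = suffix.var_ids | m.var_ids
        prefix = PVGNode(
            aa=m.aa[:cut],
            res_vars=m.res_vars[:cut],
            res_orig=m.res_orig[:cut],
            var_ids=m.var_ids,
            fs_ids=m.fs_ids,
            chain=m.chain,
            out_chain=m.out_chain,
            kind="member",
            ends_transcript=False,
            stop_terminated=False,
            tx_start=m.tx_start,
            node_id=m.node_id,
        )
        prefix.succ = [suffix]
        out.append(prefix)
    return out
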