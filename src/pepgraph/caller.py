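"""Peptide calling from the cleavage graph, and database assembly.

The calling pipeline for one backbone (transcript, fusion or circRNA) is

    TVG -> aligned bubbles -> PVG -> PCG -> peptides

``stage_and_call`` reads zero-miscleavage peptides off PCG nodes,
``extend_miscleavages`` merges nodes across cleavage edges up to the
permitted miscleavage count, and the filters below enforce length
bounds, drop ``X``-containing products and remove anything the canonical
proteome can produce.  ``dedupe_and_annotate`` collapses identical
sequences across all their sources, and ``split_tiers`` partitions the
final database.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .bubbles import build_aligned_graph
from .enzymes import EnzymeSpec, digest, get_enzyme
from .gvf import VariantRecord
from .peptide_graph import PCG, PCGNode, PVG, pop_and_collapse, to_cleavage_graph, translate_graph
from .tvg import TVG, apply_alt_splice, apply_variant, exclude_edge_case_variants, init_tvg

__all__ = [
    "CallParams",
    "RawPeptide",
    "PeptideEntry",
    "TIER_ORDER",
    "stage_and_call",
    "extend_miscleavages",
    "find_novel_orfs",
    "filter_canonical",
    "dedupe_and_annotate",
    "split_tiers",
    "call_backbone",
    "call_transcript",
    "call_alt_translation",
    "canonical_digest",
    "entries_to_fasta",
    "entries_from_fasta",
    "raw_to_sources",
]

TIER_ORDER = (
    "Variant",
    "Noncoding",
    "NoncodingVariant",
    "CircularRNA",
    "AltTranslation",
)


@dataclass(frozen=True)
class CallParams:
    """Tunable calling parameters (defaults follow the tool's database mode)."""

    enzyme: str = "trypsin"
    max_miscleavage: int | None = 2
    min_length: int = 7
    max_length: int = 25
    pop_collapse_cutoff: int = 32
    pop_collapse_x: int = 5
    w_to_f_multi_site: bool = False

    def spec(self) -> EnzymeSpec:
        return get_enzyme(self.enzyme)

    def mc(self) -> int:
        if self.max_miscleavage is None:
            return self.spec().max_miscleavage
        return self.max_miscleavage


@dataclass(frozen=True)
class RawPeptide:
    seq: str
    variant_ids: frozenset
    orf: tuple
    miscleavages: int


@dataclass
class PeptideEntry:
    """A unique database peptide with all of its sources."""

    aa_seq: str
    # source: (gene_id, backbone_id, sorted variant ids, orf label, kind)
    sources: set = field(default_factory=set)
    tier: str = ""

    def add(self, source: tuple) -> None:
        self.sources.add(source)


def stage_and_call(pcg: PCG, params: CallParams) -> list[RawPeptide]:
    """Zero-miscleavage peptides: every PCG node with a valid C-terminus."""
    out = []
    for node in pcg.nodes:
        if node.c_term == "open":
            continue
        for cls in sorted(node.sources, key=sorted):
            out.append(RawPeptide(node.seq, cls, node.orf, 0))
    return out


def extend_miscleavages(
    pcg: PCG, params: CallParams
) -> list[RawPeptide]:
    """All peptides with up to the permitted number of miscleavages."""
    max_mc = params.mc()
    max_len = params.max_length
    out: list[RawPeptide] = []
    for start in pcg.nodes:
        if not start.seq:
            continue
        stack = [(start.seq, tuple(sorted(start.sources, key=sorted)), start, 0)]
        while stack:
            seq, classes, last, mc = stack.pop()
            if last.c_term != "open" and len(seq) <= max_len:
                for cls in classes:
                    out.append(RawPeptide(seq, cls, start.orf, mc))
            if mc < max_mc and len(seq) < max_len:
                for sid in sorted(last.succ):
                    nxt = pcg.nodes[sid]
                    combined = tuple(
                        sorted(
                            {c | d for c in classes for d in nxt.sources},
                            key=sorted,
                        )
                    ) or classes
                    stack.append((seq + nxt.seq, combined, nxt, mc + 1))
    return out


def find_novel_orfs(pcg: PCG) -> set[tuple]:
    """Candidate ORF starts discovered in the graph (unknown-ORF mode)."""
    return {n.orf for n in pcg.nodes if n.n_term == "orf"}


def filter_canonical(
    peptides: list[RawPeptide], canonical_set: set[str]
) -> list[RawPeptide]:
    """Drop peptides the canonical proteome digest can produce."""
    return [p for p in peptides if p.seq not in canonical_set]


def _length_and_residue_filter(
    peptides: list[RawPeptide], params: CallParams
) -> list[RawPeptide]:
    out = []
    for p in peptides:
        if not (params.min_length <= len(p.seq) <= params.max_length):
            continue
        if "X" in p.seq:
            continue
        out.append(p)
    return out


def canonical_digest(
    proteome: dict[str, str], params: CallParams
) -> set[str]:
    """Digest every canonical protein into the exclusion lookup set."""
    enzyme = params.spec()
    out: set[str] = set()
    for seq in proteome.values():
        seq = seq.rstrip("*")
        out |= digest(
            seq,
            enzyme,
            max_miscleavage=params.mc(),
            min_length=params.min_length,
            max_length=params.max_length,
            c_term_known=True,
        )
    return out


# -- per-backbone pipeline -------------------------------------------------


def call_backbone(
    backbone_seq: str,
    variants: list[VariantRecord],
    params: CallParams,
    *,
    coding: bool,
    cds_start: int | None = None,
    sec_positions=frozenset(),
    canonical_set: set[str] | None = None,
) -> list[RawPeptide]:
    """Run the full graph pipeline for one backbone sequence.

    ``variants`` must already be edge-case filtered and validated; nested
    (alternative-splicing) variants are grouped with their parents here.
    """
    tvg = init_tvg(backbone_seq, has_known_orf=coding, cds_start=cds_start)
    by_parent: dict[str, list[VariantRecord]] = {}
    tops: list[VariantRecord] = []
    for v in variants:
        if v.parent_id is None:
            tops.append(v)
        else:
            by_parent.setdefault(v.parent_id, []).append(v)
    for v in tops:
        nested = by_parent.pop(v.variant_id, [])
        if v.is_alt_splice:
            apply_alt_splice(tvg, v, nested)
        else:
            if nested:
                raise ValueError(
                    f"{v.variant_id}: nested variants on a non-splicing parent"
                )
            apply_variant(tvg, v)
    if by_parent:
        missing = sorted(by_parent)
        raise ValueError(f"nested variants with absent parents: {missing}")

    aligned = build_aligned_graph(tvg)
    pvg = translate_graph(aligned, sec_positions=frozenset(sec_positions))
    _apply_pop_collapse(pvg, params)
    pcg = to_cleavage_graph(pvg, params.spec(),
                            max_segment_length=params.max_length)
    peptides = extend_miscleavages(pcg, params)
    peptides = _length_and_residue_filter(peptides, params)
    if canonical_set:
        peptides = filter_canonical(peptides, canonical_set)
    return peptides


def _apply_pop_collapse(pvg: PVG, params: CallParams) -> None:
    """Compact oversized bubbles in place (peptide multiset preserved)."""
    changed = False
    for node in list(pvg.nodes):
        members = [s for s in node.succ if s.kind == "member"]
        if len(members) > params.pop_collapse_cutoff and all(m.aa for m in members):
            collapsed = pop_and_collapse(
                members, params.pop_collapse_x, params.pop_collapse_cutoff
            )
            node.succ = [s for s in node.succ if s.kind != "member"] + collapsed
            changed = True
    # rebuild the node list from reachability and renumber; this also prunes
    # frame-subgraph regions no entry can reach
    order: list = []
    seen: set[int] = set()
    stack = list(pvg.entries)
    while stack:
        n = stack.pop()
        if id(n) in seen:
            continue
        seen.add(id(n))
        order.append(n)
        stack.extend(n.succ)
    for i, n in enumerate(order):
        n.node_id = i
    pvg.nodes = order
    del changed


def call_transcript(
    tx_seq: str,
    variants: list[VariantRecord],
    params: CallParams,
    *,
    coding: bool,
    cds_start: int | None = None,
    cds_end: int | None = None,
    sec_positions=frozenset(),
    canonical_set: set[str] | None = None,
) -> list[RawPeptide]:
    """Edge-case filter, validate and call one linear transcript."""
    kept, _excluded = exclude_edge_case_variants(
        variants, cds_start=cds_start if coding else None,
        cds_end=cds_end if coding else None,
    )
    parents = {v.variant_id: v for v in kept if v.parent_id is None}
    usable = []
    for v in kept:
        if v.parent_id is None:
            v.validate_against(tx_seq)
            usable.append(v)
        elif v.parent_id in parents:
            v.validate_against(parents[v.parent_id].alt_seq)
            usable.append(v)
    return call_backbone(
        tx_seq,
        usable,
        params,
        coding=coding,
        cds_start=cds_start,
        sec_positions=sec_positions,
        canonical_set=canonical_set,
    )


# -- alternative translation ----------------------------------------------


def call_alt_translation(
    proteome: dict[str, str],
    mode: str,
    params: CallParams,
    canonical_set: set[str],
) -> list[tuple[str, str, str]]:
    """Selenocysteine-termination and W>F substitutant peptides.

    Returns (peptide, protein_id, mode) tuples not producible from the
    canonical digest.
    """
    enzyme = params.spec()
    out: list[tuple[str, str, str]] = []
    if mode == "selenocysteine_termination":
        for pid, seq in sorted(proteome.items()):
            seq = seq.rstrip("*")
            for i, aa in enumerate(seq):
                if aa != "U":
                    continue
                truncated = seq[:i]
                novel = digest(
                    truncated,
                    enzyme,
                    max_miscleavage=params.mc(),
                    min_length=params.min_length,
                    max_length=params.max_length,
                    c_term_known=True,  # the Sec codon read as stop is certain
                )
                for pep in sorted(novel - canonical_set):
                    out.append((pep, pid, mode))
    elif mode == "w_to_f":
        for pid, seq in sorted(proteome.items()):
            seq = seq.rstrip("*")
            peptides = digest(
                seq,
                enzyme,
                max_miscleavage=params.mc(),
                min_length=params.min_length,
                max_length=params.max_length,
                c_term_known=True,
            )
            for pep in sorted(peptides):
                sites = [i for i, aa in enumerate(pep) if aa == "W"]
                for i in sites:
                    sub = pep[:i] + "F" + pep[i + 1 :]
                    if sub not in canonical_set:
                        out.append((sub, pid, mode))
                if params.w_to_f_multi_site and len(sites) > 1:
                    sub = "".join("F" if aa == "W" else aa for aa in pep)
                    if sub not in canonical_set:
                        out.append((sub, pid, mode))
    else:
        raise ValueError(f"unknown alternative-translation mode {mode!r}")
    return out


def raw_to_sources(
    peptides: list[RawPeptide], gene_id: str, backbone_id: str, kind: str
) -> list[tuple[str, tuple]]:
    """Attach backbone provenance to raw peptides for database assembly."""
    out = []
    for p in peptides:
        orf_label = "CDS" if p.orf[1] == "CDS" else f"ORF{p.orf[0]}"
        source = (
            gene_id,
            backbone_id,
            tuple(sorted(p.variant_ids)),
            orf_label,
            kind,
        )
        out.append((p.seq, source))
    return out


# -- database assembly -----------------------------------------------------


def _source_tier(kind: str, variant_ids: tuple) -> str:
    if kind == "alt_translation":
        return "AltTranslation"
    if kind == "circ":
        return "CircularRNA"
    if kind in ("coding_tx", "fusion_coding"):
        return "Variant"
    if kind in ("noncoding_tx", "fusion_noncoding"):
        return "NoncodingVariant" if variant_ids else "Noncoding"
    raise ValueError(f"unclassifiable source kind {kind!r}")


def dedupe_and_annotate(
    called: list[tuple[str, tuple]],
) -> dict[str, PeptideEntry]:
    """One entry per unique sequence; sources unioned.

    ``called`` holds (peptide, source) pairs where source is
    (gene_id, backbone_id, variant_ids, orf_label, kind).
    """
    entries: dict[str, PeptideEntry] = {}
    for seq, source in called:
        entry = entries.get(seq)
        if entry is None:
            entry = PeptideEntry(aa_seq=seq)
            entries[seq] = entry
        entry.add(source)
    for entry in entries.values():
        tiers = {_source_tier(s[4], s[2]) for s in entry.sources}
        entry.tier = next(t for t in TIER_ORDER if t in tiers)
    return entries


def split_tiers(
    entries: dict[str, PeptideEntry]
) -> dict[str, list[PeptideEntry]]:
    """Disjoint partition of the database by highest-priority source tier."""
    out: dict[str, list[PeptideEntry]] = {t: [] for t in TIER_ORDER}
    for seq in sorted(entries):
        entry = entries[seq]
        out[entry.tier].append(entry)
    return out


def _format_source(source: tuple) -> str:
    gene, backbone, var_ids, orf, kind = source
    vids = ";".join(var_ids) if var_ids else "."
    return f"{gene}|{backbone}|{vids}|{orf}|{kind}"


def _parse_source(block: str) -> tuple:
    gene, backbone, vids, orf, kind = block.split("|")
    var_ids = () if vids == "." else tuple(vids.split(";"))
    return (gene, backbone, var_ids, orf, kind)


def entries_to_fasta(entries: list[PeptideEntry], handle) -> None:
    """Deterministic annotated FASTA: every source in the header.

    Header grammar: space-joined source blocks
    ``gene|backbone|variant_id;...|ORF<start>|kind`` — lossless, so
    databases can be merged and re-tiered from their FASTA form.
    """
    for entry in sorted(entries, key=lambda e: e.aa_seq):
        headers = " ".join(_format_source(s) for s in sorted(entry.sources))
        handle.write(f">{headers}\n{entry.aa_seq}\n")


def entries_from_fasta(handle) -> dict[str, PeptideEntry]:
    """Read back a database written by :func:`entries_to_fasta`."""
    entries: dict[str, PeptideEntry] = {}
    header: str | None = None
    seq_parts: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(seq_parts)
        entry = entries.setdefault(seq, PeptideEntry(aa_seq=seq))
        for block in header.split(" "):
            if block:
                entry.add(_parse_source(block))

    for line in handle:
        line = line.rstrip("\n")
        if line.startswith(">"):
            flush()
            header = line[1:]
            seq_parts = []
        else:
            seq_parts.append(line)
    flush()
    for entry in entries.values():
        tiers = {_source_tier(s[4], s[2]) for s in entry.sources}
        entry.tier = next(t for t in TIER_ORDER if t in tiers)
    return entries
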