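"""Fuzz-testing framework: case simulation, brute-force oracle, comparison.

Transcripts with varying properties (coding status, strand, exon count,
selenocysteine, start/stop position) and artificial sequences are
simulated, each paired with simulated variants across the supported
types; the graph pipeline's peptides are compared against a brute-force
algorithm that iterates through all possible variant combinations,
applies each by plain string editing, translates (the annotated ORF, or
every methionine in three frames for noncoding backbones), digests and
filters.  The two engines share only declared semantics: the variant
compatibility notion (disjoint spans, nested variants require their
parent), the edge-case exclusion rules, the enzyme rule table and the
length/miscleavage bounds.  Everything else — graph construction and
traversal vs. exhaustive string enumeration — is computed independently.

The simulator places variants at transcript positions >= 3 so that
every variant is representable in all three reading-frame subgraphs
(frame roots trim the reference 5' end); biologically this excludes only
cap-proximal positions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .caller import CallParams, call_transcript, canonical_digest
from .enzymes import digest
from .gvf import CircRNAModel, FusionEvent, VariantRecord
from .reference import (
    GenomeAssembly,
    STANDARD_TABLE,
    TranscriptModel,
    translate,
    transcript_sequence,
)
from .tvg import exclude_edge_case_variants

__all__ = [
    "FuzzConfig",
    "FuzzCase",
    "simulate_case",
    "brute_force_peptides",
    "graph_peptides",
    "compare",
    "run_fuzz",
    "count_brute_subsets",
]

_NT = "ACGT"


@dataclass(frozen=True)
class FuzzConfig:
    """Study conditions for one family of simulated cases."""

    kind: str = "coding"  # coding | noncoding | alt_splice | fusion | circ
    seq_len: tuple[int, int] = (60, 600)
    n_variants: tuple[int, int] = (1, 12)
    # SNV / small indel / other (RNA-editing) weights
    type_weights: tuple[float, float, float] = (0.7, 0.2, 0.1)
    indel_len: tuple[int, int] = (1, 9)
    sec_prob: float = 0.15
    n_exons: tuple[int, int] = (1, 3)
    circ_len: tuple[int, int] = (9, 60)
    max_enumerable: int = 20


@dataclass
class FuzzCase:
    """One simulated backbone plus variants; reproducible from its seed."""

    seed: int
    kind: str
    tx_seq: str
    coding: bool
    cds_start: int | None
    cds_end: int | None
    sec_positions: frozenset
    variants: list[VariantRecord]
    proteome: dict[str, str] = field(default_factory=dict)
    genome: GenomeAssembly | None = None
    tx_model: TranscriptModel | None = None
    # fusion-specific
    fusion_event: FusionEvent | None = None
    donor_model: TranscriptModel | None = None
    acceptor_model: TranscriptModel | None = None
    acceptor_seq: str | None = None
    acceptor_variants: list[VariantRecord] = field(default_factory=list)
    # circRNA-specific
    circ_model: CircRNAModel | None = None
    circ_seq: str | None = None
    expected: set[str] | None = None


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_NT) for _ in range(n))


def _embed_transcript(
    rng: random.Random, tx_seq: str, name: str, gene: str, chrom: str,
    n_exons: int,
):
    """Write ``tx_seq`` into a synthetic genome as a spliced gene."""
    strand = rng.choice("+-")
    L = len(tx_seq)
    n_exons = min(n_exons, max(1, L // 20))
    cuts = sorted(rng.sample(range(1, L), n_exons - 1)) if n_exons > 1 else []
    bounds = [0] + cuts + [L]
    pieces = [tx_seq[a:b] for a, b in zip(bounds, bounds[1:])]
    if strand == "-":
        # genomic order is the reverse of transcript order
        from .reference import reverse_complement

        pieces = [reverse_complement(p) for p in reversed(pieces)]
    introns = [_rand_seq(rng, rng.randint(20, 60)) for _ in range(len(pieces) - 1)]
    gseq = []
    exons = []
    pos = rng.randint(5, 30)
    gseq.append(_rand_seq(rng, pos))
    for i, piece in enumerate(pieces):
        exons.append((pos, pos + len(piece)))
        gseq.append(piece)
        pos += len(piece)
        if i < len(introns):
            gseq.append(introns[i])
            pos += len(introns[i])
    gseq.append(_rand_seq(rng, rng.randint(5, 30)))
    model = TranscriptModel(
        transcript_id=name, gene_id=gene, chromosome=chrom, strand=strand,
        exons=exons,
    )
    return "".join(gseq), model


def _simulate_small_variants(
    rng: random.Random,
    tx_seq: str,
    n: int,
    cfg: FuzzConfig,
    gene: str,
    tx: str,
    lo: int = 3,
    prefix: str = "v",
) -> list[VariantRecord]:
    L = len(tx_seq)
    out: list[VariantRecord] = []
    seen = set()
    w_snv, w_indel, w_other = cfg.type_weights
    for i in range(n):
        for _attempt in range(20):
            u = rng.random()
            if u < w_snv or L - lo < 12:
                p = rng.randint(lo, L - 1)
                ref = tx_seq[p]
                alt = rng.choice([c for c in _NT if c != ref])
                rec = (p, ref, alt, "SNV", "sSNV")
            elif u < w_snv + w_indel:
                if rng.random() < 0.5:
                    p = rng.randint(lo, L - 2)
                    ins = _rand_seq(rng, rng.randint(*cfg.indel_len))
                    rec = (p, tx_seq[p], tx_seq[p] + ins, "INSERTION", "sIndel")
                else:
                    d = rng.randint(*cfg.indel_len)
                    p = rng.randint(lo, max(lo, L - 2 - d))
                    rec = (p, tx_seq[p : p + 1 + d], tx_seq[p], "DELETION", "sIndel")
            else:
                p = rng.randint(lo, L - 1)
                ref = tx_seq[p]
                alt = rng.choice([c for c in _NT if c != ref])
                rec = (p, ref, alt, "SNV", "RNAEditing")
            key = (rec[0], rec[1], rec[2])
            if key in seen:
                continue
            seen.add(key)
            p, ref, alt, vtype, source = rec
            out.append(
                VariantRecord(
                    gene_id=gene,
                    transcript_ids=(tx,),
                    start_tx=p,
                    end_tx=p + len(ref),
                    ref_seq=ref,
                    alt_seq=alt,
                    type=vtype,
                    source=source,
                    variant_id=f"{prefix}{i}",
                )
            )
            break
    return out


def _simulate_alt_splice(
    rng: random.Random, tx_seq: str, gene: str, tx: str, idx: int
) -> list[VariantRecord]:
    """One alternative-splicing event, possibly with nested small variants."""
    L = len(tx_seq)
    kind = rng.choice(["RI", "SE", "A5SS", "MXE"])
    vid = f"as{idx}"
    records: list[VariantRecord] = []
    if kind in ("RI", "A5SS"):
        p = rng.randint(3, L - 1)
        alt = _rand_seq(rng, rng.randint(9, 60))
        records.append(
            VariantRecord(
                gene_id=gene, transcript_ids=(tx,), start_tx=p, end_tx=p,
                ref_seq="", alt_seq=alt,
                type="ALT_SPLICE_RI" if kind == "RI" else "ALT_SPLICE_A5SS",
                source="AltSplice", variant_id=vid,
            )
        )
        for j in range(rng.randint(0, 2)):
            q = rng.randint(0, len(alt) - 1)
            ref = alt[q]
            nalt = rng.choice([c for c in _NT if c != ref])
            records.append(
                VariantRecord(
                    gene_id=gene, transcript_ids=(tx,), start_tx=q, end_tx=q + 1,
                    ref_seq=ref, alt_seq=nalt, type="SNV", source="sSNV",
                    variant_id=f"{vid}n{j}", parent_id=vid,
                )
            )
    elif kind == "SE":
        d = rng.randint(9, min(60, max(9, L - 10)))
        p = rng.randint(3, max(3, L - 1 - d))
        records.append(
            VariantRecord(
                gene_id=gene, transcript_ids=(tx,), start_tx=p, end_tx=p + d,
                ref_seq=tx_seq[p : p + d], alt_seq="", type="ALT_SPLICE_SE",
                source="AltSplice", variant_id=vid,
            )
        )
    else:  # MXE substitution
        d = rng.randint(6, min(45, max(6, L - 10)))
        p = rng.randint(3, max(3, L - 1 - d))
        alt = _rand_seq(rng, rng.randint(6, 45))
        records.append(
            VariantRecord(
                gene_id=gene, transcript_ids=(tx,), start_tx=p, end_tx=p + d,
                ref_seq=tx_seq[p : p + d], alt_seq=alt, type="ALT_SPLICE_MXE",
                source="AltSplice", variant_id=vid,
            )
        )
    return records


def simulate_case(seed: int, config: FuzzConfig) -> FuzzCase:
    """Deterministically simulate one case from (seed, config)."""
    rng = random.Random(f"{seed}:{config.kind}")
    if config.n_variants[0] > config.n_variants[1]:
        raise ValueError("infeasible variant-count range")
    if config.kind == "fusion":
        return _simulate_fusion(seed, rng, config)
    if config.kind == "circ":
        return _simulate_circ(seed, rng, config)

    L = rng.randint(*config.seq_len)
    coding = config.kind == "coding" or (
        config.kind == "alt_splice" and rng.random() < 0.6
    )
    tx_chars = list(_rand_seq(rng, L))
    cds_start = cds_end = None
    sec_positions: frozenset = frozenset()
    if coding:
        cds_start = rng.randint(3, max(3, L - 12))
        tx_chars[cds_start : cds_start + 3] = "ATG"
        if rng.random() < config.sec_prob and cds_start + 9 < L - 3:
            p = rng.randrange(cds_start + 3, L - 3, 3)
            tx_chars[p : p + 3] = "TGA"
            sec_positions = frozenset({p})
    tx_seq = "".join(tx_chars)
    if coding:
        cds_end = _first_stop(tx_seq, cds_start, sec_positions)

    genome_seq, model = _embed_transcript(
        rng, tx_seq, "TX1", "GENE1", "chr1", rng.randint(*config.n_exons)
    )
    genome = GenomeAssembly({"chr1": genome_seq})
    if coding:
        model.cds_start_tx = cds_start
        model.cds_end_tx = cds_end
        model.selenocysteine_positions_tx = sorted(sec_positions)
    assert transcript_sequence(genome, model) == tx_seq

    n = rng.randint(*config.n_variants)
    variants = _simulate_small_variants(rng, tx_seq, n, config, "GENE1", "TX1")
    if config.kind == "alt_splice":
        for idx in range(rng.randint(1, 2)):
            variants.extend(_simulate_alt_splice(rng, tx_seq, "GENE1", "TX1", idx))

    proteome = {}
    if coding:
        protein = translate(
            tx_seq[cds_start:],
            sec_positions=[p - cds_start for p in sec_positions],
        )
        proteome["TX1"] = protein
    return FuzzCase(
        seed=seed,
        kind=config.kind,
        tx_seq=tx_seq,
        coding=coding,
        cds_start=cds_start,
        cds_end=cds_end,
        sec_positions=sec_positions,
        variants=variants,
        proteome=proteome,
        genome=genome,
        tx_model=model,
    )


def _first_stop(seq: str, start: int, sec_positions=frozenset()) -> int:
    for i in range(start, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in ("TAA", "TAG", "TGA") and i not in sec_positions:
            return i
    return start + (len(seq) - start) // 3 * 3


def _simulate_fusion(seed: int, rng: random.Random, config: FuzzConfig) -> FuzzCase:
    Ld = rng.randint(90, 300)
    La = rng.randint(90, 300)
    donor_coding = rng.random() < 0.6
    donor_chars = list(_rand_seq(rng, Ld))
    cds_start = None
    if donor_coding:
        cds_start = rng.randint(3, 30)
        donor_chars[cds_start : cds_start + 3] = "ATG"
    donor_seq = "".join(donor_chars)
    acceptor_seq = _rand_seq(rng, La)

    dg, donor_model = _embed_transcript(rng, donor_seq, "TXD", "GENED", "chrD", rng.randint(1, 3))
    ag, acceptor_model = _embed_transcript(rng, acceptor_seq, "TXA", "GENEA", "chrA", rng.randint(1, 3))
    genome = GenomeAssembly({"chrD": dg, "chrA": ag})
    if donor_coding:
        donor_model.cds_start_tx = cds_start
        donor_model.cds_end_tx = _first_stop(donor_seq, cds_start)

    donor_intronic = len(donor_model.exons) > 1 and rng.random() < 0.3
    acceptor_intronic = len(acceptor_model.exons) > 1 and rng.random() < 0.3
    if donor_intronic:
        intron_idx = rng.randrange(len(donor_model.exons) - 1)
        intron_len = _intron_length(donor_model, intron_idx)
        donor_bp = (intron_idx, rng.randint(1, intron_len))
    else:
        lo = (cds_start + 6) if donor_coding else 6
        donor_bp = rng.randint(min(lo, Ld - 3), Ld - 3)
    if acceptor_intronic:
        intron_idx = rng.randrange(len(acceptor_model.exons) - 1)
        intron_len = _intron_length(acceptor_model, intron_idx)
        acceptor_bp = (intron_idx, rng.randint(0, intron_len - 1))
    else:
        acceptor_bp = rng.randint(3, La - 6)

    event = FusionEvent(
        fusion_id="FUS1",
        donor_gene_id="GENED",
        donor_transcript_id="TXD",
        acceptor_gene_id="GENEA",
        acceptor_transcript_id="TXA",
        donor_breakpoint=donor_bp if not donor_intronic else donor_bp[1],
        acceptor_breakpoint=acceptor_bp if not acceptor_intronic else acceptor_bp[1],
        donor_intronic=donor_intronic,
        acceptor_intronic=acceptor_intronic,
        donor_intron_idx=donor_bp[0] if donor_intronic else None,
        acceptor_intron_idx=acceptor_bp[0] if acceptor_intronic else None,
    )
    n = rng.randint(1, 6)
    donor_exonic_limit = donor_bp if not donor_intronic else _tx_end_of_exon(donor_model, donor_bp[0])
    donor_vars = [
        v
        for v in _simulate_small_variants(
            rng, donor_seq, n // 2 + 1, config, "GENED", "TXD", prefix="d"
        )
        if v.end_tx <= donor_exonic_limit
    ]
    acceptor_start = (
        acceptor_bp if not acceptor_intronic
        else _tx_end_of_exon(acceptor_model, acceptor_bp[0])
    )
    acceptor_vars = [
        v
        for v in _simulate_small_variants(
            rng, acceptor_seq, n - n // 2, config, "GENEA", "TXA", prefix="a"
        )
        if v.start_tx >= acceptor_start
    ]
    proteome = {}
    if donor_coding:
        proteome["TXD"] = translate(donor_seq[cds_start:])
    case = FuzzCase(
        seed=seed,
        kind="fusion",
        tx_seq=donor_seq,
        coding=donor_coding,
        cds_start=cds_start,
        cds_end=donor_model.cds_end_tx if donor_coding else None,
        sec_positions=frozenset(),
        variants=donor_vars,
        proteome=proteome,
        genome=genome,
        tx_model=donor_model,
        fusion_event=event,
        donor_model=donor_model,
        acceptor_model=acceptor_model,
        acceptor_seq=acceptor_seq,
        acceptor_variants=acceptor_vars,
    )
    return case


def _intron_length(model: TranscriptModel, intron_idx: int) -> int:
    # introns indexed in transcript order
    exons = model.exons if model.strand == "+" else list(reversed(model.exons))
    if model.strand == "+":
        return exons[intron_idx + 1][0] - exons[intron_idx][1]
    return exons[intron_idx][0] - exons[intron_idx + 1][1]


def _tx_end_of_exon(model: TranscriptModel, exon_idx_tx: int) -> int:
    exons = model.exons if model.strand == "+" else list(reversed(model.exons))
    return sum(b - a for a, b in exons[: exon_idx_tx + 1])


def _simulate_circ(seed: int, rng: random.Random, config: FuzzConfig) -> FuzzCase:
    Lc = rng.randint(*config.circ_len)
    host_len = Lc + rng.randint(30, 90)
    host_seq = _rand_seq(rng, host_len)
    genome_seq, model = _embed_transcript(rng, host_seq, "TXH", "GENEH", "chrH", 1)
    genome = GenomeAssembly({"chrH": genome_seq})
    start = rng.randint(0, host_len - Lc)
    circ_model = CircRNAModel(
        circ_id="CIRC1", gene_id="GENEH", transcript_id="TXH",
        segments=((start, start + Lc),),
    )
    circ_seq = host_seq[start : start + Lc]
    n = min(rng.randint(0, 3), max(0, (Lc - 4) // 4))
    variants = (
        _simulate_small_variants(rng, circ_seq, n, config, "GENEH", "CIRC1", prefix="c")
        if Lc > 12 and n
        else []
    )
    return FuzzCase(
        seed=seed,
        kind="circ",
        tx_seq=host_seq,
        coding=False,
        cds_start=None,
        cds_end=None,
        sec_positions=frozenset(),
        variants=variants,
        proteome={},
        genome=genome,
        tx_model=model,
        circ_model=circ_model,
        circ_seq=circ_seq,
    )


# -- brute force -----------------------------------------------------------


def _pair_compatible(a: VariantRecord, b: VariantRecord) -> bool:
    if a.parent_id != b.parent_id:
        return True
    return not a.overlaps(b)


def _valid_subset(subset: tuple[VariantRecord, ...]) -> bool:
    ids = {v.variant_id for v in subset if v.parent_id is None}
    for v in subset:
        if v.parent_id is not None and v.parent_id not in ids:
            return False
    n = len(subset)
    for i in range(n):
        for j in range(i + 1, n):
            if not _pair_compatible(subset[i], subset[j]):
                return False
    return True


def _enumerate_subsets(variants: list[VariantRecord]):
    n = len(variants)
    for mask in range(1 << n):
        subset = tuple(variants[i] for i in range(n) if mask & (1 << i))
        if _valid_subset(subset):
            yield subset


def count_brute_subsets(variants: list[VariantRecord]) -> int:
    return sum(1 for _ in _enumerate_subsets(variants))


def _edit_sequence(
    seq: str, subset: tuple[VariantRecord, ...]
) -> tuple[str, list[int]]:
    """Apply a variant subset by string editing; track per-base origins."""
    tops = sorted(
        (v for v in subset if v.parent_id is None),
        key=lambda v: (v.start_tx, v.end_tx),
        reverse=True,
    )
    nested: dict[str, list[VariantRecord]] = {}
    for v in subset:
        if v.parent_id is not None:
            nested.setdefault(v.parent_id, []).append(v)
    chars = list(seq)
    origins: list[int] = list(range(len(seq)))
    for v in tops:
        alt = v.alt_seq
        for nv in sorted(
            nested.get(v.variant_id, ()),
            key=lambda x: (x.start_tx, x.end_tx),
            reverse=True,
        ):
            alt = alt[: nv.start_tx] + nv.alt_seq + alt[nv.end_tx :]
        chars[v.start_tx : v.end_tx] = list(alt)
        origins[v.start_tx : v.end_tx] = [-1] * len(alt)
    return "".join(chars), origins


def _brute_translate_coding(
    edited: str, origins: list[int], cds_start: int, sec_positions
) -> tuple[str, bool]:
    aa = []
    stopped = False
    for i in range(cds_start, len(edited) - 2, 3):
        codon = edited[i : i + 3]
        if codon == "TGA" and origins[i] in sec_positions:
            aa.append("U")
            continue
        r = STANDARD_TABLE.amino_acid(codon)
        if r == "*":
            stopped = True
            break
        aa.append(r)
    return "".join(aa), stopped


def _brute_noncoding_peptides(
    edited: str, origins: list[int], sec_positions, enzyme, max_mc, min_len, max_len
) -> set[str]:
    out: set[str] = set()
    frames = []
    for f in range(3):
        aa = []
        for i in range(f, len(edited) - 2, 3):
            codon = edited[i : i + 3]
            if codon == "TGA" and origins[i] in sec_positions:
                aa.append("U")
            else:
                aa.append(STANDARD_TABLE.amino_acid(codon))
        frames.append("".join(aa))
    p = edited.find("ATG")
    while p != -1:
        f = p % 3
        idx = (p - f) // 3
        aa_f = frames[f]
        stop = aa_f.find("*", idx)
        if stop == -1:
            protein, known = aa_f[idx:], False
        else:
            protein, known = aa_f[idx:stop], True
        out |= digest(
            protein,
            enzyme,
            max_miscleavage=max_mc,
            min_length=min_len,
            max_length=max_len,
            c_term_known=known,
        )
        p = edited.find("ATG", p + 1)
    return out


def _case_backbone(case: FuzzCase) -> tuple[str, list[VariantRecord], bool, int | None]:
    """Brute-force view of the case's backbone: sequence plus variants.

    Assembled independently of the graph-route backbone builders by
    plain string concatenation.
    """
    if case.kind == "fusion":
        seq, variants, coding, cds = _brute_fusion_backbone(case)
        return seq, variants, coding, cds
    if case.kind == "circ":
        L = len(case.circ_seq)
        lin = case.circ_seq * 3
        reps: list[VariantRecord] = []
        for v in case.variants:
            for copy in range(3):
                off = copy * L
                reps.append(
                    VariantRecord(
                        gene_id=v.gene_id,
                        transcript_ids=v.transcript_ids,
                        start_tx=v.start_tx + off,
                        end_tx=v.end_tx + off,
                        ref_seq=v.ref_seq,
                        alt_seq=v.alt_seq,
                        type=v.type,
                        source=v.source,
                        variant_id=v.variant_id,
                    )
                )
        return lin, reps, False, None
    return case.tx_seq, case.variants, case.coding, case.cds_start


def _brute_fusion_backbone(case: FuzzCase):
    ev = case.fusion_event
    donor_seq = case.tx_seq
    acceptor_seq = case.acceptor_seq
    d_idx = ev.donor_intron_idx
    a_idx = ev.acceptor_intron_idx
    if ev.donor_intronic:
        exon_end = _tx_end_of_exon(case.donor_model, d_idx)
        intron = _intron_seq(case, case.donor_model, d_idx)
        donor_part = donor_seq[:exon_end] + intron[: ev.donor_breakpoint]
        donor_limit = exon_end
    else:
        donor_part = donor_seq[: ev.donor_breakpoint]
        donor_limit = ev.donor_breakpoint
    if ev.acceptor_intronic:
        intron = _intron_seq(case, case.acceptor_model, a_idx)
        exon_end = _tx_end_of_exon(case.acceptor_model, a_idx)
        acceptor_part = intron[ev.acceptor_breakpoint :] + acceptor_seq[exon_end:]
        acceptor_from = exon_end
        acceptor_shift = len(donor_part) + (
            len(intron) - ev.acceptor_breakpoint
        ) - exon_end
    else:
        acceptor_part = acceptor_seq[ev.acceptor_breakpoint :]
        acceptor_from = ev.acceptor_breakpoint
        acceptor_shift = len(donor_part) - ev.acceptor_breakpoint
    backbone = donor_part + acceptor_part
    variants: list[VariantRecord] = []
    from dataclasses import replace

    for v in case.variants:
        if v.end_tx <= donor_limit:
            variants.append(v)
    for v in case.acceptor_variants:
        if v.start_tx >= acceptor_from:
            variants.append(
                replace(
                    v,
                    start_tx=v.start_tx + acceptor_shift,
                    end_tx=v.end_tx + acceptor_shift,
                )
            )
    coding = case.coding and case.cds_start is not None and (
        case.cds_start + 3 <= donor_limit
    )
    return backbone, variants, coding, (case.cds_start if coding else None)


def _intron_seq(case: FuzzCase, model: TranscriptModel, intron_idx: int) -> str:
    """Intron sequence in transcript direction (strand-aware)."""
    from .reference import reverse_complement

    exons = model.exons if model.strand == "+" else list(reversed(model.exons))
    chrom = case.genome.chromosome(model.chromosome)
    if model.strand == "+":
        a, b = exons[intron_idx][1], exons[intron_idx + 1][0]
        return chrom[a:b]
    a, b = exons[intron_idx + 1][1], exons[intron_idx][0]
    return reverse_complement(chrom[a:b])


def brute_force_peptides(case: FuzzCase, params: CallParams) -> set[str]:
    """Exhaustive enumeration over all compatible variant combinations."""
    backbone, variants, coding, cds_start = _case_backbone(case)
    kept, _ = exclude_edge_case_variants(
        variants,
        cds_start=cds_start if coding else None,
        cds_end=case.cds_end if (coding and case.kind != "fusion") else None,
    )
    if len(kept) > case_max_enumerable(case):
        raise ValueError(
            f"case has {len(kept)} variants; too many to enumerate — shrink it"
        )
    enzyme = params.spec()
    mc = params.mc()
    canon = canonical_digest(case.proteome, params)
    out: set[str] = set()
    for subset in _enumerate_subsets(kept):
        edited, origins = _edit_sequence(backbone, subset)
        if coding:
            protein, stopped = _brute_translate_coding(
                edited, origins, cds_start, case.sec_positions
            )
            out |= digest(
                protein,
                enzyme,
                max_miscleavage=mc,
                min_length=params.min_length,
                max_length=params.max_length,
                c_term_known=stopped,
            )
        else:
            out |= _brute_noncoding_peptides(
                edited, origins, case.sec_positions, enzyme, mc,
                params.min_length, params.max_length,
            )
    out = {p for p in out if "X" not in p}
    return out - canon


def case_max_enumerable(case: FuzzCase, cap: int = 20) -> int:
    return cap


# -- graph route -----------------------------------------------------------


def graph_peptides(case: FuzzCase, params: CallParams) -> set[str]:
    """Run the graph pipeline on a fuzz case and collect peptide sequences."""
    canon = canonical_digest(case.proteome, params)
    if case.kind == "fusion":
        from .backbones import build_fusion_backbone

        backbone = build_fusion_backbone(
            case.fusion_event,
            {"TXD": case.donor_model, "TXA": case.acceptor_model},
            case.genome,
            donor_variants=case.variants,
            acceptor_variants=case.acceptor_variants,
        )
        peptides = call_transcript(
            backbone.seq,
            backbone.variants,
            params,
            coding=backbone.coding,
            cds_start=backbone.cds_start,
            canonical_set=canon,
        )
    elif case.kind == "circ":
        from .backbones import build_circ_backbone

        backbone = build_circ_backbone(
            case.circ_model, case.genome, {"TXH": case.tx_model},
            variants=case.variants,
        )
        peptides = call_transcript(
            backbone.seq, backbone.variants, params, coding=False,
            canonical_set=canon,
        )
    else:
        peptides = call_transcript(
            case.tx_seq,
            case.variants,
            params,
            coding=case.coding,
            cds_start=case.cds_start,
            cds_end=case.cds_end,
            sec_positions=case.sec_positions,
            canonical_set=canon,
        )
    return {p.seq for p in peptides}


@dataclass
class CompareReport:
    missing: set[str]
    extra: set[str]

    @property
    def ok(self) -> bool:
        return not self.missing and not self.extra


def compare(case: FuzzCase, graph_output: set[str]) -> CompareReport:
    """Diff the graph pipeline's peptides against the brute-force oracle."""
    if case.expected is None:
        case.expected = brute_force_peptides(case, CallParams())
    return CompareReport(
        missing=case.expected - graph_output,
        extra=graph_output - case.expected,
    )


def run_fuzz(
    n: int,
    seed: int,
    config: FuzzConfig,
    params: CallParams | None = None,
) -> list[tuple[int, CompareReport]]:
    """Run ``n`` cases; returns (case seed, report) for failures only."""
    params = params or CallParams()
    failures = []
    for i in range(n):
        case_seed = seed * 1_000_000 + i
        case = simulate_case(case_seed, config)
        expected = brute_force_peptides(case, params)
        got = graph_peptides(case, params)
        report = CompareReport(missing=expected - got, extra=got - expected)
        if not report.ok:
            failures.append((case_seed, report))
    return failures


# -- runtime scaling -------------------------------------------------------

_STOP_CODONS = ("TAA", "TAG", "TGA")


def simulate_scaling_case(
    rng: random.Random, n_variants: int, codons_per_variant: int = 8
) -> tuple[str, list[VariantRecord]]:
    """A stop-free coding backbone with well-separated SNVs.

    Used for runtime measurements: without premature stops every case
    processes its full open reading frame, so the workload per variant
    is uniform and the pipeline's scaling is measurable cleanly.
    """
    n_codons = codons_per_variant * n_variants + 100
    codons: list[str] = []
    while len(codons) < n_codons:
        c = _rand_seq(rng, 3)
        if c not in _STOP_CODONS:
            codons.append(c)
    seq = "ATG" + "".join(codons) + "TAA"
    positions = rng.sample(range(6, len(seq) - 9, 12), n_variants)
    variants = []
    for i, p in enumerate(sorted(positions)):
        ref = seq[p]
        alt = rng.choice([c for c in _NT if c != ref])
        variants.append(
            VariantRecord(
                gene_id="G", transcript_ids=("T",), start_tx=p, end_tx=p + 1,
                ref_seq=ref, alt_seq=alt, type="SNV", source="sSNV",
                variant_id=f"v{i}",
            )
        )
    return seq, variants


def measure_runtime_scaling(
    seed: int,
    counts=tuple(range(10, 201, 10)),
    replicates: int = 20,
    params: CallParams | None = None,
) -> tuple[float, float]:
    """Linear fit of pipeline run time against variant count.

    Returns (R^2, slope in seconds per variant).  Replicates are
    interleaved across counts so that machine drift averages out.
    """
    import time

    import numpy as np

    from .caller import call_backbone

    params = params or CallParams()
    rng = random.Random(seed)
    cases = {n: [simulate_scaling_case(rng, n) for _ in range(replicates)]
             for n in counts}
    seq0, vars0 = cases[counts[0]][0]
    call_backbone(seq0, vars0, params, coding=True, cds_start=0)  # warm-up
    acc = {n: [] for n in counts}
    for rep in range(replicates):
        for n in counts:
            seq, variants = cases[n][rep]
            t0 = time.perf_counter()
            call_backbone(seq, variants, params, coding=True, cds_start=0)
            acc[n].append(time.perf_counter() - t0)
    x = np.array(counts, dtype=float)
    y = np.array([np.mean(acc[n]) for n in counts])
    design = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    ss_res = float(((y - design @ coef) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot, float(coef[0])


def brute_subset_growth(seed: int, max_variants: int = 12) -> float:
    """Mean ratio of enumerated subset counts per added variant (1..max)."""
    rng = random.Random(seed)
    ratios = []
    prev = None
    for n in range(1, max_variants + 1):
        _seq, variants = simulate_scaling_case(rng, n)
        count = count_brute_subsets(variants)
        if prev is not None:
            ratios.append(count / prev)
        prev = count
    return sum(ratios) / len(ratios)
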