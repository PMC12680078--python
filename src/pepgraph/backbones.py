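"""Non-canonical backbones: fusion transcripts and circular RNAs.

A fusion backbone joins a donor transcript prefix to an acceptor
transcript suffix.  If a breakpoint falls in an intron, the intronic
sequence leading up to (donor side) or following (acceptor side) the
breakpoint is retained as unspliced.  The donor's ORF start is used when
the donor is coding and the start lies 5' of the junction; otherwise the
backbone is treated as noncoding.  Small variants of both partners are
mapped into backbone coordinates; variants overlapping the breakpoint
are dropped with a warning.

A circular backbone connects the circRNA sequence onto itself at the
back-splice junction.  Because the ribosome may traverse the circle up
to three times before the amino-acid sequence repeats (a non-triplet
circle shifts frame at each junction passage), the circular graph is
linearized as three concatenated copies of the circle, with the circle's
variants replicated into each copy, and called as a noncoding
transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .gvf import CircRNAModel, FusionEvent, VariantRecord
from .reference import GenomeAssembly, TranscriptModel, reverse_complement, transcript_sequence

__all__ = [
    "Backbone",
    "build_fusion_backbone",
    "build_circ_backbone",
    "map_tx_variants_to_circ",
]

logger = logging.getLogger(__name__)


@dataclass
class Backbone:
    """A linear calling substrate with variants in backbone coordinates."""

    backbone_id: str
    seq: str
    variants: list[VariantRecord]
    coding: bool
    cds_start: int | None
    kind: str  # fusion_coding | fusion_noncoding | circ
    junctions: tuple[int, ...] = ()


def _exons_tx_order(model: TranscriptModel) -> list[tuple[int, int]]:
    return model.exons if model.strand == "+" else list(reversed(model.exons))


def _intron_seq_tx_direction(
    genome: GenomeAssembly, model: TranscriptModel, intron_idx: int
) -> str:
    exons = _exons_tx_order(model)
    if intron_idx < 0 or intron_idx >= len(exons) - 1:
        raise ValueError(
            f"{model.transcript_id}: intron index {intron_idx} out of range"
        )
    if model.strand == "+":
        a, b = exons[intron_idx][1], exons[intron_idx + 1][0]
        return genome.fetch(model.chromosome, a, b)
    a, b = exons[intron_idx + 1][1], exons[intron_idx][0]
    return reverse_complement(genome.fetch(model.chromosome, a, b))


def _tx_len_through_exon(model: TranscriptModel, exon_idx_tx: int) -> int:
    exons = _exons_tx_order(model)
    return sum(b - a for a, b in exons[: exon_idx_tx + 1])


def build_fusion_backbone(
    event: FusionEvent,
    annotation: dict[str, TranscriptModel],
    genome: GenomeAssembly,
    donor_variants: list[VariantRecord] | None = None,
    acceptor_variants: list[VariantRecord] | None = None,
) -> Backbone:
    """Assemble the fused sequence and map variants into it."""
    donor = annotation[event.donor_transcript_id]
    acceptor = annotation[event.acceptor_transcript_id]
    donor_seq = transcript_sequence(genome, donor)
    acceptor_seq = transcript_sequence(genome, acceptor)
    donor_intron_idx = event.donor_intron_idx
    acceptor_intron_idx = event.acceptor_intron_idx

    if event.donor_intronic:
        if donor_intron_idx is None:
            raise ValueError(f"{event.fusion_id}: intronic donor break needs intron index")
        intron = _intron_seq_tx_direction(genome, donor, donor_intron_idx)
        if not 0 <= event.donor_breakpoint <= len(intron):
            raise ValueError(f"{event.fusion_id}: donor breakpoint outside intron")
        donor_limit = _tx_len_through_exon(donor, donor_intron_idx)
        donor_part = donor_seq[:donor_limit] + intron[: event.donor_breakpoint]
    else:
        if not 0 < event.donor_breakpoint <= len(donor_seq):
            raise ValueError(f"{event.fusion_id}: donor breakpoint outside gene body")
        donor_limit = event.donor_breakpoint
        donor_part = donor_seq[:donor_limit]

    if event.acceptor_intronic:
        if acceptor_intron_idx is None:
            raise ValueError(
                f"{event.fusion_id}: intronic acceptor break needs intron index"
            )
        intron = _intron_seq_tx_direction(genome, acceptor, acceptor_intron_idx)
        if not 0 <= event.acceptor_breakpoint < len(intron):
            raise ValueError(f"{event.fusion_id}: acceptor breakpoint outside intron")
        acceptor_from = _tx_len_through_exon(acceptor, acceptor_intron_idx)
        acceptor_part = intron[event.acceptor_breakpoint :] + acceptor_seq[acceptor_from:]
        acceptor_shift = (
            len(donor_part) + len(intron) - event.acceptor_breakpoint - acceptor_from
        )
    else:
        if not 0 <= event.acceptor_breakpoint < len(acceptor_seq):
            raise ValueError(f"{event.fusion_id}: acceptor breakpoint outside gene body")
        acceptor_from = event.acceptor_breakpoint
        acceptor_part = acceptor_seq[acceptor_from:]
        acceptor_shift = len(donor_part) - acceptor_from

    seq = donor_part + acceptor_part
    variants: list[VariantRecord] = []
    for v in donor_variants or ():
        if v.end_tx <= donor_limit:
            variants.append(v)
        else:
            logger.warning(
                "%s: donor variant %s overlaps the breakpoint; dropped",
                event.fusion_id, v.variant_id,
            )
    for v in acceptor_variants or ():
        if v.start_tx >= acceptor_from:
            variants.append(
                replace(
                    v,
                    start_tx=v.start_tx + acceptor_shift,
                    end_tx=v.end_tx + acceptor_shift,
                )
            )
        else:
            logger.warning(
                "%s: acceptor variant %s overlaps the breakpoint; dropped",
                event.fusion_id, v.variant_id,
            )

    coding = (
        donor.is_coding
        and donor.cds_start_tx is not None
        and donor.cds_start_tx + 3 <= donor_limit
    )
    return Backbone(
        backbone_id=event.fusion_id,
        seq=seq,
        variants=variants,
        coding=coding,
        cds_start=donor.cds_start_tx if coding else None,
        kind="fusion_coding" if coding else "fusion_noncoding",
        junctions=(len(donor_part),),
    )


N_CIRC_COPIES = 3  # the rolling-translation repeat bound


def build_circ_backbone(
    circ: CircRNAModel,
    genome: GenomeAssembly,
    annotation: dict[str, TranscriptModel],
    variants: list[VariantRecord] | None = None,
) -> Backbone:
    """Linearize a circRNA into three appended copies with its variants.

    Variant coordinates are circle-local; each variant is replicated
    into every copy.  Variants crossing the back-splice junction are
    dropped with a warning.
    """
    host = annotation[circ.transcript_id]
    host_seq = transcript_sequence(genome, host)
    parts = []
    for a, b in circ.segments:
        if not 0 <= a < b <= len(host_seq):
            raise ValueError(f"{circ.circ_id}: segment [{a}, {b}) outside transcript")
        parts.append(host_seq[a:b])
    circ_seq = "".join(parts)
    L = len(circ_seq)
    lin = circ_seq * N_CIRC_COPIES
    reps: list[VariantRecord] = []
    for v in variants or ():
        if v.end_tx > L or v.start_tx < 0:
            logger.warning(
                "%s: variant %s crosses the back-splice junction; dropped",
                circ.circ_id, v.variant_id,
            )
            continue
        for copy in range(N_CIRC_COPIES):
            off = copy * L
            reps.append(replace(v, start_tx=v.start_tx + off, end_tx=v.end_tx + off))
    return Backbone(
        backbone_id=circ.circ_id,
        seq=lin,
        variants=reps,
        coding=False,
        cds_start=None,
        kind="circ",
        junctions=tuple(L * i for i in range(1, N_CIRC_COPIES)),
    )


def map_tx_variants_to_circ(
    circ: CircRNAModel, variants: list[VariantRecord]
) -> list[VariantRecord]:
    """Re-express host-transcript variants in circle-local coordinates.

    Only variants fully contained in one circRNA segment are mappable;
    the rest are dropped with a warning.
    """
    out: list[VariantRecord] = []
    offset = 0
    for (a, b) in circ.segments:
        for v in variants:
            if a <= v.start_tx and v.end_tx <= b and v.parent_id is None:
                out.append(
                    replace(
                        v,
                        start_tx=v.start_tx - a + offset,
                        end_tx=v.end_tx - a + offset,
                    )
                )
        offset += b - a
    mapped = {v.variant_id for v in out}
    for v in variants:
        if v.variant_id not in mapped:
            logger.warning(
                "%s: variant %s not contained in a circRNA segment; dropped",
                circ.circ_id, v.variant_id,
            )
    return out
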