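"""Parsers for upstream caller outputs.

Each parser converts one tool family's native output into gene-centric
records in transcript coordinates:

* VEP-annotated small variants (tab output)  -> :class:`VariantRecord`
* STAR-Fusion-style TSV                      -> :class:`FusionEvent`
* rMATS-style alternative-splicing tables    -> :class:`VariantRecord`
* REDItools-style RNA-editing site tables    -> :class:`VariantRecord`
* CIRCexplorer2-style circRNA tables         -> :class:`CircRNAModel`

Variants are admitted only when their genomic footprint is fully exonic
for the transcript under consideration; partially intronic footprints
(which include the splice-site dinucleotides) are dropped, implementing
the geometric half of the splice-site exclusion rule.  Records on the
``-`` strand are reverse-complemented into transcript space.  Indels are
stored left-anchored with one retained anchor base, as in VCF.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .gvf import CircRNAModel, FusionEvent, GVFError, VariantRecord
from .reference import GenomeAssembly, TranscriptModel, reverse_complement

__all__ = [
    "parse_vep",
    "parse_fusion",
    "parse_alt_splicing",
    "parse_rna_editing",
    "parse_circrna",
]

logger = logging.getLogger(__name__)

_SPLICE_CSQ = ("splice_acceptor_variant", "splice_donor_variant")


def _gene_index(annotation: Mapping[str, TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    idx: dict[str, list[TranscriptModel]] = {}
    for tx in annotation.values():
        idx.setdefault(tx.gene_id, []).append(tx)
    for txs in idx.values():
        txs.sort(key=lambda t: t.transcript_id)
    return idx


def _read_table(source, **kw) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source, sep="\t", **kw)


# -- VEP -------------------------------------------------------------------


def _parse_location(loc: str) -> tuple[str, int, int]:
    chrom, _, span = str(loc).partition(":")
    if "-" in span:
        a, _, b = span.partition("-")
        return chrom, int(a), int(b)
    return chrom, int(span), int(span)


def parse_vep(
    vep_source,
    annotation: Mapping[str, TranscriptModel],
    genome: GenomeAssembly,
    source_tag: str = "gSNP",
) -> list[VariantRecord]:
    """Convert VEP tab output into transcript-space variant records.

    Expected columns: ``#Uploaded_variation``, ``Location``, ``Allele``,
    ``Gene``, ``Feature``, ``Consequence`` (extra columns are ignored).
    One record is produced per affected transcript.  Records whose
    reference allele mismatches the genome are rejected with a
    diagnostic; unknown transcripts are skipped with a warning, as are
    splice-site-altering consequences.
    """
    df = _read_table(vep_source, comment=None, header=0, dtype=str)
    df = df.rename(columns={df.columns[0]: "Uploaded_variation"})
    out: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        tx_id = row.Feature
        tx = annotation.get(tx_id)
        if tx is None:
            logger.warning("parse_vep: unknown transcript %s; skipped", tx_id)
            continue
        csq = getattr(row, "Consequence", "") or ""
        if any(s in csq for s in _SPLICE_CSQ):
            logger.warning(
                "parse_vep: %s on %s is splice-site-altering; dropped",
                row.Uploaded_variation, tx_id,
            )
            continue
        chrom, start1, end1 = _parse_location(row.Location)
        alt = "" if row.Allele == "-" else str(row.Allele)
        if end1 < start1:  # VEP insertion convention: start = end + 1
            gstart, gend = end1, end1  # zero-length span after base end1
            ref = ""
        else:
            gstart, gend = start1 - 1, end1
            ref = genome.fetch(chrom, gstart, gend)
        if chrom != tx.chromosome:
            continue
        # full exonic containment (splice-site geometry handled here)
        if gend > gstart and not all(
            tx.overlaps_exon(g, g + 1) for g in range(gstart, gend)
        ):
            logger.warning(
                "parse_vep: %s footprint not fully exonic on %s; dropped",
                row.Uploaded_variation, tx_id,
            )
            continue
        if gend == gstart and not tx.overlaps_exon(gstart - 1, gstart + 1):
            continue
        try:
            rec = _genomic_to_tx_record(
                tx, genome, gstart, gend, ref, alt,
                str(row.Uploaded_variation), source_tag,
            )
        except GVFError as exc:
            logger.error("parse_vep: %s rejected: %s", row.Uploaded_variation, exc)
            continue
        if rec is not None:
            out.append(rec)
    return out


def _genomic_to_tx_record(
    tx: TranscriptModel,
    genome: GenomeAssembly,
    gstart: int,
    gend: int,
    ref: str,
    alt: str,
    variant_id: str,
    source_tag: str,
) -> VariantRecord | None:
    """Map a genomic allele pair onto one transcript, VCF-anchored."""
    chrom_seq = genome.chromosome(tx.chromosome)
    if ref and chrom_seq[gstart:gend] != ref:
        raise GVFError(
            f"reference allele mismatch at {tx.chromosome}:{gstart + 1} "
            f"(expected {ref!r}, genome has {chrom_seq[gstart:gend]!r})"
        )
    if tx.strand == "+":
        if gend > gstart:
            start_tx = tx.genomic_to_tx(gstart)
            t_ref, t_alt = ref, alt
        else:
            start_tx = tx.genomic_to_tx(gstart - 1) + 1
            t_ref, t_alt = "", alt
    else:
        if gend > gstart:
            start_tx = tx.genomic_to_tx(gend - 1)
            t_ref, t_alt = reverse_complement(ref), reverse_complement(alt)
        else:
            # insertion point between gstart-1 and gstart maps to the
            # mirrored point on the transcript
            start_tx = tx.genomic_to_tx(gstart - 1)
            t_ref, t_alt = "", reverse_complement(alt)
    # left-anchor indels against the transcript, as in VCF
    if not t_ref or not t_alt:
        if start_tx == 0:
            return None  # cannot anchor at the very 5' end
        # fetch the transcript base preceding the span
        from .reference import transcript_sequence

        tx_seq = transcript_sequence(genome, tx)
        anchor = tx_seq[start_tx - 1]
        start_tx -= 1
        t_ref, t_alt = anchor + t_ref, anchor + t_alt
    if len(t_ref) == 1 and len(t_alt) == 1:
        vtype = "SNV"
    elif len(t_ref) < len(t_alt) and t_alt.startswith(t_ref):
        vtype = "INSERTION"
    elif len(t_ref) > len(t_alt) and t_ref.startswith(t_alt):
        vtype = "DELETION"
    else:
        vtype = "SUBSTITUTION"
    return VariantRecord(
        gene_id=tx.gene_id,
        transcript_ids=(tx.transcript_id,),
        start_tx=start_tx,
        end_tx=start_tx + len(t_ref),
        ref_seq=t_ref,
        alt_seq=t_alt,
        type=vtype,
        source=source_tag,
        variant_id=variant_id,
    )


# -- fusion ----------------------------------------------------------------


def _breakpoint_for_transcript(
    tx: TranscriptModel, gpos: int, side: str
) -> tuple[int, bool, int | None]:
    """Classify a genomic breakpoint as exonic or intronic for ``tx``.

    Returns (breakpoint, intronic, intron_idx).  For an exonic donor
    break, the breakpoint is exclusive (the donor keeps its sequence
    through ``gpos``); for an exonic acceptor break it is inclusive.
    Intronic breakpoints become transcript-direction offsets into the
    intron, with the donor retaining the intron up to and including the
    breakpoint base and the acceptor retaining it from the breakpoint on.
    """
    exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    try:
        tpos = tx.genomic_to_tx(gpos)
    except ValueError:
        tpos = None
    if tpos is not None:
        return (tpos + 1, False, None) if side == "donor" else (tpos, False, None)
    cum = 0
    for i in range(len(exons) - 1):
        cum += exons[i][1] - exons[i][0]
        if tx.strand == "+":
            ia, ib = exons[i][1], exons[i + 1][0]
            inside = ia <= gpos < ib
            off = gpos - ia
        else:
            ia, ib = exons[i + 1][1], exons[i][0]
            inside = ia <= gpos < ib
            off = ib - 1 - gpos
        if inside:
            return (off + 1, True, i) if side == "donor" else (off, True, i)
    raise ValueError(f"{tx.transcript_id}: breakpoint {gpos} outside gene body")


def parse_fusion(
    fusion_source,
    annotation: Mapping[str, TranscriptModel],
) -> list[FusionEvent]:
    """STAR-Fusion-style TSV -> one event per donor x acceptor transcript.

    Expected columns: ``#FusionName``, ``LeftGene``, ``LeftBreakpoint``
    (``chr:pos:strand``), ``RightGene``, ``RightBreakpoint``.  Gene ids
    may be ``symbol^ENSG`` or bare ids.  Rows whose genes are absent
    from the annotation are dropped with a warning.
    """
    df = _read_table(fusion_source, dtype=str)
    df = df.rename(columns={df.columns[0]: "FusionName"})
    genes = _gene_index(annotation)
    out: list[FusionEvent] = []
    for row in df.itertuples(index=False):
        def gene_id(raw: str) -> str:
            return raw.split("^")[-1].split(".")[0]

        dg = gene_id(row.LeftGene)
        ag = gene_id(row.RightGene)
        if dg not in genes or ag not in genes:
            logger.warning(
                "parse_fusion: %s dropped (gene absent from annotation)",
                row.FusionName,
            )
            continue
        dchrom, dpos1, _ = str(row.LeftBreakpoint).split(":")
        achrom, apos1, _ = str(row.RightBreakpoint).split(":")
        dpos, apos = int(dpos1) - 1, int(apos1) - 1
        for dtx in genes[dg]:
            for atx in genes[ag]:
                if dtx.chromosome != dchrom or atx.chromosome != achrom:
                    continue
                try:
                    dbp, d_in, d_idx = _breakpoint_for_transcript(dtx, dpos, "donor")
                    abp, a_in, a_idx = _breakpoint_for_transcript(atx, apos, "acceptor")
                except ValueError as exc:
                    logger.warning("parse_fusion: %s: %s", row.FusionName, exc)
                    continue
                out.append(
                    FusionEvent(
                        fusion_id=f"{row.FusionName}|{dtx.transcript_id}"
                        f"|{atx.transcript_id}",
                        donor_gene_id=dg,
                        donor_transcript_id=dtx.transcript_id,
                        acceptor_gene_id=ag,
                        acceptor_transcript_id=atx.transcript_id,
                        donor_breakpoint=dbp,
                        acceptor_breakpoint=abp,
                        donor_intronic=d_in,
                        acceptor_intronic=a_in,
                        donor_intron_idx=d_idx,
                        acceptor_intron_idx=a_idx,
                    )
                )
    return out


# -- alternative splicing --------------------------------------------------


def _genomic_span_seq(
    genome: GenomeAssembly, tx: TranscriptModel, gstart: int, gend: int
) -> str:
    seq = genome.fetch(tx.chromosome, gstart, gend)
    return reverse_complement(seq) if tx.strand == "-" else seq


def parse_alt_splicing(
    event_source,
    event_type: str,
    annotation: Mapping[str, TranscriptModel],
    genome: GenomeAssembly,
) -> list[VariantRecord]:
    """rMATS-style events -> insertion/deletion/substitution records.

    Each event is re-expressed against every compatible transcript:
    retained introns become insertions, skipped exons deletions, and
    A3SS/A5SS extensions insertions of the extra genomic span; MXE
    becomes a substitution replacing one exon's sequence by the other's.
    Events not reconcilable with any transcript are dropped with a
    warning.
    """
    event_type = event_type.upper()
    if event_type not in ("SE", "RI", "A3SS", "A5SS", "MXE"):
        raise ValueError(f"unknown alternative-splicing event type {event_type!r}")
    df = _read_table(event_source)
    # rMATS MXE columns start with digits, which itertuples cannot carry
    df = df.rename(
        columns={
            "1stExonStart_0base": "firstExonStart_0base",
            "1stExonEnd": "firstExonEnd",
            "2ndExonStart_0base": "secondExonStart_0base",
            "2ndExonEnd": "secondExonEnd",
        }
    )
    genes = _gene_index(annotation)
    out: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        gid = str(getattr(row, "GeneID", "")).strip('"')
        candidates = genes.get(gid, [])
        produced = False
        for tx in candidates:
            rec = _alt_splice_record(row, event_type, tx, genome, i)
            if rec is not None:
                out.append(rec)
                produced = True
        if not produced:
            logger.warning(
                "parse_alt_splicing: %s event %d not reconcilable; dropped",
                event_type, i,
            )
    return out


def _alt_splice_record(row, event_type, tx, genome, idx) -> VariantRecord | None:
    vid = f"{event_type}_{idx}_{tx.transcript_id}"
    try:
        if event_type == "SE":
            es, ee = int(row.exonStart_0base), int(row.exonEnd)
            if (es, ee) not in tx.exons:
                return None
            a = tx.genomic_to_tx(es if tx.strand == "+" else ee - 1)
            b = tx.genomic_to_tx(ee - 1 if tx.strand == "+" else es) + 1
            from .reference import transcript_sequence

            ref = transcript_sequence(genome, tx)[a:b]
            return VariantRecord(
                gene_id=tx.gene_id, transcript_ids=(tx.transcript_id,),
                start_tx=a, end_tx=b, ref_seq=ref, alt_seq="",
                type="ALT_SPLICE_SE", source="AltSplice", variant_id=vid,
            )
        if event_type == "RI":
            ues, uee = int(row.upstreamES), int(row.upstreamEE)
            des, dee = int(row.downstreamES), int(row.downstreamEE)
            if (ues, uee) not in tx.exons or (des, dee) not in tx.exons:
                return None
            if tx.strand == "+":
                gstart, gend = uee, des
                point = tx.genomic_to_tx(des)  # first base of downstream exon
            else:
                # rMATS "upstream" is 5' in transcript orientation, hence
                # genomically rightmost on the - strand
                gstart, gend = dee, ues
                point = tx.genomic_to_tx(dee - 1)
            if gend <= gstart:
                return None
            alt = _genomic_span_seq(genome, tx, gstart, gend)
            return VariantRecord(
                gene_id=tx.gene_id, transcript_ids=(tx.transcript_id,),
                start_tx=point, end_tx=point, ref_seq="", alt_seq=alt,
                type="ALT_SPLICE_RI", source="AltSplice", variant_id=vid,
            )
        if event_type in ("A3SS", "A5SS"):
            ls, le = int(row.longExonStart_0base), int(row.longExonEnd)
            ss, se = int(row.shortES), int(row.shortEE)
            if (ss, se) not in tx.exons:
                return None
            if ls == ss and le > se:  # extension past the genomic end
                gstart, gend = se, le
                point = (
                    tx.genomic_to_tx(se - 1) + 1
                    if tx.strand == "+"
                    else tx.genomic_to_tx(se - 1)
                )
            elif le == se and ls < ss:  # extension before the genomic start
                gstart, gend = ls, ss
                point = (
                    tx.genomic_to_tx(ss)
                    if tx.strand == "+"
                    else tx.genomic_to_tx(ss) + 1
                )
            else:
                return None
            alt = _genomic_span_seq(genome, tx, gstart, gend)
            return VariantRecord(
                gene_id=tx.gene_id, transcript_ids=(tx.transcript_id,),
                start_tx=point, end_tx=point, ref_seq="", alt_seq=alt,
                type=f"ALT_SPLICE_{event_type}", source="AltSplice",
                variant_id=vid,
            )
        # MXE: replace exon 1 by exon 2
        e1s, e1e = int(row.firstExonStart_0base), int(row.firstExonEnd)
        e2s, e2e = int(row.secondExonStart_0base), int(row.secondExonEnd)
        if (e1s, e1e) not in tx.exons:
            return None
        a = tx.genomic_to_tx(e1s if tx.strand == "+" else e1e - 1)
        b = tx.genomic_to_tx(e1e - 1 if tx.strand == "+" else e1s) + 1
        from .reference import transcript_sequence

        ref = transcript_sequence(genome, tx)[a:b]
        alt = _genomic_span_seq(genome, tx, e2s, e2e)
        return VariantRecord(
            gene_id=tx.gene_id, transcript_ids=(tx.transcript_id,),
            start_tx=a, end_tx=b, ref_seq=ref, alt_seq=alt,
            type="ALT_SPLICE_MXE", source="AltSplice", variant_id=vid,
        )
    except (ValueError, AttributeError):
        return None


# -- RNA editing -----------------------------------------------------------


def parse_rna_editing(
    source,
    annotation: Mapping[str, TranscriptModel],
    genome: GenomeAssembly,
) -> list[VariantRecord]:
    """REDItools-style site table -> SNV records with source RNAEditing.

    Expected columns: ``Region`` (chromosome), ``Position`` (1-based),
    ``Reference`` and ``AllSubs`` (space-separated substitutions such as
    ``AG``).  Sites in introns are dropped; reference mismatches are
    rejected with a diagnostic.
    """
    df = _read_table(source, dtype=str)
    out: list[VariantRecord] = []
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for tx in annotation.values():
        by_chrom.setdefault(tx.chromosome, []).append(tx)
    for row in df.itertuples(index=False):
        chrom = str(row.Region)
        gpos = int(row.Position) - 1
        ref = str(row.Reference)
        if genome.fetch(chrom, gpos, gpos + 1) != ref:
            logger.error(
                "parse_rna_editing: reference mismatch at %s:%d; rejected",
                chrom, gpos + 1,
            )
            continue
        subs = [s for s in str(row.AllSubs).replace(",", " ").split() if len(s) == 2]
        for tx in by_chrom.get(chrom, []):
            if not tx.overlaps_exon(gpos, gpos + 1):
                continue
            for sub in subs:
                if sub[0] != ref:
                    continue
                try:
                    rec = _genomic_to_tx_record(
                        tx, genome, gpos, gpos + 1, ref, sub[1],
                        f"RE_{chrom}_{gpos + 1}_{sub}", "RNAEditing",
                    )
                except GVFError:
                    continue
                if rec is not None:
                    out.append(rec)
    return out


# -- circRNA ---------------------------------------------------------------


def parse_circrna(
    source,
    annotation: Mapping[str, TranscriptModel],
) -> list[CircRNAModel]:
    """CIRCexplorer2-style table -> circRNA models with transcript segments.

    Expected columns: ``chrom``, ``start``, ``end``, ``strand``,
    ``isoformName`` (host transcript); the circle comprises the host
    transcript exons overlapped by ``[start, end)``, clipped to the
    span, in transcript order.
    """
    df = _read_table(source, dtype=str)
    out: list[CircRNAModel] = []
    for i, row in enumerate(df.itertuples(index=False)):
        tx = annotation.get(str(row.isoformName))
        if tx is None:
            logger.warning("parse_circrna: unknown transcript %s; dropped",
                           row.isoformName)
            continue
        gstart, gend = int(row.start), int(row.end)
        segments: list[tuple[int, int]] = []
        for (a, b) in tx.exons:
            lo, hi = max(a, gstart), min(b, gend)
            if lo < hi:
                ta = tx.genomic_to_tx(lo if tx.strand == "+" else hi - 1)
                tb = tx.genomic_to_tx(hi - 1 if tx.strand == "+" else lo) + 1
                segments.append((ta, tb))
        if not segments:
            logger.warning("parse_circrna: row %d overlaps no exon; dropped", i)
            continue
        segments.sort()
        out.append(
            CircRNAModel(
                circ_id=f"CIRC_{row.chrom}_{gstart}_{gend}",
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                segments=tuple(segments),
            )
        )
    return out
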