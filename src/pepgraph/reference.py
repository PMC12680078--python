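"""Reference sequence models: genome, transcript annotation and translation.

This module owns the three reference inputs of a proteogenomic run — the
genome assembly (FASTA), the gene annotation (GTF, GENCODE or Ensembl
dialect) and the codon table — plus the coordinate arithmetic between
genomic and spliced-transcript space that everything downstream relies on.

Conventions
-----------
* All internal coordinates are 0-based, half-open.  GTF input (1-based,
  inclusive) is converted on ingestion.
* Transcript coordinates live in spliced-transcript space, 5'->3' on the
  transcript's own strand: position 0 is the first transcribed base.
* ``N`` bases are carried through; any codon containing ``N`` translates
  to ``X``.  Peptides containing ``X`` are suppressed at output time by
  the caller, not here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from gffutils.feature import feature_from_line

__all__ = [
    "GenomeAssembly",
    "TranscriptModel",
    "CodonTable",
    "STANDARD_TABLE",
    "AnnotationError",
    "load_annotation",
    "transcript_sequence",
    "translate",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_NT = frozenset("ACGTN")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string over A/C/G/T/N."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeAssembly:
    """Chromosome name -> upper-cased nucleotide sequence (A/C/G/T/N).

    Construct from a plain mapping (tests, simulations) or from a FASTA
    file with :meth:`from_fasta`.
    """

    def __init__(self, chromosomes: Mapping[str, str]):
        self._chroms: dict[str, str] = {}
        for name, seq in chromosomes.items():
            seq = str(seq).upper()
            bad = set(seq) - _VALID_NT
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            self._chroms[name] = seq

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeAssembly":
        import pyfaidx

        fasta = pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)
        return cls({name: str(fasta[name][:]) for name in fasta.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def chromosome(self, chrom: str) -> str:
        try:
            return self._chroms[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in assembly") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence ``[start, end)`` of ``chrom``; length is ``end - start``."""
        seq = self.chromosome(chrom)
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom!r} "
                f"(length {len(seq)})"
            )
        return seq[start:end]


@dataclass
class TranscriptModel:
    """Exon structure and ORF annotation of one transcript.

    ``exons`` are genomic intervals in ascending genomic order regardless
    of strand; transcript order is the reverse for ``-`` strand.
    ``cds_start_tx``/``cds_end_tx`` are transcript-coordinate ORF bounds
    that exclude the stop codon: translation discovers stops from sequence.
    ``selenocysteine_positions_tx`` are transcript coordinates of codon
    starts at which TGA encodes selenocysteine (U).
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_tx: int | None = None
    cds_end_tx: int | None = None
    selenocysteine_positions_tx: list[int] = field(default_factory=list)
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a >= b:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{a}, {b})")
        for (_, b), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        if self.is_coding:
            if not (0 <= self.cds_start_tx < self.cds_end_tx <= self.length):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS bounds "
                    f"[{self.cds_start_tx}, {self.cds_end_tx}) outside transcript "
                    f"of length {self.length}"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_start_tx is not None and self.cds_end_tx is not None

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    # -- coordinate mapping -------------------------------------------------

    def tx_to_genomic(self, pos: int) -> int:
        """Map a transcript coordinate to its genomic coordinate."""
        if not (0 <= pos < self.length):
            raise ValueError(
                f"{self.transcript_id}: transcript position {pos} out of range "
                f"[0, {self.length})"
            )
        if self.strand == "+":
            off = pos
            for a, b in self.exons:
                if off < b - a:
                    return a + off
                off -= b - a
        else:
            off = pos
            for a, b in reversed(self.exons):
                if off < b - a:
                    return b - 1 - off
                off -= b - a
        raise AssertionError("unreachable")

    def genomic_to_tx(self, gpos: int) -> int:
        """Map a genomic coordinate to its transcript coordinate.

        Raises ``ValueError`` if ``gpos`` does not fall in an exon.
        """
        if self.strand == "+":
            off = 0
            for a, b in self.exons:
                if a <= gpos < b:
                    return off + (gpos - a)
                off += b - a
        else:
            off = 0
            for a, b in reversed(self.exons):
                if a <= gpos < b:
                    return off + (b - 1 - gpos)
                off += b - a
        raise ValueError(
            f"{self.transcript_id}: genomic position {gpos} not exonic"
        )

    def overlaps_exon(self, gstart: int, gend: int) -> bool:
        return any(a < gend and gstart < b for a, b in self.exons)


@dataclass(frozen=True)
class CodonTable:
    """Codon -> amino-acid map with stop codons and the selenocysteine rule.

    TGA translates to ``U`` only at codon-start offsets listed by the
    caller (annotated selenocysteine positions); everywhere else it is a
    stop codon.
    """

    forward: Mapping[str, str]
    stop_codons: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

    def __post_init__(self) -> None:
        if len(self.forward) != 64:
            raise ValueError("codon table must map all 64 codons")

    def amino_acid(self, codon: str) -> str:
        """Translate one codon; '*' for stops, 'X' for codons containing N."""
        if "N" in codon:
            return "X"
        if codon in self.stop_codons:
            return "*"
        return self.forward[codon]


def _standard_forward() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


STANDARD_TABLE = CodonTable(forward=_standard_forward())


def translate(
    seq: str,
    table: CodonTable = STANDARD_TABLE,
    sec_positions: Iterable[int] = (),
    stop_behavior: str = "truncate_at_stop",
) -> str:
    """Translate ``seq`` codon by codon from offset 0.

    ``sec_positions`` are codon-start offsets within ``seq`` where TGA
    reads as selenocysteine (U).  ``stop_behavior``:

    * ``truncate_at_stop`` — halt at the first stop codon (default);
    * ``read_through_unknown`` — emit ``X`` for stop codons and continue.

    A trailing 1-2 nt remainder is dropped.  Non-ACGTN characters raise
    ``ValueError``.
    """
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    if stop_behavior not in ("truncate_at_stop", "read_through_unknown"):
        raise ValueError(f"unknown stop_behavior {stop_behavior!r}")
    secs = set(sec_positions)
    out: list[str] = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon == "TGA" and i in secs:
            out.append("U")
            continue
        aa = table.amino_acid(codon)
        if aa == "*":
            if stop_behavior == "truncate_at_stop":
                break
            out.append("X")
        else:
            out.append(aa)
    return "".join(out)


def transcript_sequence(genome: GenomeAssembly, tx: TranscriptModel) -> str:
    """Spliced transcript sequence, 5'->3' on the transcript's strand.

    Exon sequences are concatenated in genomic order and reverse
    complemented for ``-`` strand transcripts.  Exons outside chromosome
    bounds raise ``ValueError``.
    """
    parts = [genome.fetch(tx.chromosome, a, b) for a, b in tx.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if tx.strand == "-" else seq


# -- GTF ingestion ---------------------------------------------------------

_CONSUMED_FEATURES = {"gene", "transcript", "exon", "CDS", "stop_codon"}


def load_annotation(gtf_source) -> dict[str, TranscriptModel]:
    """Parse a GTF into transcript models keyed by transcript id.

    ``gtf_source`` is a path or an open text handle.  Only
    gene/transcript/exon/CDS/stop_codon features are consumed; both
    GENCODE and Ensembl attribute quoting are accepted (delegated to
    gffutils' line parser).  CDS features are converted to transcript
    coordinates; a CDS outside the transcript's exons rejects the model.
    """
    if hasattr(gtf_source, "read"):
        handle = gtf_source
        close = False
    else:
        handle = open(gtf_source)
        close = True
    try:
        return _load_annotation_handle(handle)
    finally:
        if close:
            handle.close()


def _load_annotation_handle(handle: io.TextIOBase) -> dict[str, TranscriptModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []

    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line, dialect=None)
        except Exception as exc:  # pragma: no cover - gffutils error text varies
            raise AnnotationError(f"line {lineno}: unparseable GTF line: {exc}")
        if feat.featuretype not in _CONSUMED_FEATURES:
            continue
        if feat.featuretype == "gene":
            continue
        attrs = feat.attributes
        tx_ids = attrs.get("transcript_id")
        if not tx_ids:
            raise AnnotationError(
                f"line {lineno}: {feat.featuretype} feature lacks transcript_id"
            )
        tx_id = tx_ids[0]
        start0 = feat.start - 1  # GTF is 1-based inclusive
        end0 = feat.end
        if tx_id not in meta:
            gene_ids = attrs.get("gene_id") or [""]
            meta[tx_id] = {
                "gene_id": gene_ids[0],
                "chromosome": feat.seqid,
                "strand": feat.strand,
                "tags": set(attrs.get("tag", [])),
            }
            order.append(tx_id)
        if feat.featuretype == "exon":
            exons.setdefault(tx_id, []).append((start0, end0))
        elif feat.featuretype == "CDS":
            cds.setdefault(tx_id, []).append((start0, end0))
        elif feat.featuretype == "stop_codon":
            meta[tx_id]["tags"].add("stop-codon-annotated")

    models: dict[str, TranscriptModel] = {}
    for tx_id in order:
        if tx_id not in exons:
            continue  # transcript line without exons: nothing to model
        m = meta[tx_id]
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=m["gene_id"],
            chromosome=m["chromosome"],
            strand=m["strand"],
            exons=exons[tx_id],
            tags=m["tags"],
        )
        if tx_id in cds:
            tx_positions: list[int] = []
            for a, b in cds[tx_id]:
                for g in (a, b - 1):
                    try:
                        tx_positions.append(model.genomic_to_tx(g))
                    except ValueError:
                        raise AnnotationError(
                            f"{tx_id}: CDS [{a}, {b}) outside exons"
                        )
            model.cds_start_tx = min(tx_positions)
            model.cds_end_tx = max(tx_positions) + 1
            model = TranscriptModel(  # re-validate CDS bounds
                transcript_id=model.transcript_id,
                gene_id=model.gene_id,
                chromosome=model.chromosome,
                strand=model.strand,
                exons=model.exons,
                cds_start_tx=model.cds_start_tx,
                cds_end_tx=model.cds_end_tx,
                tags=model.tags,
            )
        models[tx_id] = model
    return models
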