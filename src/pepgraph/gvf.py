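"""Gene-centric variant records and the GVF text format.

GVF is a tab-separated, VCF-derived dialect storing one variant per line
in *transcript* coordinates:

``CHROM=gene_id  POS=start_tx+1  ID=variant_id  REF  ALT  QUAL='.'
FILTER='.'  INFO``

INFO carries ``TRANSCRIPT=`` (comma-joined transcript ids), ``TYPE=``,
``SOURCE=`` and optional keys (``PARENT=`` for variants nested inside an
alternative-splicing insertion, whose coordinates are then offsets into
the parent's alternative sequence).  ``##`` metadata headers name the
producing parser and annotation version.  Records are ordered by
(gene_id, start_tx, alt_seq) so that a write-read-write round trip is
byte stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "VariantRecord",
    "FusionEvent",
    "CircRNAModel",
    "GVFError",
    "read_gvf",
    "write_gvf",
    "read_fusion_gvf",
    "write_fusion_gvf",
    "read_circ_gvf",
    "write_circ_gvf",
    "VARIANT_TYPES",
    "VARIANT_SOURCES",
]

VARIANT_TYPES = {
    "SNV",
    "INSERTION",
    "DELETION",
    "SUBSTITUTION",
    "RNA_EDITING",
    "ALT_SPLICE_SE",
    "ALT_SPLICE_RI",
    "ALT_SPLICE_A3SS",
    "ALT_SPLICE_A5SS",
    "ALT_SPLICE_MXE",
    "FUSION",
    "CIRC_RNA",
}

VARIANT_SOURCES = {
    "gSNP",
    "gIndel",
    "sSNV",
    "sIndel",
    "RNAEditing",
    "AltSplice",
    "Fusion",
    "circRNA",
    "Simulated",
}


class GVFError(ValueError):
    """Malformed GVF content."""


@dataclass(frozen=True)
class VariantRecord:
    """One gene-centric variant in transcript coordinates.

    ``[start_tx, end_tx)`` is the replaced reference span on the
    transcript; ``ref_seq``/``alt_seq`` are the replaced and replacement
    nucleotides (either may be empty, not both).  A record with
    ``parent_id`` set lives inside the inserted sequence of an
    alternative-splicing variant: its coordinates are offsets into the
    parent's ``alt_seq`` and it is only applicable together with the
    parent.
    """

    gene_id: str
    transcript_ids: tuple[str, ...]
    start_tx: int
    end_tx: int
    ref_seq: str
    alt_seq: str
    type: str
    source: str
    variant_id: str
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.type not in VARIANT_TYPES:
            raise GVFError(f"unknown variant type {self.type!r}")
        if self.source not in VARIANT_SOURCES:
            raise GVFError(f"unknown variant source {self.source!r}")
        if self.end_tx - self.start_tx != len(self.ref_seq):
            raise GVFError(
                f"{self.variant_id}: end_tx - start_tx = "
                f"{self.end_tx - self.start_tx} != len(ref_seq) = {len(self.ref_seq)}"
            )
        if self.type == "SNV" and not (len(self.ref_seq) == len(self.alt_seq) == 1):
            raise GVFError(f"{self.variant_id}: SNV must have 1 nt ref and alt")
        if not self.ref_seq and not self.alt_seq:
            raise GVFError(f"{self.variant_id}: ref and alt both empty")

    @property
    def s_ref(self) -> int:
        return len(self.ref_seq)

    @property
    def s_alt(self) -> int:
        return len(self.alt_seq)

    @property
    def frameshift(self) -> int:
        """Net reading-frame shift (S_ref - S_alt) mod 3 in {0, 1, 2}."""
        return (self.s_ref - self.s_alt) % 3

    @property
    def is_frameshifting(self) -> bool:
        return self.frameshift != 0

    @property
    def is_alt_splice(self) -> bool:
        return self.type.startswith("ALT_SPLICE_")

    def overlaps(self, other: "VariantRecord") -> bool:
        """Do the two replaced spans intersect (same coordinate space)?

        Zero-length (pure insertion) spans conflict with any span that
        contains or touches the insertion point interior-wise.
        """
        a0, a1 = self.start_tx, self.end_tx
        b0, b1 = other.start_tx, other.end_tx
        if a0 == a1 and b0 == b1:
            return a0 == b0
        if a0 == a1:
            return b0 < a0 < b1 or b0 == a0 == b1
        if b0 == b1:
            return a0 < b0 < a1 or a0 == b0 == a1
        return a0 < b1 and b0 < a1

    def validate_against(self, seq: str) -> None:
        """Check ``ref_seq`` against the sequence the record claims to edit."""
        if self.start_tx < 0 or self.end_tx > len(seq):
            raise GVFError(
                f"{self.variant_id}: span [{self.start_tx}, {self.end_tx}) outside "
                f"sequence of length {len(seq)}"
            )
        found = seq[self.start_tx : self.end_tx]
        if found != self.ref_seq:
            raise GVFError(
                f"{self.variant_id}: ref mismatch at [{self.start_tx}, "
                f"{self.end_tx}): expected {self.ref_seq!r}, sequence has {found!r}"
            )

    def for_transcript(self, transcript_id: str) -> "VariantRecord":
        return replace(self, transcript_ids=(transcript_id,))


@dataclass(frozen=True)
class FusionEvent:
    """A donor/acceptor transcript pair with breakpoints.

    Breakpoints are transcript coordinates when the break falls in an
    exon.  When it falls in an intron, the ``*_intronic`` flag is set,
    ``*_intron_idx`` names the intron (0-based, transcript order) and
    the breakpoint is an offset into that intron in transcript
    direction.  The donor contributes its sequence 5' of
    ``donor_breakpoint``; the acceptor contributes from
    ``acceptor_breakpoint`` on.
    """

    fusion_id: str
    donor_gene_id: str
    donor_transcript_id: str
    acceptor_gene_id: str
    acceptor_transcript_id: str
    donor_breakpoint: int
    acceptor_breakpoint: int
    donor_intronic: bool = False
    acceptor_intronic: bool = False
    donor_intron_idx: int | None = None
    acceptor_intron_idx: int | None = None


@dataclass(frozen=True)
class CircRNAModel:
    """A back-spliced circular RNA built from host transcript segments."""

    circ_id: str
    gene_id: str
    transcript_id: str
    segments: tuple[tuple[int, int], ...]  # transcript-coordinate intervals
    intron_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.segments:
            raise GVFError(f"{self.circ_id}: empty segment list")
        if sum(b - a for a, b in self.segments) < 1:
            raise GVFError(f"{self.circ_id}: zero-length circRNA")


# -- serialization ---------------------------------------------------------

_HEADER_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"


def _sort_key(rec: VariantRecord):
    return (rec.gene_id, rec.start_tx, rec.alt_seq, rec.variant_id)


def write_gvf(
    records: Iterable[VariantRecord],
    path_or_handle,
    parser_name: str = "pepgraph",
    annotation_version: str = ".",
) -> None:
    """Write records as GVF with deterministic ordering."""
    if hasattr(path_or_handle, "write"):
        _write_gvf_handle(records, path_or_handle, parser_name, annotation_version)
    else:
        with open(path_or_handle, "w") as fh:
            _write_gvf_handle(records, fh, parser_name, annotation_version)


def _write_gvf_handle(records, fh, parser_name, annotation_version) -> None:
    fh.write("##fileformat=GVF\n")
    fh.write(f"##parser={parser_name}\n")
    fh.write(f"##annotation={annotation_version}\n")
    fh.write(_HEADER_COLUMNS + "\n")
    for rec in sorted(records, key=_sort_key):
        info = [
            "TRANSCRIPT=" + ",".join(rec.transcript_ids),
            "TYPE=" + rec.type,
            "SOURCE=" + rec.source,
        ]
        if rec.parent_id is not None:
            info.append("PARENT=" + rec.parent_id)
        fh.write(
            "\t".join(
                [
                    rec.gene_id,
                    str(rec.start_tx + 1),
                    rec.variant_id,
                    rec.ref_seq or ".",
                    rec.alt_seq or ".",
                    ".",
                    ".",
                    ";".join(info),
                ]
            )
            + "\n"
        )


def read_gvf(path_or_handle) -> list[VariantRecord]:
    """Read a GVF file; malformed lines raise :class:`GVFError` with line number."""
    if hasattr(path_or_handle, "read"):
        return _read_gvf_handle(path_or_handle)
    with open(path_or_handle) as fh:
        return _read_gvf_handle(fh)


def _read_gvf_handle(fh) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise GVFError(f"line {lineno}: expected 8 columns, got {len(fields)}")
        gene_id, pos, vid, ref, alt, _qual, _filt, info = fields
        try:
            start = int(pos) - 1
        except ValueError:
            raise GVFError(f"line {lineno}: non-integer POS {pos!r}")
        ref = "" if ref == "." else ref
        alt = "" if alt == "." else alt
        kv: dict[str, str] = {}
        for item in info.split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                kv[k] = v
        for key in ("TRANSCRIPT", "TYPE", "SOURCE"):
            if key not in kv:
                raise GVFError(f"line {lineno}: INFO lacks {key}=")
        try:
            records.append(
                VariantRecord(
                    gene_id=gene_id,
                    transcript_ids=tuple(t for t in kv["TRANSCRIPT"].split(",") if t),
                    start_tx=start,
                    end_tx=start + len(ref),
                    ref_seq=ref,
                    alt_seq=alt,
                    type=kv["TYPE"],
                    source=kv["SOURCE"],
                    variant_id=vid,
                    parent_id=kv.get("PARENT"),
                )
            )
        except GVFError as exc:
            raise GVFError(f"line {lineno}: {exc}")
    return records


# -- fusion / circRNA GVF dialects ----------------------------------------


def write_fusion_gvf(events: Iterable[FusionEvent], path_or_handle) -> None:
    """Fusion events in the GVF container (TYPE=FUSION rows)."""
    def _write(fh):
        fh.write("##fileformat=GVF\n##dialect=fusion\n")
        fh.write(_HEADER_COLUMNS + "\n")
        for e in sorted(events, key=lambda x: x.fusion_id):
            info = [
                f"TYPE=FUSION",
                f"SOURCE=Fusion",
                f"DONOR_TX={e.donor_transcript_id}",
                f"ACCEPTOR_GENE={e.acceptor_gene_id}",
                f"ACCEPTOR_TX={e.acceptor_transcript_id}",
                f"ACCEPTOR_BP={e.acceptor_breakpoint}",
                f"DONOR_INTRONIC={int(e.donor_intronic)}",
                f"ACCEPTOR_INTRONIC={int(e.acceptor_intronic)}",
                f"DONOR_INTRON={e.donor_intron_idx if e.donor_intron_idx is not None else '.'}",
                f"ACCEPTOR_INTRON={e.acceptor_intron_idx if e.acceptor_intron_idx is not None else '.'}",
            ]
            fh.write(
                "\t".join(
                    [
                        e.donor_gene_id,
                        str(e.donor_breakpoint + 1),
                        e.fusion_id,
                        ".",
                        ".",
                        ".",
                        ".",
                        ";".join(info),
                    ]
                )
                + "\n"
            )

    if hasattr(path_or_handle, "write"):
        _write(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _write(fh)


def read_fusion_gvf(path_or_handle) -> list[FusionEvent]:
    def _read(fh):
        out = []
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise GVFError(f"line {lineno}: expected 8 columns")
            kv = dict(
                item.split("=", 1) for item in fields[7].split(";") if "=" in item
            )
            if kv.get("TYPE") != "FUSION":
                raise GVFError(f"line {lineno}: not a fusion record")
            out.append(
                FusionEvent(
                    fusion_id=fields[2],
                    donor_gene_id=fields[0],
                    donor_transcript_id=kv["DONOR_TX"],
                    acceptor_gene_id=kv["ACCEPTOR_GENE"],
                    acceptor_transcript_id=kv["ACCEPTOR_TX"],
                    donor_breakpoint=int(fields[1]) - 1,
                    acceptor_breakpoint=int(kv["ACCEPTOR_BP"]),
                    donor_intronic=kv.get("DONOR_INTRONIC") == "1",
                    acceptor_intronic=kv.get("ACCEPTOR_INTRONIC") == "1",
                    donor_intron_idx=None
                    if kv.get("DONOR_INTRON", ".") == "."
                    else int(kv["DONOR_INTRON"]),
                    acceptor_intron_idx=None
                    if kv.get("ACCEPTOR_INTRON", ".") == "."
                    else int(kv["ACCEPTOR_INTRON"]),
                )
            )
        return out

    if hasattr(path_or_handle, "read"):
        return _read(path_or_handle)
    with open(path_or_handle) as fh:
        return _read(fh)


def write_circ_gvf(models: Iterable[CircRNAModel], path_or_handle) -> None:
    """circRNA models in the GVF container (TYPE=CIRC_RNA rows)."""
    def _write(fh):
        fh.write("##fileformat=GVF\n##dialect=circRNA\n")
        fh.write(_HEADER_COLUMNS + "\n")
        for c in sorted(models, key=lambda x: x.circ_id):
            segs = ",".join(f"{a}-{b}" for a, b in c.segments)
            info = [
                "TYPE=CIRC_RNA",
                "SOURCE=circRNA",
                f"TRANSCRIPT={c.transcript_id}",
                f"SEGMENTS={segs}",
            ]
            fh.write(
                "\t".join(
                    [
                        c.gene_id,
                        str(c.segments[0][0] + 1),
                        c.circ_id,
                        ".",
                        ".",
                        ".",
                        ".",
                        ";".join(info),
                    ]
                )
                + "\n"
            )

    if hasattr(path_or_handle, "write"):
        _write(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _write(fh)


def read_circ_gvf(path_or_handle) -> list[CircRNAModel]:
    def _read(fh):
        out = []
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise GVFError(f"line {lineno}: expected 8 columns")
            kv = dict(
                item.split("=", 1) for item in fields[7].split(";") if "=" in item
            )
            if kv.get("TYPE") != "CIRC_RNA":
                raise GVFError(f"line {lineno}: not a circRNA record")
            segments = tuple(
                (int(a), int(b))
                for a, b in (s.split("-") for s in kv["SEGMENTS"].split(","))
            )
            out.append(
                CircRNAModel(
                    circ_id=fields[2],
                    gene_id=fields[0],
                    transcript_id=kv["TRANSCRIPT"],
                    segments=segments,
                )
            )
        return out

    if hasattr(path_or_handle, "read"):
        return _read(path_or_handle)
    with open(path_or_handle) as fh:
        return _read(fh)
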