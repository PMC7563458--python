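"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA, FASTQ (paired), BLAST-style tabular hits (4-column minimal
and 12-column standard), BED5 TIP calls, a minimal SAM text subset, and
labels TSV.

Coordinate conventions
----------------------
Alignment hits are 1-based inclusive on the subject (BLAST convention);
BED records are 0-based half-open (BED standard). The conversion between
the two happens exactly once, at window assignment in :mod:`tipscan.tip_call`.
A raw tabular hit with subject-start > subject-end denotes a minus-strand
alignment; it is normalized to start <= end with strand ``-``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

from Bio import SeqIO

from .errors import ConfigurationError, PairingError, ParseError, ValidationError

Source = Union[str, Path, IO[str], Iterable[str]]


@dataclass(slots=True)
class SeqRecord:
    """A named DNA sequence (uppercase over A, C, G, T, N)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.seq:
            raise ValidationError(f"sequence record {self.id!r} is empty")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True, frozen=True)
class AlignmentHit:
    """One alignment of a query read to a subject sequence.

    ``start``/``end`` are 1-based inclusive on the subject, start <= end.
    ``strand`` is ``-`` exactly when the raw input had start > end.
    ``score`` is an aligner-dependent match score (0 for imported hits).
    """

    query_id: str
    subject_id: str
    start: int
    end: int
    strand: str = "+"
    score: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: invalid interval "
                f"[{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"hit {self.query_id}: bad strand {self.strand!r}")


@dataclass(slots=True, frozen=True)
class BedRecord:
    """A BED5 TIP call: window interval, TE family name, supporting-read count."""

    chrom: str
    start: int
    end: int
    name: str
    score: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"bed record {self.chrom}: invalid interval [{self.start}, {self.end})"
            )
        if self.score < 1:
            raise ValidationError(f"bed record {self.chrom}:{self.start}: score < 1")


# TipCall is the domain name for a windowed BED5 call.
TipCall = BedRecord

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(name: str):
    """Sort key ordering numeric components numerically: chr2 < chr10 < chrX."""
    return tuple(
        (0, int(part)) if part.isdigit() else (1, part)
        for part in _NAT_SPLIT.split(name)
        if part != ""
    )


def hit_sort_key(hit: AlignmentHit):
    return (natural_key(hit.subject_id), hit.start, hit.end, hit.strand, hit.query_id)


def bed_sort_key(rec: BedRecord):
    return (natural_key(rec.chrom), rec.start, rec.end, rec.name)


def _as_line_iter(source: Source) -> tuple[Iterator[str], bool]:
    """Return (line iterator, needs_close)."""
    if isinstance(source, (str, Path)):
        handle = open(source, "rt", encoding="utf-8")
        return iter(handle), True
    return iter(source), False


_DIALECTS = {
    # column indices: subject, subject-start, subject-end, query
    "minimal4": {"ncols": 4, "s": 0, "ss": 1, "se": 2, "q": 3},
    # NCBI outfmt 6: qseqid sseqid pident length mismatch gapopen
    #                qstart qend sstart send evalue bitscore
    "blast12": {"ncols": 12, "s": 1, "ss": 8, "se": 9, "q": 0},
}


def read_tabular_hits(source: Source, dialect: str = "minimal4") -> list[AlignmentHit]:
    """Parse tabular alignment hits, normalizing minus-strand intervals.

    ``minimal4`` columns: subject id, subject start, subject end, query id.
    ``blast12`` is standard BLAST outfmt 6. Rows are kept in input order;
    no e-value or identity thresholding is applied here.
    """
    if dialect not in _DIALECTS:
        raise ConfigurationError(
            f"unknown tabular dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        )
    layout = _DIALECTS[dialect]
    hits: list[AlignmentHit] = []
    lines, close = _as_line_iter(source)
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < layout["ncols"]:
                raise ParseError(
                    f"line {lineno}: expected >= {layout['ncols']} columns for "
                    f"{dialect}, got {len(fields)}"
                )
            try:
                sstart = int(fields[layout["ss"]])
                send = int(fields[layout["se"]])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if sstart <= 0 or send <= 0:
                raise ParseError(f"line {lineno}: non-positive coordinate")
            strand = "+"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-"
            hits.append(
                AlignmentHit(
                    query_id=fields[layout["q"]],
                    subject_id=fields[layout["s"]],
                    start=sstart,
                    end=send,
                    strand=strand,
                )
            )
    finally:
        if close:
            lines.close()  # type: ignore[union-attr]
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], dest: Union[str, Path, IO[str]]) -> None:
    """Write hits in the minimal 4-column dialect (subject, start, end, query).

    Minus-strand hits are emitted with start > end, round-tripping the
    normalization applied by :func:`read_tabular_hits`.
    """
    own = isinstance(dest, (str, Path))
    handle: IO[str] = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[assignment]
    try:
        for h in hits:
            s, e = (h.end, h.start) if h.strand == "-" else (h.start, h.end)
            handle.write(f"{h.subject_id}\t{s}\t{e}\t{h.query_id}\n")
    finally:
        if own:
            handle.close()


def strip_mate_suffix(read_id: str) -> str:
    """Drop a trailing ``/1`` or ``/2`` (or ``.1``/``.2``) mate marker."""
    if len(read_id) > 2 and read_id[-2] in "/." and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def _parse_fastq(source: Source, which: str) -> list[SeqRecord]:
    handle_owned = isinstance(source, (str, Path))
    handle = open(source, "rt", encoding="utf-8") if handle_owned else source
    try:
        try:
            return [
                SeqRecord(id=strip_mate_suffix(rec.id), seq=str(rec.seq))
                for rec in SeqIO.parse(handle, "fastq")
            ]
        except ValueError as exc:
            raise ParseError(f"{which}: malformed FASTQ: {exc}") from exc
    finally:
        if handle_owned:
            handle.close()  # type: ignore[union-attr]


def read_pairs_fastq(r1: Source, r2: Source) -> list[tuple[SeqRecord, SeqRecord]]:
    """Read two FASTQ streams into record-order mate pairs.

    Mate-number suffixes are stripped so both mates of a pair share one core
    id. Base qualities are discarded: nothing downstream uses them.
    """
    recs1 = _parse_fastq(r1, "R1")
    recs2 = _parse_fastq(r2, "R2")
    if len(recs1) != len(recs2):
        raise PairingError(
            f"mate files differ in record count: R1 has {len(recs1)}, R2 has {len(recs2)}"
        )
    return list(zip(recs1, recs2))


def read_fasta(source: Source) -> list[SeqRecord]:
    handle_owned = isinstance(source, (str, Path))
    handle = open(source, "rt", encoding="utf-8") if handle_owned else source
    try:
        return [SeqRecord(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if handle_owned:
            handle.close()  # type: ignore[union-attr]


def write_fasta(records: Iterable[SeqRecord], dest: Union[str, Path, IO[str]], width: int = 70) -> None:
    own = isinstance(dest, (str, Path))
    handle: IO[str] = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[assignment]
    try:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


def write_fastq(records: Iterable[SeqRecord], dest: Union[str, Path, IO[str]], qual_char: str = "I") -> None:
    own = isinstance(dest, (str, Path))
    handle: IO[str] = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[assignment]
    try:
        for rec in records:
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{qual_char * len(rec.seq)}\n")
    finally:
        if own:
            handle.close()


def write_bed(calls: Sequence[BedRecord], dest: Union[str, Path, IO[str]]) -> None:
    """Write BED5 calls in canonical (natural chrom, start) order."""
    ordered = sorted(calls, key=bed_sort_key)
    own = isinstance(dest, (str, Path))
    handle: IO[str] = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[assignment]
    try:
        for rec in ordered:
            handle.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{rec.score}\n")
    finally:
        if own:
            handle.close()


def read_bed(source: Source) -> list[BedRecord]:
    records: list[BedRecord] = []
    lines, close = _as_line_iter(source)
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"line {lineno}: expected 5 BED columns, got {len(fields)}")
            try:
                records.append(
                    BedRecord(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3],
                        score=int(fields[4]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer BED field") from exc
    finally:
        if close:
            lines.close()  # type: ignore[union-attr]
    return records


def read_labels(source: Source) -> dict[str, int]:
    """Read a two-column TSV of sample_id and 0/1 condition label."""
    labels: dict[str, int] = {}
    lines, close = _as_line_iter(source)
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected sample_id<TAB>label")
            if fields[1] not in ("0", "1"):
                raise ParseError(f"line {lineno}: label must be 0 or 1, got {fields[1]!r}")
            labels[fields[0]] = int(fields[1])
    finally:
        if close:
            lines.close()  # type: ignore[union-attr]
    return labels


def write_labels(labels: dict[str, int], dest: Union[str, Path, IO[str]]) -> None:
    own = isinstance(dest, (str, Path))
    handle: IO[str] = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[assignment]
    try:
        for sample in sorted(labels, key=natural_key):
            handle.write(f"{sample}\t{labels[sample]}\n")
    finally:
        if own:
            handle.close()


# --- minimal SAM text subset -------------------------------------------------
#
# Emitted fields: QNAME FLAG RNAME POS MAPQ=255 CIGAR=<len>M RNEXT=* PNEXT=0
# TLEN=0 SEQ=* QUAL=*. FLAG carries only 0x4 (unmapped) and 0x10 (reverse).
# This is enough to round-trip mapped/unmapped verdicts and hit intervals so
# that external aligner output can substitute for the built-in mapper.

def write_sam(
    results: Iterable,
    subject_lengths: dict[str, int],
    dest: Union[str, Path, IO[str]],
) -> None:
    """Write MapResult-shaped objects (``query_id``, ``hits``) as minimal SAM."""
    own = isinstance(dest, (str, Path))
    handle: IO[str] = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[assignment]
    try:
        handle.write("@HD\tVN:1.6\tSO:unknown\n")
        for sid in sorted(subject_lengths, key=natural_key):
            handle.write(f"@SQ\tSN:{sid}\tLN:{subject_lengths[sid]}\n")
        for res in results:
            if not res.hits:
                handle.write(f"{res.query_id}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
                continue
            for hit in res.hits:
                flag = 16 if hit.strand == "-" else 0
                cigar = f"{hit.end - hit.start + 1}M"
                handle.write(
                    f"{res.query_id}\t{flag}\t{hit.subject_id}\t{hit.start}\t255\t"
                    f"{cigar}\t*\t0\t0\t*\t*\n"
                )
    finally:
        if own:
            handle.close()


def read_sam(path: Union[str, Path]) -> dict[str, list[AlignmentHit]]:
    """Read a SAM file into query_id -> hits (empty list for unmapped reads).

    Uses pysam, so any SAM with a valid header works, not just files written
    by :func:`write_sam`.
    """
    import pysam

    out: dict[str, list[AlignmentHit]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            qname = strip_mate_suffix(aln.query_name or "")
            out.setdefault(qname, [])
            if aln.is_unmapped:
                continue
            length = aln.query_alignment_length or (aln.infer_query_length() or 0)
            if aln.cigartuples:
                ref_span = aln.reference_length or length
            else:
                ref_span = length
            start = aln.reference_start + 1  # pysam is 0-based
            end = start + max(ref_span, 1) - 1
            out[qname].append(
                AlignmentHit(
                    query_id=qname,
                    subject_id=aln.reference_name or "*",
                    start=start,
                    end=end,
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return out
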