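"""Minimal built-in read mapper: exact k-mer seeding plus ungapped extension.

This is the stand-in for the external mapping/alignment stages (a short-read
mapper against the TE consensus library, and an aligner of anchored mates
against the reference genome), so the full pipeline runs without external
binaries. It is substitution-aware but ungapped; imported SAM/BLAST files
can substitute stage-for-stage when indels matter (see
:mod:`tipscan.io_formats`).

Two parameter regimes are used by the pipeline:

* genome alignment: k=21, min_identity=0.95, min_cov=0.9 — near-exact
  placement of anchored mates;
* TE-library mapping: k=15, min_identity=0.9, min_cov=0.5 — looser, because
  genomic TE copies diverge from the family consensus and reads may overlap
  an element's edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import IndexingError
from .io_formats import AlignmentHit, SeqRecord, hit_sort_key

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Genome-alignment regime defaults.
GENOME_K = 21
GENOME_MIN_IDENTITY = 0.95
GENOME_MIN_COV = 0.9
# TE-library regime defaults (consensus sequences diverge from real copies).
TE_K = 15
TE_MIN_IDENTITY = 0.9
TE_MIN_COV = 0.5


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class SeedIndex:
    """Exact k-mer lookup table over a set of subject sequences.

    k-mers containing N are never stored. ``subjects`` keeps the raw
    sequences for the extension step.
    """

    k: int
    subject_lengths: dict[str, int] = field(default_factory=dict)
    subjects: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


@dataclass(slots=True)
class MapResult:
    """Mapping verdict for one read: all retained hits, in canonical order."""

    query_id: str
    hits: list[AlignmentHit] = field(default_factory=list)

    @property
    def mapped(self) -> bool:
        return bool(self.hits)


def build_index(subjects: Iterable[SeqRecord], k: int) -> SeedIndex:
    """Index every ACGT-only k-mer occurrence of every subject.

    Deterministic for a fixed input order. Raises
    :class:`~tipscan.errors.IndexingError` for a subject shorter than k.
    """
    if k < 11:
        raise IndexingError(f"seed length k={k} below the minimum of 11")
    index = SeedIndex(k=k)
    seeds = index.seeds
    for rec in subjects:
        seq = rec.seq
        if len(seq) < k:
            raise IndexingError(
                f"subject {rec.id!r} (length {len(seq)}) is shorter than k={k}"
            )
        index.subject_lengths[rec.id] = len(seq)
        index.subjects[rec.id] = seq
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if "N" in kmer:
                continue
            seeds.setdefault(kmer, []).append((rec.id, off))
    return index


def _seed_offsets(read_len: int, k: int, stride: int) -> list[int]:
    last = read_len - k
    offsets = list(range(0, last + 1, stride))
    if offsets[-1] != last:
        offsets.append(last)
    return offsets


def _merge_overlapping(hits: list[tuple[AlignmentHit, int]]) -> list[AlignmentHit]:
    """Collapse overlapping hits on one subject to the best-scoring one."""
    out: list[AlignmentHit] = []
    by_subject: dict[str, list[AlignmentHit]] = {}
    for hit, _ in hits:
        by_subject.setdefault(hit.subject_id, []).append(hit)
    for sid in by_subject:
        group = sorted(by_subject[sid], key=lambda h: (h.start, h.end))
        current = group[0]
        current_end = current.end
        for hit in group[1:]:
            if hit.start <= current_end:  # overlap: keep the better score
                if hit.score > current.score:
                    current = hit
                current_end = max(current_end, hit.end)
            else:
                out.append(current)
                current = hit
                current_end = hit.end
        out.append(current)
    out.sort(key=hit_sort_key)
    return out


def map_read(
    read: SeqRecord,
    index: SeedIndex,
    min_identity: float = GENOME_MIN_IDENTITY,
    min_cov: float = GENOME_MIN_COV,
    seed_stride: int | None = None,
) -> MapResult:
    """Map one read against the index, both orientations.

    Candidate loci come from exact seed matches (sampled every
    ``seed_stride`` positions, default k//2, plus the final offset); each
    candidate is scored by ungapped extension over the full read placement,
    clipped at subject ends. A hit is retained when its identity over the
    aligned span is >= ``min_identity`` and the span covers >= ``min_cov``
    of the read. Overlapping hits on one subject are merged to the
    best-scoring one. A read shorter than k returns unmapped with a warning.
    """
    k = index.k
    seq = read.seq
    length = len(seq)
    if length < k:
        logger.warning("read %s shorter than k=%d; treated as unmapped", read.id, k)
        return MapResult(query_id=read.id)
    stride = seed_stride if seed_stride is not None else max(1, k // 2)
    offsets = _seed_offsets(length, k, stride)
    seeds = index.seeds

    candidates: set[tuple[str, str, int]] = set()
    rc = reverse_complement(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for off in offsets:
            kmer = s[off : off + k]
            if "N" in kmer:
                continue
            for sid, soff in seeds.get(kmer, ()):
                candidates.add((strand, sid, soff - off))

    scored: list[tuple[AlignmentHit, int]] = []
    for strand, sid, pos in sorted(candidates):
        subject = index.subjects[sid]
        s = seq if strand == "+" else rc
        a = max(pos, 0)
        b = min(pos + length, len(subject))
        span = b - a
        if span < min_cov * length:
            continue
        window = subject[a:b]
        piece = s[a - pos : b - pos]
        matches = sum(x == y for x, y in zip(piece, window))
        if matches < min_identity * span:
            continue
        scored.append(
            (
                AlignmentHit(
                    query_id=read.id,
                    subject_id=sid,
                    start=a + 1,
                    end=b,
                    strand=strand,
                    score=matches,
                ),
                matches,
            )
        )
    if not scored:
        return MapResult(query_id=read.id)
    return MapResult(query_id=read.id, hits=_merge_overlapping(scored))


def map_reads(
    reads: Iterable[SeqRecord],
    index: SeedIndex,
    min_identity: float,
    min_cov: float,
    seed_stride: int | None = None,
) -> list[MapResult]:
    return [map_read(r, index, min_identity, min_cov, seed_stride) for r in reads]


def best_hit(result: MapResult) -> AlignmentHit | None:
    """Highest-scoring hit (ties broken by canonical order)."""
    if not result.hits:
        return None
    # hits are in canonical order; max() keeps the first of equal scores
    return max(result.hits, key=lambda h: h.score)


def results_from_hits(
    hits_by_query: dict[str, list[AlignmentHit]],
) -> dict[str, MapResult]:
    """Wrap imported per-query hit lists (e.g. from SAM) as MapResults."""
    return {
        q: MapResult(query_id=q, hits=sorted(hs, key=hit_sort_key))
        for q, hs in hits_by_query.items()
    }
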