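"""The TIP detection core.

Four steps per sample and TE family:

1. anchored-pair extraction — keep read pairs where exactly one mate mapped
   to the TE consensus library; the unmapped mate anchors the insertion in
   the genome;
2. unique-hit filtering — after aligning anchored mates to the reference,
   keep only reads with exactly one genomic alignment (ambiguous placements
   are discarded);
3. fixed-window counting — the genome is divided into a fixed grid
   (default 10 kb) and each retained read is counted in one window;
4. TIP calling — windows with at least ``min_support`` reads become BED5
   calls scored by their supporting-read count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .errors import PairingError, ValidationError
from .io_formats import AlignmentHit, BedRecord, SeqRecord, hit_sort_key, natural_key
from .kmer_align import MapResult, best_hit

WINDOW_SIZE = 10_000  # default genome grid


@dataclass(slots=True)
class PairStatus:
    """Which mate of a pair mapped to the TE library, plus the anchor mate.

    ``unmapped_mate_seq`` is present iff exactly one mate mapped; that read
    is the one aligned to the reference genome downstream. ``te_family`` is
    the subject of the mapped mate's best TE hit.
    """

    pair_id: str
    te_family: str | None
    mate1_mapped: bool
    mate2_mapped: bool
    unmapped_mate_seq: SeqRecord | None

    def __post_init__(self) -> None:
        one_mapped = self.mate1_mapped != self.mate2_mapped
        if one_mapped != (self.unmapped_mate_seq is not None):
            raise ValidationError(
                f"pair {self.pair_id}: anchor sequence presence inconsistent "
                f"with mate mapping flags"
            )


@dataclass(slots=True)
class WindowCount:
    """Supporting-read count for one genome-grid window (0-based half-open)."""

    chrom: str
    window_index: int
    start: int
    end: int
    count: int


def extract_anchored(
    pairs: Iterable[tuple[tuple[SeqRecord, MapResult], tuple[SeqRecord, MapResult]]],
) -> list[PairStatus]:
    """Keep pairs with exactly one TE-mapped mate (the discordant anchors).

    Each input element is ((read1, te_result1), (read2, te_result2)) for one
    pair. Pairs with zero or two mapped mates are dropped. Output order
    follows input order.
    """
    statuses: list[PairStatus] = []
    for (read1, res1), (read2, res2) in pairs:
        if read1.id != res1.query_id or read2.id != res2.query_id:
            raise PairingError(
                f"mate/result id mismatch: reads ({read1.id}, {read2.id}) vs "
                f"results ({res1.query_id}, {res2.query_id})"
            )
        if read1.id != read2.id:
            raise PairingError(
                f"mates with different core ids: {read1.id!r} vs {read2.id!r}"
            )
        if res1.mapped == res2.mapped:
            continue
        mapped_res, anchor = (res1, read2) if res1.mapped else (res2, read1)
        top = best_hit(mapped_res)
        statuses.append(
            PairStatus(
                pair_id=read1.id,
                te_family=top.subject_id if top else None,
                mate1_mapped=res1.mapped,
                mate2_mapped=res2.mapped,
                unmapped_mate_seq=anchor,
            )
        )
    return statuses


def unique_hit_filter(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Keep hits whose query occurs exactly once in the input.

    A read with more than one alignment record cannot place an insertion
    unambiguously and is discarded entirely. Output is in canonical
    (natural chrom, start) order. Idempotent.
    """
    multiplicity = Counter(h.query_id for h in hits)
    kept = [h for h in hits if multiplicity[h.query_id] == 1]
    kept.sort(key=hit_sort_key)
    return kept


def count_in_windows(
    hits: Sequence[AlignmentHit],
    chrom_lengths: dict[str, int],
    window_size: int = WINDOW_SIZE,
    mode: Literal["start", "overlap"] = "start",
) -> list[WindowCount]:
    """Count reads per fixed genome window.

    In ``start`` mode (default) each hit contributes 1 to the single window
    containing its 0-based alignment start, so the total count equals the
    number of hits exactly. ``overlap`` mode counts a hit once in every
    window its interval intersects (bedtools-coverage parity); totals may
    then exceed the hit count. Windows with zero count are omitted.
    """
    counters: Counter[tuple[str, int]] = Counter()
    for hit in hits:
        length = chrom_lengths.get(hit.subject_id)
        if length is None:
            raise ValidationError(
                f"hit {hit.query_id}: unknown chromosome {hit.subject_id!r}"
            )
        if hit.end > length:
            raise ValidationError(
                f"hit {hit.query_id} at {hit.subject_id}:{hit.start}-{hit.end} "
                f"extends beyond chromosome length {length}"
            )
        first = (hit.start - 1) // window_size  # 1-based -> 0-based once, here
        if mode == "start":
            counters[(hit.subject_id, first)] += 1
        else:
            last = (hit.end - 1) // window_size
            for w in range(first, last + 1):
                counters[(hit.subject_id, w)] += 1
    out = [
        WindowCount(
            chrom=chrom,
            window_index=w,
            start=w * window_size,
            end=min((w + 1) * window_size, chrom_lengths[chrom]),
            count=count,
        )
        for (chrom, w), count in counters.items()
    ]
    out.sort(key=lambda wc: (natural_key(wc.chrom), wc.start))
    return out


def call_tips(
    counts: Sequence[WindowCount],
    te_family: str,
    min_support: int = 1,
) -> list[BedRecord]:
    """Turn window counts into BED5 TIP calls (score = supporting reads)."""
    if min_support < 1:
        raise ValidationError(f"min_support must be >= 1, got {min_support}")
    calls = [
        BedRecord(chrom=wc.chrom, start=wc.start, end=wc.end, name=te_family, score=wc.count)
        for wc in counts
        if wc.count >= min_support
    ]
    calls.sort(key=lambda r: (natural_key(r.chrom), r.start))
    return calls
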