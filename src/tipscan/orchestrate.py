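"""Pipeline driver and the deterministic scatter/gather contract.

The cohort-scale workload is data-parallel: read pairs (or hit-file lines)
are split into contiguous blocks, each block runs the same stage, and the
merged result must equal the single-block run exactly, whatever the block
count. The partition/merge functions here express that contract; the
drivers run the blocks serially (any execution backend satisfying the
contract would produce identical output).

Per-sample pipeline stages:

1. map both mates of every pair against the TE consensus index;
2. keep pairs with exactly one TE-mapped mate (anchored pairs);
3. align each pair's unmapped mate against the reference genome;
4. unique-hit filter, fixed-window counting, TIP calling (BED5).

Stage record counts are logged and the conservation identity
(sum of window counts == number of unique-hit reads) is asserted on
every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import assoc, cohort, tip_call
from .errors import ConfigurationError, MergeError, ValidationError
from .io_formats import (
    AlignmentHit,
    BedRecord,
    SeqRecord,
    bed_sort_key,
    hit_sort_key,
    read_sam,
    read_tabular_hits,
)
from .kmer_align import (
    GENOME_K,
    GENOME_MIN_COV,
    GENOME_MIN_IDENTITY,
    TE_K,
    TE_MIN_COV,
    TE_MIN_IDENTITY,
    MapResult,
    SeedIndex,
    build_index,
    map_read,
    results_from_hits,
)
from .tip_call import extract_anchored, unique_hit_filter

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class RunConfig:
    """Per-sample run configuration (builtin mapper or imported alignments)."""

    sample_id: str
    window_size: int = tip_call.WINDOW_SIZE
    min_support: int = 1
    n_parts: int = 1
    count_mode: str = "start"
    te_k: int = TE_K
    te_min_identity: float = TE_MIN_IDENTITY
    te_min_cov: float = TE_MIN_COV
    genome_k: int = GENOME_K
    genome_min_identity: float = GENOME_MIN_IDENTITY
    genome_min_cov: float = GENOME_MIN_COV
    # import mode: precomputed TE-stage SAM per mate and/or genome-stage hits
    te_sam_r1: str | Path | None = None
    te_sam_r2: str | Path | None = None
    genome_hits: str | Path | None = None
    genome_hits_dialect: str = "minimal4"


@dataclass(slots=True)
class RunStats:
    """Per-stage record counts for one sample run."""

    sample_id: str
    n_pairs: int = 0
    n_anchored: int = 0
    n_genome_hits: int = 0
    n_unique: int = 0
    n_window_reads: int = 0
    n_calls: int = 0


def partition_pairs(pairs: Sequence, n_parts: int) -> list[Sequence]:
    """Contiguous balanced blocks; sizes differ by at most one.

    Trailing parts may be empty when n_parts exceeds the pair count;
    concatenating the blocks reproduces the input exactly.
    """
    if n_parts < 1:
        raise ConfigurationError(f"n_parts must be >= 1, got {n_parts}")
    total = len(pairs)
    base, extra = divmod(total, n_parts)
    blocks = []
    pos = 0
    for i in range(n_parts):
        size = base + (1 if i < extra else 0)
        blocks.append(pairs[pos : pos + size])
        pos += size
    return blocks


def partition_hit_lines(
    lines: Sequence[str], n_parts: int, dialect: str = "minimal4"
) -> list[tuple[int, int]]:
    """Balanced line ranges that never split one query across parts.

    Returns half-open (start, end) line-index ranges. Each nominal block
    boundary is extended forward to the next query-id change, so the
    unique-hit count is computable per part without a global merge of
    per-part dictionaries.
    """
    if n_parts < 1:
        raise ConfigurationError(f"n_parts must be >= 1, got {n_parts}")
    qcol = {"minimal4": 3, "blast12": 0}.get(dialect)
    if qcol is None:
        raise ConfigurationError(f"unknown dialect {dialect!r}")

    def query_of(line: str) -> str:
        fields = line.split("\t") if "\t" in line else line.split()
        return fields[qcol]

    total = len(lines)
    base, extra = divmod(total, n_parts)
    ranges: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_parts):
        size = base + (1 if i < extra else 0)
        end = min(pos + size, total)
        if pos >= total:
            ranges.append((total, total))
            continue
        # extend to the next query boundary
        while end < total and end > 0 and query_of(lines[end]) == query_of(lines[end - 1]):
            end += 1
        ranges.append((pos, end))
        pos = end
    return ranges


def merge_partials(parts: Sequence[Sequence | None]) -> list:
    """Merge part outputs into one canonically sorted, deduplicated list.

    Records identical in every field (which the partition contract makes
    impossible for honest parts) are deduplicated with a warning. A missing
    (None) part raises :class:`~tipscan.errors.MergeError`.
    """
    merged: list = []
    for i, part in enumerate(parts):
        if part is None:
            raise MergeError(f"part {i} produced no output")
        merged.extend(part)
    seen = set()
    unique = []
    for rec in merged:
        if rec in seen:
            logger.warning("duplicate record across parts dropped: %r", rec)
            continue
        seen.add(rec)
        unique.append(rec)
    if unique and isinstance(unique[0], BedRecord):
        unique.sort(key=bed_sort_key)
    elif unique and isinstance(unique[0], AlignmentHit):
        unique.sort(key=hit_sort_key)
    else:
        unique.sort()
    return unique


def _map_part_to_genome_hits(
    part: Sequence[tuple[SeqRecord, SeqRecord]],
    te_index: SeedIndex,
    genome_index: SeedIndex,
    config: RunConfig,
    stats: RunStats,
) -> list[AlignmentHit]:
    """Stages 1-3 for one block of pairs: TE mapping, anchoring, genome hits."""
    pair_results = []
    for read1, read2 in part:
        res1 = map_read(read1, te_index, config.te_min_identity, config.te_min_cov)
        res2 = map_read(read2, te_index, config.te_min_identity, config.te_min_cov)
        pair_results.append(((read1, res1), (read2, res2)))
    anchored = extract_anchored(pair_results)
    stats.n_anchored += len(anchored)
    hits: list[AlignmentHit] = []
    for status in anchored:
        anchor = status.unmapped_mate_seq
        assert anchor is not None
        result = map_read(
            anchor, genome_index, config.genome_min_identity, config.genome_min_cov
        )
        hits.extend(result.hits)
    return hits


def run_sample(
    pairs: Sequence[tuple[SeqRecord, SeqRecord]],
    te_records: Sequence[SeqRecord],
    genome_records: Sequence[SeqRecord],
    config: RunConfig,
    te_index: SeedIndex | None = None,
    genome_index: SeedIndex | None = None,
) -> tuple[list[BedRecord], RunStats]:
    """Run the four detection stages for one sample, scatter/gather style.

    Pre-built indexes may be passed to amortize construction across a
    cohort. In import mode (``config.genome_hits`` or ``config.te_sam_*``
    set), the corresponding built-in stages are skipped and the imported
    alignments are used instead.
    """
    stats = RunStats(sample_id=config.sample_id, n_pairs=len(pairs))
    te_family = te_records[0].id if te_records else "TE"
    chrom_lengths = {c.id: len(c.seq) for c in genome_records}

    if config.genome_hits is not None:
        all_hits = read_tabular_hits(config.genome_hits, config.genome_hits_dialect)
    elif config.te_sam_r1 is not None and config.te_sam_r2 is not None:
        all_hits = _hits_from_imported_sam(pairs, config, genome_records, stats)
    else:
        if te_index is None:
            te_index = build_index(te_records, config.te_k)
        if genome_index is None:
            genome_index = build_index(genome_records, config.genome_k)
        blocks = partition_pairs(pairs, config.n_parts)
        part_hits = [
            _map_part_to_genome_hits(block, te_index, genome_index, config, stats)
            for block in blocks
        ]
        all_hits = merge_partials(part_hits)
    stats.n_genome_hits = len(all_hits)

    unique = unique_hit_filter(all_hits)
    stats.n_unique = len(unique)
    counts = tip_call.count_in_windows(
        unique, chrom_lengths, config.window_size, mode=config.count_mode
    )
    stats.n_window_reads = sum(wc.count for wc in counts)
    if config.count_mode == "start" and stats.n_window_reads != stats.n_unique:
        raise ValidationError(
            f"{config.sample_id}: window counts ({stats.n_window_reads}) do not "
            f"conserve unique hits ({stats.n_unique})"
        )
    calls = tip_call.call_tips(counts, te_family, config.min_support)
    stats.n_calls = len(calls)
    logger.info(
        "%s: pairs=%d anchored=%d genome_hits=%d unique=%d window_reads=%d calls=%d",
        stats.sample_id,
        stats.n_pairs,
        stats.n_anchored,
        stats.n_genome_hits,
        stats.n_unique,
        stats.n_window_reads,
        stats.n_calls,
    )
    return calls, stats


def _hits_from_imported_sam(
    pairs: Sequence[tuple[SeqRecord, SeqRecord]],
    config: RunConfig,
    genome_records: Sequence[SeqRecord],
    stats: RunStats,
) -> list[AlignmentHit]:
    """Import mode: TE verdicts from SAM, genome alignment via builtin mapper."""
    sam1 = results_from_hits(read_sam(config.te_sam_r1))
    sam2 = results_from_hits(read_sam(config.te_sam_r2))
    pair_results = []
    for read1, read2 in pairs:
        res1 = sam1.get(read1.id, MapResult(query_id=read1.id))
        res2 = sam2.get(read2.id, MapResult(query_id=read2.id))
        pair_results.append(((read1, res1), (read2, res2)))
    anchored = extract_anchored(pair_results)
    stats.n_anchored += len(anchored)
    genome_index = build_index(genome_records, config.genome_k)
    hits: list[AlignmentHit] = []
    for status in anchored:
        anchor = status.unmapped_mate_seq
        assert anchor is not None
        result = map_read(
            anchor, genome_index, config.genome_min_identity, config.genome_min_cov
        )
        hits.extend(result.hits)
    return hits


def run_cohort(
    calls_by_sample: Mapping[str, Sequence[BedRecord]],
    labels: Mapping[str, int],
    alpha: float = 0.05,
    yates_mode: assoc.YatesMode = "floored",
    c_mode: assoc.CMode = "sqrt",
    correction: assoc.Correction = "none",
) -> tuple[cohort.TipMatrix, list[assoc.AssociationResult], dict[str, int]]:
    """Aggregate per-sample calls and run the association scan."""
    matrix = cohort.build_matrix(calls_by_sample, labels)
    results = assoc.associate_all(
        matrix, alpha=alpha, yates_mode=yates_mode, c_mode=c_mode, correction=correction
    )
    counts = assoc.per_chromosome_counts(results)
    return matrix, results, counts
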