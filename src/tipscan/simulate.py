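"""Synthetic cohort generator: the pipeline's entire test bed.

Emulates a two-group resequencing cohort in which case genomes carry novel
full-length TE insertions at elevated per-site frequency:

* a uniform-random reference genome and a TE consensus that shares no exact
  21-mer with it (so TE-derived reads can never map to the reference);
* a shared pool of candidate insertion sites; each case carries each site
  with probability ``case_site_freq`` and each control with
  ``control_site_freq``, and carrying splices the full TE sequence into
  that sample's genome;
* paired-end substitution-error reads drawn from each (modified) sample
  genome, so discordant anchored pairs arise from the insertion junctions
  themselves rather than being injected;
* machine-readable ground truth (every placement, plus per-window carrier
  counts on the reference window grid).

All randomness flows from one seed through named spawned streams
(reference, planting, then one stream per sample's reads), so every
artifact is reproducible and per-sample reads do not depend on how many
other samples were generated first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cohort import TipMatrix, Window
from .errors import GenerationError, ValidationError
from .io_formats import (
    SeqRecord,
    write_fasta,
    write_fastq,
    write_labels,
)
from .kmer_align import reverse_complement
from .tip_call import WINDOW_SIZE

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(slots=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``n_sites`` candidate insertion sites are shared across the cohort;
    group carrier frequencies make them polymorphic and differential.
    Defaults model a small two-group cohort with strongly case-enriched
    insertions, error-free reads, and a 10-kb reporting grid.
    """

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    te_length: int = 5_000
    n_cases: int = 15
    n_controls: int = 15
    n_sites: int = 10
    case_site_freq: float = 0.8
    control_site_freq: float = 0.1
    read_length: int = 100
    insert_size_mean: int = 350
    insert_size_sd: float = 35.0
    coverage: float = 10.0
    error_rate: float = 0.0
    window_size: int = WINDOW_SIZE

    def __post_init__(self) -> None:
        if self.read_length >= self.insert_size_mean:
            raise ValidationError("read_length must be < insert_size_mean")
        for name in ("n_chroms", "chrom_length", "te_length", "n_cases",
                     "n_controls", "n_sites", "read_length", "window_size"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("case_site_freq", "control_site_freq", "error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"case{i + 1:02d}" for i in range(self.n_cases)] + [
            f"control{i + 1:02d}" for i in range(self.n_controls)
        ]

    @property
    def labels(self) -> dict[str, int]:
        return {
            s: 1 if s.startswith("case") else 0 for s in self.sample_ids
        }


@dataclass(slots=True)
class SimTruth:
    """Ground truth of the planted insertions.

    ``sites`` is the shared candidate pool; ``placements`` maps each sample
    to its carried (chrom, position, window) triples; carrier counts are
    per reference-grid window.
    """

    sites: list[tuple[str, int]]
    placements: dict[str, list[tuple[str, int, Window]]]
    case_carriers: dict[Window, int]
    control_carriers: dict[Window, int]

    def windows_for(self, sample_id: str) -> set[Window]:
        return {w for _, _, w in self.placements.get(sample_id, [])}

    @property
    def all_windows(self) -> set[Window]:
        return {w for p in self.placements.values() for _, _, w in p}


def _rng_streams(config: SimConfig) -> dict[str, np.random.SeedSequence]:
    """Named child seed sequences: draw order is fixed and documented here.

    Kept as seeds (not generators) so a stream can be re-instantiated for
    repeatable per-sample read generation.
    """
    children = np.random.SeedSequence(config.seed).spawn(2 + len(config.sample_ids))
    streams = {"reference": children[0], "planting": children[1]}
    for i, sample in enumerate(config.sample_ids):
        streams[f"reads:{sample}"] = children[2 + i]
    return streams


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def make_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[SeqRecord], SeqRecord]:
    """Uniform-random chromosomes plus a TE consensus disjoint at k=21.

    The TE is resampled (bounded retries) until it shares no exact 21-mer
    with the genome, so TE-derived read content can never align to the
    reference and every genomic hit of an anchored mate is genuine flank.
    """
    if config.chrom_length < 10 * config.window_size:
        raise ValidationError("chrom_length must be >= 10 windows")
    if config.te_length < 2 * config.read_length:
        raise ValidationError("te_length must be >= 2 * read_length")
    rng = rng if rng is not None else np.random.default_rng(_rng_streams(config)["reference"])
    genome = [
        SeqRecord(id=f"chr{i + 1}", seq=_random_seq(rng, config.chrom_length))
        for i in range(config.n_chroms)
    ]
    k = 21
    for _ in range(20):
        te_seq = _random_seq(rng, config.te_length)
        te_kmers = {te_seq[i : i + k] for i in range(len(te_seq) - k + 1)}
        te_kmers |= {reverse_complement(m) for m in set(te_kmers)}
        collision = any(
            chrom.seq[i : i + k] in te_kmers
            for chrom in genome
            for i in range(len(chrom.seq) - k + 1)
        )
        if not collision:
            return genome, SeqRecord(id="TE1", seq=te_seq)
    raise GenerationError("could not sample a TE sharing no 21-mer with the genome")


def _draw_sites(
    config: SimConfig, genome: Sequence[SeqRecord], rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Shared candidate sites, spaced and kept clear of window boundaries.

    Sites sit >= insert_size_mean from chromosome ends and from each other,
    and >= insert_size_mean + 4 sd from any window-grid boundary so one
    insertion's anchored-mate footprint stays inside one window.
    """
    wsize = config.window_size
    end_margin = config.insert_size_mean
    boundary_margin = int(config.insert_size_mean + 4 * config.insert_size_sd)
    if 2 * boundary_margin >= wsize:
        raise GenerationError("window too small for the boundary margin")
    sites: list[tuple[str, int]] = []
    attempts = 0
    max_attempts = 1000 * max(config.n_sites, 1)
    while len(sites) < config.n_sites:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"placed only {len(sites)}/{config.n_sites} sites under the "
                f"spacing constraints"
            )
        chrom = genome[int(rng.integers(0, len(genome)))]
        n_windows = len(chrom.seq) // wsize
        w = int(rng.integers(0, n_windows))
        offset = int(rng.integers(boundary_margin, wsize - boundary_margin))
        pos = w * wsize + offset
        if pos < end_margin or pos > len(chrom.seq) - end_margin:
            continue
        if any(
            c == chrom.id and abs(p - pos) < config.insert_size_mean
            for c, p in sites
        ):
            continue
        sites.append((chrom.id, pos))
    sites.sort()
    return sites


def plant_insertions(
    genome: Sequence[SeqRecord],
    te: SeqRecord,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[SeqRecord]], SimTruth]:
    """Draw the shared site pool once, then per-sample carrier indicators.

    Carrying a site splices the full TE sequence into that sample's genome
    at the site position (reference coordinates; later sites shift by the
    TE lengths inserted before them within the sample's own copy).
    """
    rng = rng if rng is not None else np.random.default_rng(_rng_streams(config)["planting"])
    sites = _draw_sites(config, genome, rng)
    wsize = config.window_size
    chrom_len = {c.id: len(c.seq) for c in genome}

    def window_of(chrom: str, pos: int) -> Window:
        start = (pos // wsize) * wsize
        return (chrom, start, min(start + wsize, chrom_len[chrom]))

    placements: dict[str, list[tuple[str, int, Window]]] = {}
    case_carriers: dict[Window, int] = {}
    control_carriers: dict[Window, int] = {}
    sample_genomes: dict[str, list[SeqRecord]] = {}
    labels = config.labels
    for sample in config.sample_ids:
        freq = config.case_site_freq if labels[sample] else config.control_site_freq
        carried = [site for site in sites if rng.random() < freq]
        placements[sample] = [(c, p, window_of(c, p)) for c, p in carried]
        for _, _, w in placements[sample]:
            bucket = case_carriers if labels[sample] else control_carriers
            bucket[w] = bucket.get(w, 0) + 1
        per_chrom: dict[str, list[int]] = {}
        for c, p in carried:
            per_chrom.setdefault(c, []).append(p)
        modified: list[SeqRecord] = []
        for chrom in genome:
            positions = sorted(per_chrom.get(chrom.id, []))
            if not positions:
                modified.append(chrom)
                continue
            pieces: list[str] = []
            prev = 0
            for pos in positions:
                pieces.append(chrom.seq[prev:pos])
                pieces.append(te.seq)
                prev = pos
            pieces.append(chrom.seq[prev:])
            modified.append(SeqRecord(id=chrom.id, seq="".join(pieces)))
        sample_genomes[sample] = modified
    truth = SimTruth(
        sites=sites,
        placements=placements,
        case_carriers=case_carriers,
        control_carriers=control_carriers,
    )
    return sample_genomes, truth


def simulate_pairs(
    sample_genome: Sequence[SeqRecord],
    config: SimConfig,
    rng: np.random.Generator,
    id_prefix: str = "p",
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Paired substitution-error reads from one sample genome.

    Fragment count = coverage * genome_length / (2 * read_length), starts
    uniform, lengths normal(mean, sd) clipped to >= read_length + 1. R1 is
    the fragment's first ``read_length`` bases; R2 the reverse complement
    of its last ``read_length`` bases. Pair ids share one core serial, so
    both mates of pair i are ``{id_prefix}_{i}``.
    """
    if config.coverage <= 0:
        raise ValidationError("coverage must be > 0")
    rl = config.read_length
    lengths = np.array([len(c.seq) for c in sample_genome], dtype=np.int64)
    total = int(lengths.sum())
    n_frag = int(round(config.coverage * total / (2 * rl)))
    chrom_idx = rng.choice(len(sample_genome), size=n_frag, p=lengths / total)
    frag_len = np.rint(
        rng.normal(config.insert_size_mean, config.insert_size_sd, size=n_frag)
    ).astype(np.int64)
    frag_len = np.clip(frag_len, rl + 1, lengths[chrom_idx])
    starts = np.floor(rng.random(n_frag) * (lengths[chrom_idx] - frag_len + 1)).astype(
        np.int64
    )
    seqs = [c.seq for c in sample_genome]
    r1: list[SeqRecord] = []
    r2: list[SeqRecord] = []
    for i in range(n_frag):
        seq = seqs[chrom_idx[i]]
        a = int(starts[i])
        b = a + int(frag_len[i])
        fwd = seq[a : a + rl]
        rev = reverse_complement(seq[b - rl : b])
        if config.error_rate > 0:
            fwd = _mutate(fwd, config.error_rate, rng)
            rev = _mutate(rev, config.error_rate, rng)
        pair_id = f"{id_prefix}_{i}"
        r1.append(SeqRecord(id=pair_id, seq=fwd))
        r2.append(SeqRecord(id=pair_id, seq=rev))
    return r1, r2


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


@dataclass
class SimCohort:
    """A fully simulated cohort with lazy per-sample read generation."""

    config: SimConfig
    reference: list[SeqRecord]
    te: SeqRecord
    sample_genomes: dict[str, list[SeqRecord]]
    truth: SimTruth
    _read_streams: dict[str, np.random.SeedSequence] = field(repr=False, default_factory=dict)

    @property
    def labels(self) -> dict[str, int]:
        return self.config.labels

    def reads(self, sample_id: str) -> tuple[list[SeqRecord], list[SeqRecord]]:
        """R1/R2 for one sample; deterministic per (seed, sample) and per call."""
        rng = np.random.default_rng(self._read_streams[f"reads:{sample_id}"])
        return simulate_pairs(
            self.sample_genomes[sample_id], self.config, rng, id_prefix=sample_id
        )


def simulate_cohort(config: SimConfig) -> SimCohort:
    streams = _rng_streams(config)
    reference, te = make_reference(config, np.random.default_rng(streams["reference"]))
    sample_genomes, truth = plant_insertions(
        reference, te, config, np.random.default_rng(streams["planting"])
    )
    return SimCohort(
        config=config,
        reference=reference,
        te=te,
        sample_genomes=sample_genomes,
        truth=truth,
        _read_streams=streams,
    )


def simulate_presence_matrix(
    n_cases: int,
    n_controls: int,
    case_probs: Sequence[float],
    control_probs: Sequence[float],
    seed: int,
    chrom: str = "chr1",
    window_size: int = WINDOW_SIZE,
) -> TipMatrix:
    """Matrix-level cohort: draw presence indicators directly per window.

    Window j is present in a case with probability ``case_probs[j]`` and in
    a control with ``control_probs[j]``. Used for association calibration
    (type-I error and power) where read-level simulation adds nothing.
    """
    if len(case_probs) != len(control_probs):
        raise ValidationError("case_probs and control_probs must have equal length")
    m = len(case_probs)
    rng = np.random.default_rng(seed)
    samples = [f"case{i + 1:03d}" for i in range(n_cases)] + [
        f"control{i + 1:03d}" for i in range(n_controls)
    ]
    labels = {s: 1 if s.startswith("case") else 0 for s in samples}
    data = np.zeros((len(samples), m), dtype=np.int8)
    case_p = np.asarray(case_probs, dtype=float)
    ctrl_p = np.asarray(control_probs, dtype=float)
    for i, s in enumerate(samples):
        p = case_p if labels[s] else ctrl_p
        data[i] = rng.random(m) < p
    windows: list[Window] = [
        (chrom, j * window_size, (j + 1) * window_size) for j in range(m)
    ]
    return TipMatrix(samples=samples, windows=windows, data=data, labels=labels)


def write_cohort(cohort: SimCohort, outdir: str | Path) -> None:
    """Write genome/TE FASTA, per-sample FASTQ pairs, labels and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.reference, outdir / "genome.fasta")
    write_fasta([cohort.te], outdir / "te.fasta")
    write_labels(cohort.labels, outdir / "labels.tsv")
    with open(outdir / "truth.tsv", "wt", encoding="utf-8") as handle:
        handle.write("sample_id\tchrom\tposition\twindow_start\twindow_end\n")
        for sample in cohort.config.sample_ids:
            for chrom, pos, (wc, ws, we) in cohort.truth.placements[sample]:
                handle.write(f"{sample}\t{chrom}\t{pos}\t{ws}\t{we}\n")
    for sample in cohort.config.sample_ids:
        r1, r2 = cohort.reads(sample)
        write_fastq(
            [SeqRecord(id=f"{r.id}/1", seq=r.seq) for r in r1],
            outdir / f"{sample}_R1.fastq",
        )
        write_fastq(
            [SeqRecord(id=f"{r.id}/2", seq=r.seq) for r in r2],
            outdir / f"{sample}_R2.fastq",
        )
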