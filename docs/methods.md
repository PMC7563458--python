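# Methods

## Detection model

tipscan detects non-reference TE insertions from the discordant geometry of
paired-end reads. If a sample carries a TE insertion absent from the
reference, fragments spanning an insertion junction produce pairs in which
one mate lies inside the TE sequence (and therefore maps to the family
consensus but nowhere in the reference) while the other mate lies in
flanking genomic sequence. The TE-mapped mate identifies the family; the
flank mate ("anchor"), aligned to the reference, localizes the insertion.

Reads are reported on a fixed window grid rather than at base-pair
breakpoints: each uniquely-aligned anchor is counted in the 10-kb window
(configurable `window_size`) containing its 0-based alignment start, and a
window with at least `min_support` anchors becomes a TIP call whose BED
score is the anchor count. Window-level reporting trades breakpoint
precision for robustness and for exact comparability across samples — all
samples share one grid, so the cohort matrix needs no interval merging.

Two counting semantics are provided. The default, start-based counting,
assigns each read to exactly one window, which makes the conservation
identity `sum(window counts) == number of unique-hit reads` exact; this
identity is asserted on every pipeline run. An overlap mode (one count per
intersected window) is available for parity with coverage-style counting,
at the cost of that identity.

### Unique-hit filtering

A read with more than one reference alignment cannot place an insertion
unambiguously. The filter drops *all* alignments of any query appearing
more than once, rather than picking a best hit: repetitive-region anchors
carry no reliable positional information, and keeping a best-scoring
ambiguous hit would inflate support in repeat-dense windows.

## Built-in mapper

A minimal k-mer seed-and-extend mapper makes the pipeline self-contained.
Candidate loci come from exact seed matches (seeds sampled every k/2
positions plus the final offset, both orientations); each candidate is
scored by ungapped full-read extension clipped at subject ends, and
retained when identity ≥ `min_identity` over a span covering ≥ `min_cov` of
the read. Overlapping hits on one subject collapse to the best-scoring one.

Two regimes are used, reflecting the two alignment roles:

| stage | k | min_identity | min_cov | rationale |
|---|---|---|---|---|
| TE-library mapping | 15 | 0.90 | 0.50 | genomic TE copies diverge from the consensus; edge reads cover the element partially |
| genome alignment | 21 | 0.95 | 0.90 | anchors must place near-exactly to support a window |

The mapper is ungapped by design: it targets substitution-level divergence,
and alignment around indels is the province of full aligners, whose SAM or
BLAST tabular output can be imported stage-for-stage (`RunConfig.te_sam_*`,
`RunConfig.genome_hits`). On error-free reads its mapped/unmapped verdict
is provably identical to an exhaustive all-offsets scan (any sampled seed
of an exact placement matches exactly); this equivalence is tested against
an independent brute-force oracle on random genomes.

## Association procedure

For window *j*, the 2×2 table crosses presence Y ∈ {0,1} (rows) with the
condition X ∈ {0,1} (columns) over the n samples. Expected frequencies are
e_ij = n_i·n_·j/n; the statistic is χ² = Σ(O−e)²/e with one degree of
freedom, and the window is declared associated when χ² ≥ χ²_{α,1}
(default α = 0.05, critical value 3.841). The p-value (upper tail of χ²₁)
is reported alongside and is equivalent to the quantile criterion.

Yates' continuity correction is applied exactly when the smallest expected
frequency is below 5. The textbook corrected statistic Σ(|O−e|−0.5)²/e is
positive even when O = e, which contradicts the statistic's purpose, so the
default `floored` mode clips |O−e|−0.5 at zero (a standard safeguard);
`literal` mode evaluates the uncorrected formula as written for users who
need to reproduce that behavior.

Association strength is Pearson's contingency coefficient
C = √(χ²/(n+χ²)) (`sqrt` mode, default). The unrooted ratio χ²/(n+χ²) is
retained as `literal` mode. Both lie in [0, 1) and are 0 iff χ² = 0.

Degenerate tables — a window present in every sample or none, which makes
a margin zero and e_ij undefined — are reported with χ² = 0,
`significant = False` and a `degenerate` flag rather than being dropped,
so the number of tested windows m is never silently reduced.

Multiple testing: the default is the per-test 5% criterion, matching the
classical single-window decision rule; Bonferroni and Benjamini–Hochberg
adjusted-p criteria are available as options. Both corrected criteria are
monotone in the unadjusted p, so their significant sets are subsets of the
uncorrected one.

## Synthetic cohort generator

The generator emulates the signal the detector exploits, at desk scale:

* **Reference and TE**: uniform-random ACGT chromosomes and a TE consensus
  resampled until it shares no exact 21-mer (either strand) with the
  genome. This guarantees TE-derived read content cannot align to the
  reference, isolating the anchored-pair mechanism.
* **Insertions**: a shared pool of `n_sites` candidate sites is drawn once;
  each case sample carries each site with probability `case_site_freq`
  (default 0.8) and each control with `control_site_freq` (default 0.1).
  Carrying splices the full TE sequence into the sample's genome, and reads
  are then drawn from the modified genome — anchored pairs arise from the
  junctions themselves, not by injection.
* **Site placement**: sites sit at least `insert_size_mean` from chromosome
  ends and from each other, and at least `insert_size_mean + 4·insert_size_sd`
  (≈ 490 bp at the defaults) from any window-grid boundary. Anchors fall
  within roughly one insert length of the junction, so this margin keeps
  one insertion's support footprint inside a single window and makes truth
  windows well-defined at window resolution. Insertions landing near a
  window boundary in real data would split support across two adjacent
  windows — a resolution limit of any windowed method, not modeled here.
* **Reads**: fragment count = coverage × genome_length/(2 × read_length)
  (mean depth equals the nominal coverage exactly); starts uniform; lengths
  normal(350, 35) clipped to > read_length; R1 = first 100 bp of the
  fragment, R2 = reverse complement of the last 100 bp; independent
  per-base substitutions at `error_rate` (default 0 — the defaults model
  the clean-signal regime; quality-profile and indel error models are out
  of scope).
* **Determinism**: all draws flow from one seed through named spawned
  streams (reference, planting, one per sample's reads), so any artifact is
  reproducible in isolation and repeated read generation for one sample is
  idempotent.

What the simulator deliberately omits — truncated or internally diverged TE
copies, target-site duplications, reference-carried ancestral insertions,
GC bias, PCR duplicates, indel errors — means passing tests demonstrate the
pipeline mechanics (anchoring, filtering, counting, association) rather
than robustness to real-library artifacts. Validation on real data still
requires an external aligner via the import path.

Matrix-level simulation (`simulate_presence_matrix`) draws presence
indicators directly per window and is used where read-level simulation adds
nothing: type-I error calibration (both groups at presence probability 0.3,
n = 30+30, m = 2000 windows; the observed rejection fraction at α = 0.05
falls in [0.03, 0.07]) and power (20 windows at 0.8 vs 0.1, n = 15+15;
≥ 80% flagged, in practice ≈ 100%).

## Scatter/gather contract

The per-sample workload is data-parallel over read pairs. Parallelism is
specified as a contract, not a runtime: inputs split into contiguous
balanced blocks (sizes differing by ≤ 1), each block processed
identically, results merged, canonically sorted and deduplicated — and the
merged output must be byte-identical to the single-block run for every
block count. Hit-file line partitioning additionally extends block
boundaries to query-id changes, so no read's alignments straddle two
blocks and the unique-hit filter is computable without a global
reconciliation step. The serial driver here satisfies the contract by
construction; any process-pool or message-passing backend that honors it
would produce identical output.

## Problem sizes and numerical choices

Integration and validation runs use 1–2 chromosomes of 0.3–1 Mb, a 5-kb TE
family, 10× coverage, and cohorts of 4–6 samples at the read level (the
association calibrations use their stated 30–60-sample cohorts at matrix
level, where sample count is free). At these sizes the end-to-end
recall and precision of planted-window recovery are 1.0 with
`min_support = 2`. The read-level cohort sizes are far below what the
association stage needs for power — with 3 cases vs 3 controls the
Yates-corrected statistic cannot exceed the 5% critical value even under
perfect separation — which is why detection and association are validated
at their own natural scales.

Other fixed choices: chromosome names sort naturally (numeric components
numerically, so chr2 < chr10 < chrX); tabular hit coordinates are 1-based
inclusive with minus-strand rows normalized to start ≤ end at parse time;
the single 1-based→0-based conversion happens at window assignment; ties
among equal-scoring candidate loci are all kept (the unique-hit filter is
the arbiter of multiplicity); FASTQ qualities are read and ignored (the
method never uses them).

## Known limitations

* No split-read breakpoint refinement, absence (reference-TE deletion)
  calling, genotyping, or target-site-duplication detection — calls are
  window-resolution presence/absence only.
* The built-in mapper is ungapped and unsuitable for indel-rich or
  spliced alignment; use imported aligner output there.
* One TE family per detection run; multi-family analyses loop at the
  orchestration level.
* The association test treats windows independently; linkage between
  nearby windows is not modeled.
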