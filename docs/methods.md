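# Methods

## The damage-profiling model

Anti-oxoG ChIP-seq read density is treated as a proxy for 8-oxoguanine
lesion density.  The pipeline makes no positional model of damage within a
bin: a sample is reduced to per-(chromosome, 10-kb bin) read counts keyed by
each read's leftmost aligned base, and all downstream inference operates on
those counts.  The assumptions this encodes:

- **Reads are exchangeable evidence.**  Both mates of a pair count as
  independent reads; no fragment-level deduplication beyond the aligner's
  duplicate flag is attempted.
- **Library size is the only depth covariate.**  Counts are scaled by
  10⁶ / N, with N the number of reads surviving all filters (MAPQ ≥ 20,
  mitochondrial discard, and by default unmapped/secondary/supplementary/
  duplicate removal — each an overridable policy flag, so the minimal
  MAPQ-only filter is also expressible).  The paired test is invariant to
  the scale factor; 10⁶ affects reporting only.
- **Sparse bins are noise.**  Bins with fewer than 10 raw hits are dropped
  per sample.  The cutoff applies to raw counts by default because "hits"
  are counted reads and a threshold on normalized values would depend on the
  arbitrary scale; a `threshold_on="normalized"` variant exists because the
  original ordering of the two steps is ambiguous.  The discard is
  per-sample (no cross-sample bin mask): the procedure is a per-file
  pipeline, and a shared-mask variant would change the statistic.
- **Chromosomes are the replication unit.**  Retained normalized values are
  summed per chromosome, averaged across a condition's replicates, and the
  two conditions' per-chromosome means are compared pairwise.

Coordinates are 0-based half-open internally and in bedGraph output; SAM POS
is converted on read.  "First-base position" means the leftmost aligned
reference coordinate regardless of strand — for sorted alignments that is
the plainest reading, and at 10-kb resolution the ≤ read-length difference
between leftmost base and biological 5′ end is immaterial.

## The paired signed-rank test

Differences dᵢ = meanB(chrᵢ) − meanA(chrᵢ); zeros removed (n pairs remain);
|dᵢ| ranked with midranks for ties.  W⁺ is the rank sum over positive
differences.  The exact p-value uses the permutation distribution of W⁺ over
all 2ⁿ equiprobable sign assignments, computed by subset-sum dynamic
programming on doubled ranks (midranks × 2 are integers, so ties need no
special path; counts are exact in float64 for n ≤ 53).  The two-sided p is
2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)) capped at 1 — the convention matching common
implementations.  Two-sided is the default sidedness (the conservative
choice when no direction is pre-registered); `greater`/`less` are available.
Beyond n = 25 nonzero pairs, `compare_conditions(method="auto")` switches to
the normal approximation with mean n(n+1)/4, variance n(n+1)(2n+1)/24 minus
the tie correction Σ(t³−t)/48, and a continuity correction.  The
approximation's relative error against the exact distribution is a few
percent in the body but grows in the far discrete tail (measured up to ~25%
relative at exact p ≈ 0.01 for n = 15), which is why the exact route covers
every n the chromosome count can produce.

Significance is p < α with α = 0.05 by default.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes, not
sequence content (no bases, qualities, error models, or paired-end mates —
single-end placement suffices because only the first-base bin assignment is
consumed).

An **intensity map** assigns each analyzable bin an expected read weight:
a seed-chosen hotspot set (fraction 0.05 of bins by default) shared between
conditions carries a condition-specific mass (`hotspot_mass`: 0.1 for "wt",
0.5 for "mut" by default), and the remainder spreads over background bins
either uniformly (`diffuse`) or over a seeded 10% subset (`concentrated`).
With hotspot mass 0 the map degenerates to uniform over all bins.  Because
library normalization cancels any global scaling, a detectable
between-condition difference must come from signal *concentration* — in the
default scenario the diffuse WT background sits below the 10-hit cutoff and
is discarded while the concentrated mutant signal survives, raising every
mutant chromosome total.

Sampling is a single multinomial draw of `n_reads_per_sample` (default
2×10⁵) over bins.  The **count level** stops there; the **read level**
expands the same draw (same seed, same first rng use, so the two layers
agree exactly when noise fractions are zero) into reads placed uniformly
within their bin and clipped to fit the chromosome, with a two-point MAPQ
mixture (0 vs 60 — only the ≥ 20 threshold matters downstream; 5% low by
default), mitochondrial reassignment (1%), duplicate flags (2%) and
fair-coin strand.  Every generator is a pure function of (inputs, seed).

What the generator does **not** emulate: mappability and GC structure,
copy-number variation, chromosome-length heterogeneity, fragment-length
effects, antibody efficiency differences, or any true spatial model of
oxidative damage (none is established; the hotspot/diffuseness model is an
assumption).  Passing tests therefore show the pipeline's arithmetic,
invariances and error control under its own model — not that real oxoG
enrichment follows this spatial structure.

## Monte-Carlo calibration and problem sizes

- **Null calibration**: 23 chromosomes × 50 bins (500-kb toy chromosomes),
  both conditions drawn from one uniform intensity map, 5,000 reads/sample,
  2 replicates/condition, 1000 runs.  The depth puts ≈ 4.3 expected reads in
  each bin, so the sparse-bin cutoff is active and per-chromosome totals are
  dominated by chromosome-local retention noise; the empirical rejection
  fraction at α = 0.05 then tracks the exact test's achievable size
  (≈ 0.0475 at n = 23; the test is slightly conservative, measured ≈ 0.04).
- **A structural caveat, deliberately surfaced**: at saturating depth, where
  every bin clears the cutoff, each sample's chromosome totals sum exactly
  to the scale factor, so paired differences are compositional — they sum to
  zero and are negatively correlated — and the signed-rank test becomes
  extremely conservative (empirical size near 0, W⁺ variance far below its
  nominal value).  A genome-wide *uniform* damage increase is invisible to
  this statistic by construction; what it detects is redistribution of
  signal mass across the retention threshold.  Users comparing deeply
  sequenced libraries should read a non-significant result accordingly.
- **Power scenario**: 23 × 12-Mb chromosomes (27,600 bins), default config,
  100 runs.  The diffuse WT background (≈ 6.9 reads/bin) is mostly
  discarded; WT hotspots (≈ 14.5 reads/bin) and all mutant signal survive,
  so the mutant minus WT difference is positive on every chromosome with
  overwhelming probability (measured: 100/100 runs significant with positive
  median difference).  Sizes were chosen so the whole calibration suite runs
  in seconds on one core while per-bin expectations sit in the regimes of
  interest.

## Numerical and format choices

- bedGraph and TSV floats are written with shortest round-trip (`repr`)
  formatting, making write → parse → write byte-stable.
- Bin ends in bedGraph are clipped to the chromosome length; the last bin
  may be short.
- Multinomial draws, hotspot layout and all replicate seeds derive from
  numpy `SeedSequence` spawning, so every experiment is reproducible from
  one integer and independent across replicates.
- Degenerate inputs fail loudly: an empty filtered stream (normalization
  undefined), all-zero difference vectors (statistic undefined), zero
  control colonies (plating efficiency undefined), mismatched chromosome
  sets between replicates or conditions.
- BED records without a score column are treated as passing the MAPQ filter
  (deposited interval files often carry no qualities); a warning is logged.

## Known limitations

- The exact test conditions on the observed |difference| ranks; with heavy
  ties among midranks its discreteness makes it conservative.
- The compositional effect above means power comes from concentration
  differences, not uniform fold increases, at matched library sizes.
- BAM input is not read directly; convert with `samtools view -h` (the SAM
  reader is pysam-backed, so the text path is equivalent).
- The mutant-frequency metric is a frequency, not a Luria–Delbrück mutation
  rate; no fluctuation analysis is attempted.
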