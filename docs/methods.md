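# Methods

## Duplicate definition and filtering

A read's duplicate key is its strand-aware 5' mapping coordinate with
soft/hard clips restored (the *unclipped* position), so identical fragments
that were clipped differently still collide.  For reverse-strand reads the
5' coordinate is the rightmost aligned base.  Read pairs use both ends,
ordered canonically, so two pairs sharing one end but differing in fragment
size are *not* duplicates.  Reads at the same position on opposite strands
occupy distinct keys.

Reads enter any counting only after the uniqueness filters: mapping quality
>= 20 (default, configurable) and no substitution mismatch among the first
five *sequenced* bases.  "Sequenced" is read-orientation: for a
reverse-strand record the check applies to the tail of the stored SEQ.
Mismatch evidence comes from the MD tag; when it is absent, strict mode
raises and non-strict mode falls back to requiring edit distance zero.
Insertions and soft-clipped bases are not counted as mismatches (only
substitutions are); secondary and supplementary alignments are always
dropped.  Filtered-out reads contribute to no denominator.

Per key holding `n` reads, `n − 1` are duplicates.  The representative
(nonredundant) read is the first in `(coordinate, read id)` order — a
deterministic choice; base-quality-based selection (as in Picard) would
only permute which read represents a key, never any count.

## Region accounting

Coordinates are 0-based half-open internally; SAM positions convert at the
I/O boundary.  Peaks overlapping the blacklist by >= 1 bp are removed.
Non-peak regions are the complement of peaks padded by a 100 bp buffer.
Flanking regions are peak-sized windows 300 bp up/downstream, truncated
(not dropped) at chromosome edges unless fully out of bounds.  Replicate
peak lists merge by single-linkage at >= 1 bp overlap.

Reads are assigned to regions by the *point* position of their duplicate
key (smaller end for pairs), not by any-overlap.  Point assignment makes
the peak / buffer / non-peak / blacklist-peak partition exact: the four
duplicate counts always sum to the library total, which the tests assert
on every fixture.  Peak coverage is expressed over the mappable genome,
taken as 0.75 × total chromosome length (configurable).

Library QC definitions: duplicate rate = duplicates / uniquely mapped
reads; NRF = distinct keys / uniquely mapped reads; FRiP = nonredundant
reads in peaks / total nonredundant reads; RPK10M = count / (kb of region)
/ (library reads / 10^7).  Replicate correlation uses per-merged-peak
duplicate RPK10M, log2(x + 1) (the offset retains zero-duplicate peaks),
Pearson r with a Fisher-z 95% CI.  Confidence groups sort peaks by
p-value ascending (stable, coordinate tie-break) into k groups; when
n mod k != 0 the earliest (most confident) groups take the extra peaks.
Feature correlations are Spearman rho of in-peak duplicate level (per kb,
*not* library-size normalised) against enrichment level, the two matched
input levels, GC fraction (G/C over all bases including N), and the
fractions of the peak covered by segmental-duplication and low-complexity
annotations.

## The signal/noise partition

Within blacklist-filtered peaks, duplicates are first capped at five per
(position, strand) key; towers beyond the cap are overwhelmingly
amplification artifacts.  The capped duplicate level (per kb) is regressed
on the enrichment level (nonredundant reads per kb) with lowess — tricube
neighbourhood weights, span 2/3, three robustifying passes with bisquare
weights on six times the median absolute residual, interpolation delta of
0.01 × range(x) — the defaults of the classical implementation, via
statsmodels.  Fitted values are clipped at zero, and peaks with zero
nonredundant reads get a predicted level of zero.  Each peak's natural
level is min(observed capped level, predicted level); S = that level times
peak kb, rounded half-to-even and clamped into [0, capped count];
N = capped − S.  The library signal fraction is the duplicate-weighted
ΣS / Σcapped (the per-peak distribution and the top-confidence-decile
fraction are also reported).  The fit is per library; with fewer than ten
peaks the model refuses and advises pooling replicates.

The min rule makes the estimate conservative: peaks sitting above the
collision trend surrender their excess as noise, while peaks below it keep
everything they have.  The procedure is identifiable precisely when PCR
amplification is heterogeneous across loci — the robust fit then tracks
the collision-driven bulk and amplified peaks show up as positive
outliers.  If amplification were perfectly uniform across peaks, the PCR
component would itself be a smooth function of enrichment and no
regression on enrichment could separate the two; the estimate would then
approach the capped total.

## Rewrite

The output alignment file keeps every nonredundant read, plus, per peak, a
kept set of signal duplicates obtained by removing a uniform random sample
(numpy PCG64, seeded; ids sorted before sampling so the draw is
input-order independent) of N read ids from the capped duplicate pool.
Over-cap duplicates are removed outright before sampling.  Non-peak
duplicates are all removed.  In paired mode both ends of a pair share its
fate.  Duplicate flags are cleared on retained reads, and a program-group
header line records cap, span and seed.  Conservation (records out =
nonredundant + ΣS) is exact, and re-marking the output yields S duplicates
per peak and none elsewhere.

## The synthetic-data generator

The generator is the test substrate: it emulates exactly the two
mechanisms the method distinguishes and labels every read.

* Genome: one 1 Mb chromosome (configurable).  Fifty non-overlapping 2 kb
  peaks are placed uniformly with spacing margins (ordered-uniform
  construction).  Per-peak expected template counts are lognormal
  (sdlog 0.5) scaled so peaks hold 85% of ~50,000 templates; the rest is
  uniform background.  These sizes keep a full pipeline run around a
  second while leaving thousands of in-peak duplicates to partition.
* Template 5' keys: truncated normal around the peak centre
  (sd = 0.35 × peak length), strand uniform.  Natural duplicates are pure
  coordinate collisions of independent templates — no special process.
  Truncated (rather than clipped) sampling avoids probability atoms at
  peak edges that would distort collision counts.
* PCR: per-template extra copies are geometric.  Amplification is
  locus-specific: a fixed fraction of peaks (default 0.25) is amplified at
  rate `pcr_rate`, the rest are amplification-free, mirroring jackpotting
  and GC-dependent amplification bias.  `SimConfig.for_natural_fraction`
  solves the rate analytically from the expected collision count
  (E[natural] per peak = T − Σ_cells (1 − e^(−T·w)) under the truncated
  normal cell weights) so a library hits a requested true natural
  fraction; the calibration reuses the simulation's own intensity and
  amplified-peak draws via per-purpose RNG sub-streams, making it exact in
  expectation and independent of the estimator.
* Pseudo p-values: p = exp(−template count / 200), giving the ascending
  confidence order a peak caller would produce without calling peaks.
* Reads are emitted pre-aligned (MAPQ 30–60, perfect MD/NM); optional
  fractions of reads failing the MAPQ or first-five-base filters can be
  injected to exercise the filters.  Paired mode draws one fragment length
  per template so PCR copies share both ends.

What the generator does *not* model: sequencing errors and base-quality
structure, GC-dependent coverage, mappability gaps, chromatin-driven
background structure, optical duplicates, and peak-caller boundary error
(simulated peaks are exactly the template-generating intervals).  Passing
tests therefore demonstrate the method's correctness under its own
assumptions — collision-driven natural duplicates plus locus-heterogeneous
amplification — not its accuracy on any particular real dataset.

## Numerical choices and edge cases

* Lowess oracle testing compares against an independent per-point weighted
  least-squares implementation with delta = 0 (with delta > 0 non-anchor
  points are interpolated); agreement is required to 1e-6.
* Ties in top-position ranking break by (chrom, pos, strand); ties in
  p-value break by coordinate.
* Degenerate inputs raise typed errors: unsorted alignments (naming the
  first offender), zero-read libraries, all-equal lowess abscissae, fewer
  than three peaks for correlation, noise draws exceeding the pool.
* Fisher-z CIs are undefined at |r| = 1 and returned as NaN.
* Spearman rho for constant columns is reported as NaN rather than an
  arbitrary zero.

## Known limitations

The partition assumes amplified loci are a minority; if most peaks are
strongly amplified the robust fit follows the amplified bulk and the
signal fraction is overestimated.  The per-position cap slightly biases
the estimate upward when amplification is extreme (the capped pool is
enriched for natural duplicates relative to the raw pool).  Point
assignment of reads to regions differs from any-overlap counting by at
most the reads whose key lies within a read length of a boundary.
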