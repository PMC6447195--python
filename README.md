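# peakdedup

Signal-aware deduplication for ChIP-seq alignments.

## The problem

Standard practice removes every duplicate read (same mapping position and
strand; same both-end coordinates for pairs) before peak calling and signal
quantification.  But inside peaks many duplicates are **natural**:
independent DNA fragments that collide on the same 5' coordinate simply
because enriched regions are read-dense.  Removing them all flattens the
signal exactly where it matters most — the strongest peaks.  Outside peaks,
duplicates are overwhelmingly **PCR copies** and should still be removed.

`peakdedup` quantifies duplicates per region, predicts how many in-peak
duplicates are natural, and writes a *properly deduplicated* alignment file
that keeps the predicted natural duplicates in peaks while removing all
other duplicates.

## The method

For each blacklist-filtered peak *i* with length *L_i* (kb), let

- *x_i* = nonredundant reads / *L_i*  (the **target enrichment level**),
- *y_i* = duplicates / *L_i* after keeping at most **5 duplicates per
  (position, strand)** (the capped **duplicate level**).

A robust locally weighted regression (lowess: tricube weights, span 2/3,
three bisquare reweighting passes) of *y* on *x* across peaks gives a
predicted natural-duplicate level *ŷ(x_i)*.  Each peak's natural level is
set to **min(y_i, ŷ(x_i))** — the raw or predicted level, whichever is
smaller — yielding per-peak signal counts *S_i* and noise counts
*N_i = capped_i − S_i*.  A uniform random sample of *N_i* duplicate read ids
is removed from each peak; everything else that is a duplicate (non-peak,
over-cap, blacklist) is removed too.  Natural duplicates track the
enrichment trend because coordinate collisions are a smooth increasing
function of local fragment density; PCR jackpotting inflates individual
peaks above that trend.

The package also computes the standard duplicate-accounting QC suite:
duplicate rate, NRF (nonredundant fraction), FRiP, peak coverage of the
mappable genome (0.75 × genome size), RPK10M levels, confidence-decile
duplicate profiles, flanking-region baselines, top duplicated positions,
replicate correlation of duplicate levels (log2 RPK10M, Pearson with
Fisher-z CI), and Spearman correlations of duplicate level with six
peak features (enrichment, input levels, GC, segmental duplication,
low-complexity content).

## Worked example

The built-in simulator generates a library with per-read ground truth
(template ids and PCR-copy flags), here calibrated so that 60% of in-peak
duplicates are natural:

```python
import peakdedup as pk
from peakdedup.simdata import SimConfig, simulate_library, truth_summary
from peakdedup.dedup_rewrite import collect_key_read_ids
from peakdedup.dup_metrics import library_metrics

cfg = SimConfig.for_natural_fraction(0.6, seed=1)   # 1 Mb genome, 50 peaks
sim = simulate_library(cfg)
tallies, flags = pk.mark_duplicates(iter(sim.records))
print(library_metrics(tallies, sim.peaks, cfg.chrom_sizes))

key_ids = collect_key_read_ids(iter(sim.records))
f_true, _ = truth_summary(sim.truth, tallies, key_ids, sim.peaks)
print("true natural fraction:", round(f_true, 3))

fit = pk.SignalDuplicateModel.from_tallies(sim.peaks, tallies).fit()
print(fit.summary())
```

Output:

```
LibraryQC(n_uniq=53710, dup_rate=0.1820145224353007, nrf=0.8179854775646993,
          frip=0.847134337870442, peak_size_frac=0.13333333333333333,
          pct_dups_in_peaks=0.998056464811784)
true natural fraction: 0.602
Signal-duplicate partition (cap -> lowess -> min)
=================================================
peaks:                 50
capped duplicates:     9731
predicted signal (S):  5771
predicted noise (N):   3960
library signal frac:   0.5931
lowess span:           0.6667  (robust iterations: 3)
top-decile signal frac: 0.6073
```

The library has 53,710 uniquely mapped reads of which 18.2% are duplicates,
almost all inside peaks (99.8%).  The partition predicts that 59.3% of the
capped in-peak duplicates are natural signal — within one point of the
simulator's ground truth (60.2%).  `fit.partition` holds the per-peak
S/N table and `peakdedup dedup` (or `peakdedup run`) writes the rewritten
BAM keeping exactly those S duplicates per peak.

The same workflow runs from the shell:

```
peakdedup simulate --seed 1 --out-dir sim/
peakdedup run --bam sim/sim.bam --peaks sim/sim_peaks.bed \
    --chrom-sizes chrom.sizes --seed 17 --out-dir results/
```

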