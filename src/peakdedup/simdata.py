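"""Synthetic ChIP-seq libraries with per-read duplicate ground truth.

The generator emulates the two duplicate-generating mechanisms of a real
ChIP-seq library:

* **Natural duplicates** arise purely from coordinate collisions of
  independent templates.  Template 5' positions inside a peak follow a
  truncated normal centred on the peak; whenever two independent templates
  land on the same (position, strand) key, the extra ones are natural
  duplicates.
* **PCR duplicates** are extra sequenced copies of a template.  Copy
  counts are geometric per template.  Amplification is *locus-specific*:
  a configurable fraction of peaks is "amplified" (per-template geometric
  copy rate ``pcr_rate``) while the rest are amplification-free.  This
  heterogeneity mirrors the jackpotting / GC-dependent amplification bias
  of real libraries, and is what makes PCR duplicates visible as peaks
  lying above the collision-driven trend of duplicate level versus
  enrichment level.  With amplification uniform across loci the PCR
  component would itself be a smooth function of enrichment and no
  regression on enrichment could separate it.

:meth:`SimConfig.for_natural_fraction` solves the amplified-peak copy rate
analytically (from the expected collision count under the configured
template density) so the simulated library has a requested true
natural-duplicate fraction among in-peak duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import pysam

from .errors import PeakDedupError

READ_LENGTH = 50

# deterministic sub-streams so analytic calibration can reproduce exactly
# the draws the simulation will make
_STREAM_PLACEMENT = 1
_STREAM_INTENSITY = 2
_STREAM_AMPLIFIED = 3
_STREAM_READS = 4


def _stream(seed: int, which: int) -> np.random.Generator:
    return np.random.default_rng([seed, which])


@dataclass
class SimConfig:
    """Study conditions for one synthetic library.

    Defaults describe a desk-scale narrow-peak library: a 1 Mb toy genome,
    50 non-overlapping 2 kb peaks holding ~85% of ~50k templates with
    lognormal intensity spread, uniform background elsewhere, and
    locus-specific PCR amplification in a quarter of the peaks.
    """

    chrom_sizes: Dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    n_peaks: int = 50
    peak_length: int = 2_000
    n_templates: int = 50_000
    peak_template_fraction: float = 0.85   # remainder is background
    intensity_sdlog: float = 0.5           # lognormal spread of per-peak intensity
    position_sd_frac: float = 0.35         # template 5' spread, fraction of peak length
    pcr_rate: float = 0.0                  # geometric copy rate in amplified peaks
    amplified_peak_fraction: float = 0.25  # fraction of peaks subject to amplification
    background_pcr_rate: float = 0.0
    paired: bool = False
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 20.0
    read_length: int = READ_LENGTH
    pvalue_scale: float = 200.0            # pseudo p = exp(-templates / scale)
    filter_fail_mapq_frac: float = 0.0     # extra reads failing the MAPQ filter
    filter_fail_mismatch_frac: float = 0.0  # extra reads with a first-5-bp mismatch
    seed: int = 0
    replicate_id: int = 0                  # perturbs only the read draws; same peaks

    def __post_init__(self):
        if self.seed is None:
            raise PeakDedupError("seed is mandatory")
        for name in ("pcr_rate", "background_pcr_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise PeakDedupError(f"{name} must be in [0, 1), got {v}")

    # -- draws shared between calibration and simulation ----------------

    def peak_intensities(self) -> np.ndarray:
        rng = _stream(self.seed, _STREAM_INTENSITY)
        rel = rng.lognormal(0.0, self.intensity_sdlog, self.n_peaks)
        return rel / rel.sum() * self.n_templates * self.peak_template_fraction

    def amplified_peaks(self) -> np.ndarray:
        rng = _stream(self.seed, _STREAM_AMPLIFIED)
        n_amp = max(1, int(round(self.amplified_peak_fraction * self.n_peaks)))
        return rng.choice(self.n_peaks, n_amp, replace=False)

    # -- analytic collision expectations -------------------------------

    def _cell_weights(self) -> np.ndarray:
        L, sd = self.peak_length, self.peak_length * self.position_sd_frac
        grid = np.arange(L) + 0.5
        w = np.exp(-0.5 * ((grid - L / 2) / sd) ** 2)
        w = w / w.sum()
        return np.concatenate([w, w]) / 2.0  # two strands

    def expected_natural_duplicates(self, intensities: np.ndarray) -> float:
        """E[in-peak natural duplicates] given per-peak expected template counts."""
        W = self._cell_weights()
        return float(sum(T - (1 - np.exp(-T * W)).sum() for T in intensities))

    @classmethod
    def for_natural_fraction(cls, f: float, seed: int, **overrides) -> "SimConfig":
        """Config whose true natural fraction among in-peak duplicates is ~``f``.

        Solves the amplified-peak geometric copy rate so the expected PCR
        duplicate count equals ``E[natural] * (1 - f) / f``, using the same
        intensity and amplified-peak draws the simulation will make.
        """
        if not (0 < f <= 1):
            raise PeakDedupError(f"natural fraction must be in (0, 1], got {f}")
        cfg = cls(seed=seed, **overrides)
        lam = cfg.peak_intensities()
        if f == 1.0:
            return replace(cfg, pcr_rate=0.0)
        e_nat = cfg.expected_natural_duplicates(lam)
        t_amp = lam[cfg.amplified_peaks()].sum()
        mean_extra = e_nat * (1 - f) / f / t_amp
        rho = mean_extra / (1 + mean_extra)
        return replace(cfg, pcr_rate=float(rho))


@dataclass
class SimResult:
    """In-memory simulated library."""

    records: List[pysam.AlignedSegment]
    header: pysam.AlignmentHeader
    peaks: pd.DataFrame       # chrom, start, end, name, score, strand, p_value
    truth: pd.DataFrame       # read_id, template_id, is_pcr_copy, origin
    config: SimConfig

    def write(self, out_dir: str, prefix: str = "sim") -> Dict[str, str]:
        """Write BAM (sorted, indexed), peaks BED6+p and truth TSV."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        bam = os.path.join(out_dir, f"{prefix}.bam")
        with pysam.AlignmentFile(bam, "wb", header=self.header) as fh:
            for rec in self.records:
                fh.write(rec)
        pysam.index(bam)
        peaks_path = os.path.join(out_dir, f"{prefix}_peaks.bed")
        self.peaks.to_csv(peaks_path, sep="\t", header=False, index=False)
        truth_path = os.path.join(out_dir, f"{prefix}_truth.tsv")
        self.truth.to_csv(truth_path, sep="\t", index=False)
        return {"bam": bam, "peaks": peaks_path, "truth": truth_path}


def _margin(cfg: SimConfig) -> int:
    if cfg.paired:
        return int(cfg.fragment_length_mean + 5 * cfg.fragment_length_sd) + 10
    return cfg.read_length + 10


def _place_peaks(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping peak placement with a margin for read/fragment bodies."""
    margin = _margin(cfg)
    rows = []
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(cfg.n_peaks, sizes / sizes.sum())
    gap = 2 * margin  # keeps flanks/buffers of neighbouring peaks disjoint too
    for chrom, n in zip(chroms, n_per):
        size = cfg.chrom_sizes[chrom]
        if n == 0:
            continue
        # ordered-uniform construction: n intervals of peak_length with
        # pairwise gaps > `gap`, uniformly over all feasible placements
        free = size - 2 * margin - n * cfg.peak_length - (n - 1) * gap
        if free <= 0:
            raise PeakDedupError(
                f"cannot place {n} peaks of {cfg.peak_length} bp with {gap} bp "
                f"spacing on {chrom} ({size} bp)"
            )
        offsets = np.sort(rng.integers(0, free, size=n))
        starts = margin + offsets + np.arange(n) * (cfg.peak_length + gap)
        rows.extend((chrom, int(s), int(s + cfg.peak_length)) for s in starts)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"peak_{i}" for i in range(len(df))]
    return df


def _truncnorm_positions(
    rng: np.random.Generator, center: float, sd: float, low: int, high: int, n: int
) -> np.ndarray:
    """Integer positions from a normal truncated to [low, high)."""
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.normal(center, sd, size=2 * (n - filled) + 16)
        draw = draw[(draw >= low) & (draw < high)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take].astype(int)
        filled += take
    return out


def _geometric_extra(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    """Extra PCR copies per template: P(g) = (1 - rate) * rate**g."""
    if rate <= 0 or n == 0:
        return np.zeros(n, dtype=int)
    return rng.geometric(1 - rate, size=n) - 1


def simulate_library(config: SimConfig) -> SimResult:
    """Generate a coordinate-sorted synthetic library with ground truth.

    Every read is uniquely mapped (MAPQ >= 30, clean first bases) except the
    optional filter-failure reads, whose truth ``origin`` is
    ``filter_fail_mapq`` / ``filter_fail_mismatch``; those are meant to be
    removed by :func:`peakdedup.alignment_io.passes_filters` and are
    excluded from template bookkeeping (their template_id is -1).
    """
    cfg = config
    peaks = _place_peaks(cfg, _stream(cfg.seed, _STREAM_PLACEMENT))
    lam = cfg.peak_intensities()
    amp_idx = set(cfg.amplified_peaks().tolist())
    rng = np.random.default_rng([cfg.seed, _STREAM_READS, cfg.replicate_id])

    tmpl_chrom: List[str] = []
    tmpl_pos: List[np.ndarray] = []
    tmpl_strand: List[np.ndarray] = []
    tmpl_origin: List[np.ndarray] = []
    tmpl_rate: List[float] = []
    margin = _margin(cfg)
    for i in range(len(peaks)):
        row = peaks.iloc[i]
        T = rng.poisson(lam[i])
        L = cfg.peak_length
        sd = L * cfg.position_sd_frac
        pos = _truncnorm_positions(
            rng, row["start"] + L / 2, sd, int(row["start"]), int(row["end"]), T
        )
        tmpl_chrom.append(str(row["chrom"]))
        tmpl_pos.append(pos)
        tmpl_strand.append(rng.integers(0, 2, T))
        tmpl_origin.append(np.full(T, row["name"], dtype=object))
        tmpl_rate.append(cfg.pcr_rate if i in amp_idx else 0.0)
    n_bg = rng.poisson(cfg.n_templates * (1 - cfg.peak_template_fraction))
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    bg_per = rng.multinomial(n_bg, sizes / sizes.sum())
    for chrom, n in zip(chroms, bg_per):
        lo, hi = margin, cfg.chrom_sizes[chrom] - margin
        tmpl_chrom.append(chrom)
        tmpl_pos.append(rng.integers(lo, hi, size=n))
        tmpl_strand.append(rng.integers(0, 2, n))
        tmpl_origin.append(np.full(n, "background", dtype=object))
        tmpl_rate.append(cfg.background_pcr_rate)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(s)} for c, s in cfg.chrom_sizes.items()],
        }
    )
    ref_ids = {c: i for i, c in enumerate(cfg.chrom_sizes)}

    reads: List[Tuple[int, int, bool, str, int]] = []
    truth_rows: List[Tuple[str, int, bool, str]] = []
    template_id = 0
    for chrom, pos_arr, strand_arr, origin_arr, rate in zip(
        tmpl_chrom, tmpl_pos, tmpl_strand, tmpl_origin, tmpl_rate
    ):
        extra = _geometric_extra(rng, rate, len(pos_arr))
        cid = ref_ids[chrom]
        for pos, strand, origin, g in zip(pos_arr, strand_arr, origin_arr, extra):
            # fragment length is a template property: PCR copies share both ends
            fl = int(
                max(
                    rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd),
                    cfg.read_length + 2,
                )
            ) if cfg.paired else 0
            for copy_index in range(1 + int(g)):
                rid = f"r{template_id:07d}.{copy_index}"
                truth_rows.append((rid, template_id, copy_index > 0, origin))
                reads.append((cid, int(pos), bool(strand), rid, fl))
            template_id += 1

    records = []
    rl = cfg.read_length
    seq = "A" * rl
    qual = pysam.qualitystring_to_array("I" * rl)
    for cid, key_pos, rev, rid, fl in reads:
        mapq = int(rng.integers(30, 61))
        if not cfg.paired:
            rec = pysam.AlignedSegment(header)
            rec.query_name = rid
            rec.reference_id = cid
            rec.flag = 16 if rev else 0
            rec.reference_start = key_pos - rl + 1 if rev else key_pos
            rec.mapping_quality = mapq
            rec.cigarstring = f"{rl}M"
            rec.query_sequence = seq
            rec.query_qualities = qual
            rec.set_tag("NM", 0)
            rec.set_tag("MD", str(rl))
            records.append(rec)
        else:
            if not rev:
                ends = [(key_pos, False, key_pos + fl - rl, True),
                        (key_pos + fl - rl, True, key_pos, False)]
            else:
                ends = [(key_pos - rl + 1, True, key_pos - fl + 1, False),
                        (key_pos - fl + 1, False, key_pos - rl + 1, True)]
            for which, (start, is_rev, mstart, mrev) in enumerate(ends):
                rec = pysam.AlignedSegment(header)
                rec.query_name = rid
                rec.reference_id = cid
                rec.next_reference_id = cid
                rec.flag = (
                    1 | 2 | (16 if is_rev else 0) | (32 if mrev else 0)
                    | (64 if which == 0 else 128)
                )
                rec.reference_start = start
                rec.next_reference_start = mstart
                rec.template_length = -fl if is_rev else fl
                rec.mapping_quality = mapq
                rec.cigarstring = f"{rl}M"
                rec.query_sequence = seq
                rec.query_qualities = qual
                rec.set_tag("NM", 0)
                rec.set_tag("MD", str(rl))
                records.append(rec)

    records.extend(_filter_failure_reads(cfg, rng, header, ref_ids, len(truth_rows)))
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))

    template_counts = (
        pd.Series([o for _, _, is_pcr, o in truth_rows if not is_pcr]).value_counts()
    )
    p = peaks.copy()
    tcount = p["name"].map(template_counts).fillna(0).astype(int)
    p["score"] = np.minimum(tcount, 1000)
    p["strand"] = "."
    p["p_value"] = np.exp(-tcount / cfg.pvalue_scale)
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "template_id", "is_pcr_copy", "origin"]
    )
    return SimResult(records=records, header=header, peaks=p, truth=truth, config=cfg)


def _filter_failure_reads(cfg, rng, header, ref_ids, n_total):
    """Optional reads that must be removed by the uniqueness filters."""
    out = []
    rl = cfg.read_length
    spec = [
        ("filter_fail_mapq", int(round(cfg.filter_fail_mapq_frac * n_total))),
        ("filter_fail_mismatch", int(round(cfg.filter_fail_mismatch_frac * n_total))),
    ]
    chrom = next(iter(cfg.chrom_sizes))
    size = cfg.chrom_sizes[chrom]
    for origin, n in spec:
        for j in range(n):
            pos = int(rng.integers(rl, size - rl - 1))
            rec = pysam.AlignedSegment(header)
            rec.query_name = f"{origin}_{j}"
            rec.reference_id = ref_ids[chrom]
            rec.flag = 0
            rec.reference_start = pos
            rec.cigarstring = f"{rl}M"
            rec.query_sequence = "A" * rl
            rec.query_qualities = pysam.qualitystring_to_array("I" * rl)
            if origin == "filter_fail_mapq":
                rec.mapping_quality = int(rng.integers(0, 20))
                rec.set_tag("NM", 0)
                rec.set_tag("MD", str(rl))
            else:
                rec.mapping_quality = 60
                mpos = int(rng.integers(0, 5))
                rec.set_tag("NM", 1)
                rec.set_tag("MD", f"{mpos}C{rl - mpos - 1}")
            out.append(rec)
    return out


def truth_summary(
    truth: pd.DataFrame,
    tallies,
    key_read_ids,
    peaks: pd.DataFrame,
) -> Tuple[float, pd.DataFrame]:
    """Ground-truth natural/PCR split of in-peak duplicates.

    Within each key holding ``r`` reads of ``m`` distinct templates, the
    ``r - 1`` duplicates decompose into ``m - 1`` natural duplicates (first
    read of each extra template) and ``r - m`` PCR duplicates (additional
    copies of any template).  Returns the natural fraction among in-peak
    duplicates and a per-peak table of natural/PCR counts.
    """
    from .dup_metrics import assign_keys

    read_to_template = dict(zip(truth["read_id"], truth["template_id"]))
    assignment = assign_keys(tallies, peaks)
    peak_ids = (
        peaks["name"].astype(str).tolist()
        if "name" in peaks.columns
        else [f"peak_{i}" for i in range(len(peaks))]
    )
    per_peak = {p: [0, 0] for p in peak_ids}  # [natural, pcr]
    for key, row in assignment.items():
        if row is None:
            continue
        t = tallies[key]
        if t.n_reads < 2:
            continue
        templates = set()
        for rid in key_read_ids[key]:
            if rid not in read_to_template:
                raise PeakDedupError(f"read id {rid!r} missing from truth")
            templates.add(read_to_template[rid])
        m = len(templates)
        per_peak[peak_ids[row]][0] += m - 1
        per_peak[peak_ids[row]][1] += t.n_reads - m
    table = pd.DataFrame(
        [(p, nat, pcr) for p, (nat, pcr) in per_peak.items()],
        columns=["peak_id", "natural_duplicates", "pcr_duplicates"],
    )
    tot_nat = int(table["natural_duplicates"].sum())
    tot_pcr = int(table["pcr_duplicates"].sum())
    frac = tot_nat / (tot_nat + tot_pcr) if tot_nat + tot_pcr else float("nan")
    return frac, table
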