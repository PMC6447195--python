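"""Interval algebra for peaks, blacklist, complements, flanks and composition.

Coordinates are BED-style 0-based half-open throughout; SAM's 1-based
positions are converted at the I/O boundary by pysam.  Peaks live in pandas
DataFrames with at least ``chrom, start, end`` and optionally ``name``,
``p_value`` (linear scale) and ``fdr`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import PeakDedupError

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "name"]

#: fraction of the genome considered mappable when expressing peak coverage
MAPPABLE_GENOME_FRACTION = 0.75


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    name: str = "."
    p_value: Optional[float] = None
    fdr: Optional[float] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise PeakDedupError(f"peak {self.name}: end {self.end} <= start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Sorted, merged, non-overlapping intervals with their chromosome sizes."""

    label: str
    intervals: pd.DataFrame  # columns chrom, start, end (sorted, merged)
    chrom_sizes: Dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, label: str, df: pd.DataFrame, chrom_sizes=None) -> "RegionSet":
        return cls(label, merge_intervals(df), dict(chrom_sizes or {}))

    def total_bases(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def _index(self):
        cached = getattr(self, "_point_index", None)
        if cached is None:
            cached = {
                chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for chrom, sub in self.intervals.sort_values(["chrom", "start"]).groupby("chrom")
            }
            object.__setattr__(self, "_point_index", cached)
        return cached

    def contains_point(self, chrom: str, pos: int) -> bool:
        idx = self._index()
        if chrom not in idx:
            return False
        starts, ends = idx[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        return bool(i >= 0 and pos < ends[i])


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort intervals and merge any >= 1 bp overlap.

    Half-open semantics: abutting intervals [a,b) and [b,c) share no base
    and are kept separate.
    """
    if df.empty:
        return df[["chrom", "start", "end"]].copy()
    out = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # >= 1 bp overlap
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def read_chrom_sizes(path: str) -> Dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def read_bed(path: str) -> pd.DataFrame:
    """BED3/BED6 reader (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name", 4: "score", 5: "strand"})
    keep = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    return df[keep]


def read_narrowpeak(path: str) -> pd.DataFrame:
    """ENCODE narrowPeak reader; converts -log10 p/q to linear p_value/fdr."""
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signal", "neg_log10_p", "neg_log10_q", "summit"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    df["p_value"] = 10.0 ** (-df["neg_log10_p"])
    df["fdr"] = np.where(df["neg_log10_q"] >= 0, 10.0 ** (-df["neg_log10_q"]), np.nan)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _check_chrom_overlap(peaks: pd.DataFrame, other: pd.DataFrame, other_label: str) -> None:
    pc, oc = set(peaks["chrom"]), set(other["chrom"])
    if pc and oc and not (pc & oc):
        summary = {"peaks": sorted(pc)[:5], other_label: sorted(oc)[:5]}
        logger.warning("no chromosome names shared between peaks and %s: %s", other_label, summary)


def filter_blacklist(
    peaks: pd.DataFrame, blacklist: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split peaks into (kept, removed); any >= 1 bp blacklist overlap removes a peak."""
    if peaks.empty:
        return peaks.copy(), peaks.copy()
    _check_chrom_overlap(peaks, blacklist, "blacklist")
    bl = merge_intervals(blacklist)
    removed_mask = np.zeros(len(peaks), dtype=bool)
    for chrom, sub in bl.groupby("chrom"):
        sel = peaks["chrom"] == chrom
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        p_start = peaks.loc[sel, "start"].to_numpy()
        p_end = peaks.loc[sel, "end"].to_numpy()
        # overlap iff some blacklist interval with start < p_end and end > p_start
        i = np.searchsorted(ends, p_start, side="right")
        hit = (i < len(starts)) & (starts[np.minimum(i, len(starts) - 1)] < p_end)
        removed_mask[np.flatnonzero(sel.to_numpy())] = hit
    kept = peaks[~removed_mask].reset_index(drop=True)
    removed = peaks[removed_mask].reset_index(drop=True)
    logger.info("blacklist filter: kept %d, removed %d peaks", len(kept), len(removed))
    return kept, removed


def pad_intervals(df: pd.DataFrame, pad: int, chrom_sizes: Dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    out["start"] = np.maximum(out["start"] - pad, 0)
    out["end"] = [min(e + pad, chrom_sizes.get(c, e + pad)) for c, e in zip(out["chrom"], out["end"])]
    return merge_intervals(out)


def nonpeak_complement(
    peaks: pd.DataFrame, chrom_sizes: Dict[str, int], buffer_bp: int = 100
) -> RegionSet:
    """Complement of peaks padded by ``buffer_bp``, over all chromosomes."""
    padded = pad_intervals(peaks, buffer_bp, chrom_sizes)
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = padded[padded["chrom"] == chrom]
        cursor = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s > cursor:
                rows.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < size:
            rows.append((chrom, cursor, size))
    return RegionSet("nonpeak", pd.DataFrame(rows, columns=["chrom", "start", "end"]), chrom_sizes)


def flanking_regions(
    peak: Peak, gap_bp: int = 300, chrom_sizes: Optional[Dict[str, int]] = None
) -> Tuple[Optional[Peak], Optional[Peak]]:
    """Peak-sized windows ``gap_bp`` up- and downstream of a peak.

    Flanks are truncated at chromosome edges; a flank that falls entirely
    outside the chromosome is dropped (returned as None, with a log note).
    """
    L = peak.length
    size = None if chrom_sizes is None else chrom_sizes.get(peak.chrom)
    f5_start, f5_end = peak.start - gap_bp - L, peak.start - gap_bp
    f3_start, f3_end = peak.end + gap_bp, peak.end + gap_bp + L

    def _clip(s, e, tag):
        s2 = max(s, 0)
        e2 = min(e, size) if size is not None else e
        if e2 <= s2:
            logger.info("flank %s of peak %s out of chromosome bounds; dropped", tag, peak.name)
            return None
        return Peak(peak.chrom, s2, e2, f"{peak.name}_{tag}")

    return _clip(f5_start, f5_end, "flank5"), _clip(f3_start, f3_end, "flank3")


def merge_replicate_peaks(peak_lists: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Single-linkage merge of >= 1 bp overlapping peaks across replicates.

    Returns merged intervals with a ``sources`` column listing the original
    (replicate_index, name) pairs collapsed into each interval.
    """
    if len(peak_lists) < 2:
        raise PeakDedupError("merge_replicate_peaks expects at least two peak lists")
    tagged = []
    for i, df in enumerate(peak_lists):
        sub = df[["chrom", "start", "end"]].copy()
        names = df["name"] if "name" in df.columns else [f"peak{j}" for j in range(len(df))]
        sub["source"] = [(i, str(n)) for n in names]
        tagged.append(sub)
    allp = pd.concat(tagged, ignore_index=True).sort_values(
        ["chrom", "start", "end"], ignore_index=True
    )
    rows = []
    for chrom, sub in allp.groupby("chrom", sort=True):
        cur_s = cur_e = None
        src: List[Tuple[int, str]] = []
        for s, e, so in zip(sub["start"], sub["end"], sub["source"]):
            if cur_s is None:
                cur_s, cur_e, src = s, e, [so]
            elif s < cur_e:
                cur_e = max(cur_e, e)
                src.append(so)
            else:
                rows.append((chrom, cur_s, cur_e, tuple(src)))
                cur_s, cur_e, src = s, e, [so]
        rows.append((chrom, cur_s, cur_e, tuple(src)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "sources"])
    out["name"] = [f"merged_{i}" for i in range(len(out))]
    return out


def annotate_composition(
    peaks: pd.DataFrame,
    genome_fasta: str,
    segdup: Optional[RegionSet] = None,
    lowcomplex: Optional[RegionSet] = None,
) -> pd.DataFrame:
    """Add gc, pct_segdup and pct_lowcomplex columns to a peak table.

    GC counts G/C case-insensitively; N is excluded from the numerator but
    stays in the denominator (peak length).  Percentages are overlapping
    bases over peak length, in [0, 1].
    """
    from pyfaidx import Fasta

    fasta = Fasta(genome_fasta)
    gc = []
    for chrom, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"]):
        if chrom not in fasta:
            raise PeakDedupError(f"chromosome {chrom!r} absent from {genome_fasta}")
        if e > len(fasta[chrom]):
            raise PeakDedupError(f"peak {chrom}:{s}-{e} beyond contig length {len(fasta[chrom])}")
        seq = str(fasta[chrom][s:e]).upper()
        gc.append((seq.count("G") + seq.count("C")) / (e - s))
    out = peaks.copy()
    out["gc"] = gc
    for col, rs in (("pct_segdup", segdup), ("pct_lowcomplex", lowcomplex)):
        if rs is None:
            continue
        out[col] = [
            overlap_bases(rs.intervals, chrom, s, e) / (e - s)
            for chrom, s, e in zip(out["chrom"], out["start"], out["end"])
        ]
    return out


def overlap_bases(intervals: pd.DataFrame, chrom: str, start: int, end: int) -> int:
    """Bases of [start, end) covered by a merged interval set."""
    sub = intervals[intervals["chrom"] == chrom]
    if sub.empty:
        return 0
    s = np.maximum(sub["start"].to_numpy(), start)
    e = np.minimum(sub["end"].to_numpy(), end)
    return int(np.maximum(e - s, 0).sum())


def peak_size_fraction(
    peaks: pd.DataFrame,
    chrom_sizes: Dict[str, int],
    mappable_fraction: float = MAPPABLE_GENOME_FRACTION,
) -> float:
    """Total peak bases over the mappable genome (default 0.75 x genome size)."""
    total = int((peaks["end"] - peaks["start"]).sum())
    genome = sum(chrom_sizes.values())
    return total / (mappable_fraction * genome)
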