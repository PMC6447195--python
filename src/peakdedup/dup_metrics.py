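"""Duplicate-accounting statistics per region set and per library.

Reads are assigned to regions by the 5' coordinate of their duplicate key
(point assignment; for read pairs, the smaller end).  Because every key maps
to exactly one point, counts over a disjoint partition of the genome sum
exactly to the library totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .alignment_io import DupKey, PositionTally
from .errors import PeakDedupError
from .regions import RegionSet, merge_intervals, peak_size_fraction


@dataclass
class RegionCounts:
    region_id: str
    n_total: int = 0            # reads assigned to the region
    n_nondup: int = 0           # nonredundant reads (distinct keys)
    n_positions: int = 0        # distinct keys with >= 1 read
    n_positions_with_dup: int = 0

    @property
    def n_dup(self) -> int:
        return self.n_total - self.n_nondup


@dataclass
class LibraryQC:
    n_uniq: int                 # filtered uniquely mapped reads (or pairs)
    dup_rate: float             # duplicates / n_uniq
    nrf: float                  # distinct positions / n_uniq
    frip: float                 # nonredundant reads in peaks / total nonredundant
    peak_size_frac: float       # peak bases / (0.75 x genome)
    pct_dups_in_peaks: float    # duplicates in peaks / library duplicates


@dataclass
class GroupProfile:
    group_index: int            # 1..k, 1 = most confident (smallest p)
    n_peaks: int
    n_reads: int
    n_dup: int
    dup_rate_in_group: float            # group duplicates / library n_uniq
    pct_library_dups_in_group: float    # group duplicates / library duplicates
    matched_input_dup_rate: Optional[float] = None
    matched_input_pct: Optional[float] = None


def key_point(key: DupKey) -> Tuple[str, int]:
    """Assignment point of a duplicate key (smaller end for pairs)."""
    return key[0], key[1]


def assign_keys(
    tallies: Dict[DupKey, PositionTally], regions: pd.DataFrame
) -> Dict[DupKey, Optional[int]]:
    """Map each key to the row index of the non-overlapping region containing
    its assignment point, or None."""
    merged = regions.sort_values(["chrom", "start"]).reset_index()
    by_chrom = {}
    for chrom, sub in merged.groupby("chrom"):
        by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["index"].to_numpy(),
        )
    out: Dict[DupKey, Optional[int]] = {}
    for key in tallies:
        chrom, pos = key_point(key)
        hit = None
        if chrom in by_chrom:
            starts, ends, idx = by_chrom[chrom]
            i = np.searchsorted(starts, pos, side="right") - 1
            if i >= 0 and pos < ends[i]:
                hit = int(idx[i])
        out[key] = hit
    return out


def count_regions(
    regions: pd.DataFrame,
    tallies: Dict[DupKey, PositionTally],
    region_id_col: str = "name",
) -> pd.DataFrame:
    """Per-region read accounting from tallies.

    ``regions`` must be non-overlapping.  Returns one row per region with
    n_total, n_nondup, n_dup, n_positions, n_positions_with_dup, plus the
    region coordinates.
    """
    ids = (
        regions[region_id_col].astype(str)
        if region_id_col in regions.columns
        else pd.Series([f"region_{i}" for i in range(len(regions))])
    )
    counts = [RegionCounts(region_id=r) for r in ids]
    assignment = assign_keys(tallies, regions)
    for key, row in assignment.items():
        if row is None:
            continue
        t = tallies[key]
        c = counts[row]
        c.n_total += t.n_reads
        c.n_nondup += 1
        c.n_positions += 1
        if t.n_reads >= 2:
            c.n_positions_with_dup += 1
    out = regions[["chrom", "start", "end"]].copy().reset_index(drop=True)
    out["region_id"] = list(ids)
    for col in ("n_total", "n_nondup", "n_positions", "n_positions_with_dup"):
        out[col] = [getattr(c, col) for c in counts]
    out["n_dup"] = out["n_total"] - out["n_nondup"]
    return out


def library_totals(tallies: Dict[DupKey, PositionTally]) -> Tuple[int, int, int]:
    """(n_uniq reads, n_positions, n_duplicates) over all tallies."""
    n_uniq = sum(t.n_reads for t in tallies.values())
    n_pos = len(tallies)
    return n_uniq, n_pos, n_uniq - n_pos


def library_metrics(
    tallies: Dict[DupKey, PositionTally],
    peaks: pd.DataFrame,
    chrom_sizes: Dict[str, int],
    mappable_fraction: float = 0.75,
) -> LibraryQC:
    """Library-level QC: duplicate rate, NRF, FRiP, peak coverage, duplicate share."""
    n_uniq, n_pos, n_dup = library_totals(tallies)
    if n_uniq == 0:
        raise PeakDedupError("zero-read library")
    peak_counts = count_regions(merge_intervals(peaks), tallies, region_id_col="name")
    nondup_in_peaks = int(peak_counts["n_nondup"].sum())
    dups_in_peaks = int(peak_counts["n_dup"].sum())
    return LibraryQC(
        n_uniq=n_uniq,
        dup_rate=n_dup / n_uniq,
        nrf=n_pos / n_uniq,
        frip=nondup_in_peaks / n_pos,
        peak_size_frac=peak_size_fraction(peaks, chrom_sizes, mappable_fraction),
        pct_dups_in_peaks=(dups_in_peaks / n_dup) if n_dup else float("nan"),
    )


def rpk10m(count: float, length_bp: float, library_size: float) -> float:
    """Reads per kilobase per 10 million library reads."""
    if length_bp <= 0 or library_size <= 0:
        raise PeakDedupError("length_bp and library_size must be positive")
    return count / (length_bp / 1e3) / (library_size / 1e7)


def enrichment_level(
    ip_in_peaks: int, ip_total: int, input_in_peaks: int, input_total: int
) -> float:
    """(IP nonredundant fraction in peaks) / (input fraction in same regions).

    Returns ``inf`` when the input has no reads in the peak regions.
    """
    if ip_total == 0 or input_total == 0:
        raise PeakDedupError("zero-total library in enrichment_level")
    ip_frac = ip_in_peaks / ip_total
    if input_in_peaks == 0:
        return float("inf")
    return ip_frac / (input_in_peaks / input_total)


def _group_sizes(n: int, k: int) -> List[int]:
    base, rem = divmod(n, k)
    return [base + 1 if i < rem else base for i in range(k)]


def confidence_groups(
    peaks: pd.DataFrame,
    tallies: Dict[DupKey, PositionTally],
    k: int = 10,
    score_col: str = "p_value",
    input_tallies: Optional[Dict[DupKey, PositionTally]] = None,
    input_n_uniq: Optional[int] = None,
) -> List[GroupProfile]:
    """Split peaks into ``k`` confidence groups and profile duplicates per group.

    Peaks are stably sorted by ``score_col`` ascending (ties broken by
    coordinate); group 1 holds the smallest scores.  The remainder when
    ``n % k != 0`` goes to the earliest groups.  Per-group duplicate rate is
    relative to the library's uniquely mapped reads.  With matched input
    tallies, the identical peak coordinates are profiled in the input.
    """
    if score_col not in peaks.columns:
        raise PeakDedupError(f"peaks lack a {score_col!r} column")
    missing = peaks[peaks[score_col].isna()]
    if len(missing):
        names = missing.get("name", missing.index).astype(str).tolist()[:5]
        raise PeakDedupError(f"{len(missing)} peaks missing {score_col}: {names}")
    n_uniq, _, n_dup_lib = library_totals(tallies)
    ordered = peaks.sort_values(
        [score_col, "chrom", "start"], kind="stable", ignore_index=True
    )
    counts = count_regions(ordered, tallies, region_id_col="name")
    in_counts = None
    if input_tallies is not None:
        in_counts = count_regions(ordered, input_tallies, region_id_col="name")
        if input_n_uniq is None:
            input_n_uniq, _, _ = library_totals(input_tallies)
    sizes = _group_sizes(len(ordered), k)
    profiles = []
    lo = 0
    for gi, size in enumerate(sizes, start=1):
        hi = lo + size
        sl = counts.iloc[lo:hi]
        n_dup = int(sl["n_dup"].sum())
        prof = GroupProfile(
            group_index=gi,
            n_peaks=size,
            n_reads=int(sl["n_total"].sum()),
            n_dup=n_dup,
            dup_rate_in_group=n_dup / n_uniq,
            pct_library_dups_in_group=(n_dup / n_dup_lib) if n_dup_lib else float("nan"),
        )
        if in_counts is not None:
            isl = in_counts.iloc[lo:hi]
            in_dup = int(isl["n_dup"].sum())
            in_dup_lib = library_totals(input_tallies)[2]
            prof.matched_input_dup_rate = in_dup / input_n_uniq
            prof.matched_input_pct = (in_dup / in_dup_lib) if in_dup_lib else float("nan")
        profiles.append(prof)
        lo = hi
    return profiles


def top_positions(
    tallies: Dict[DupKey, PositionTally],
    n: int,
    peaks: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Top-``n`` keys by duplicate count (ties by chrom, pos, strand).

    With peaks given, each position is labelled in-peak and a summary of the
    in-peak fraction and distinct peaks hit is attached as ``df.attrs``.
    """
    rows = [
        (k[0], k[1], k[2] if len(k) == 3 else k[2], t.duplicates)
        for k, t in tallies.items()
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "duplicates"])
    df = df.sort_values(
        ["duplicates", "chrom", "pos", "strand"],
        ascending=[False, True, True, True],
        kind="stable",
        ignore_index=True,
    )
    if n > len(df):
        import logging

        logging.getLogger(__name__).info(
            "requested top %d positions but only %d exist", n, len(df)
        )
        n = len(df)
    df = df.head(n).copy()
    if peaks is not None:
        merged = merge_intervals(peaks).sort_values(["chrom", "start"])
        labels = []
        hits = set()
        by_chrom = {
            c: (s["start"].to_numpy(), s["end"].to_numpy(), s.index.to_numpy())
            for c, s in merged.groupby("chrom")
        }
        for chrom, pos in zip(df["chrom"], df["pos"]):
            lab = False
            if chrom in by_chrom:
                starts, ends, idx = by_chrom[chrom]
                i = np.searchsorted(starts, pos, side="right") - 1
                if i >= 0 and pos < ends[i]:
                    lab = True
                    hits.add((chrom, int(starts[i])))
            labels.append(lab)
        df["in_peak"] = labels
        df.attrs["fraction_in_peaks"] = float(np.mean(labels)) if len(df) else float("nan")
        df.attrs["n_peaks_hit"] = len(hits)
    return df


def pearson_fisher_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    r, _ = stats.pearsonr(x, y)
    n = len(x)
    if n < 4 or abs(r) >= 1.0:
        return r, float("nan"), float("nan")
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return r, float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def replicate_correlation(
    dup_counts: Sequence[Sequence[float]],
    lengths_bp: Sequence[float],
    library_sizes: Sequence[float],
    log2_offset: float = 1.0,
) -> Tuple[float, float, float]:
    """Pearson r (with Fisher-z 95% CI) of log2 duplicate RPK10M between two
    replicates over merged peaks.

    ``dup_counts`` is a pair of per-peak duplicate counts; ``library_sizes``
    the two uniquely-mapped totals.
    """
    a, b = (np.asarray(c, dtype=float) for c in dup_counts)
    L = np.asarray(lengths_bp, dtype=float)
    if len(a) < 3:
        raise PeakDedupError("need >= 3 merged peaks for replicate correlation")
    xa = np.log2(a / (L / 1e3) / (library_sizes[0] / 1e7) + log2_offset)
    xb = np.log2(b / (L / 1e3) / (library_sizes[1] / 1e7) + log2_offset)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise PeakDedupError("zero variance in replicate duplicate levels")
    return pearson_fisher_ci(xa, xb)


FEATURE_COLUMNS = [
    "nondup_level",
    "input_dup_level",
    "input_nondup_level",
    "gc",
    "pct_segdup",
    "pct_lowcomplex",
]


def feature_correlations(
    peak_table: pd.DataFrame, dup_col: str = "dup_level"
) -> Dict[str, float]:
    """Spearman rho of per-peak duplicate level against each of six features.

    Levels are raw per-kb values (no library-size normalisation).  Constant
    columns yield NaN.
    """
    out = {}
    y = peak_table[dup_col].to_numpy(dtype=float)
    for col in FEATURE_COLUMNS:
        if col not in peak_table.columns:
            raise PeakDedupError(f"peak table lacks feature column {col!r}")
        x = peak_table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[col] = float("nan")
            continue
        rho, _ = stats.spearmanr(y, x)
        out[col] = float(rho)
    return out


def mean_dups_per_position(
    tallies: Dict[DupKey, PositionTally],
    blacklist: Optional[RegionSet] = None,
) -> float:
    """Average duplicates per occupied position, excluding blacklisted keys."""
    tot_dup = 0
    n_pos = 0
    for key, t in tallies.items():
        chrom, pos = key_point(key)
        if blacklist is not None and blacklist.contains_point(chrom, pos):
            continue
        tot_dup += t.duplicates
        n_pos += 1
    if n_pos == 0:
        raise PeakDedupError("no positions left after blacklist exclusion")
    return tot_dup / n_pos


def partition_accounting(
    tallies: Dict[DupKey, PositionTally],
    kept_peaks: pd.DataFrame,
    removed_peaks: pd.DataFrame,
    chrom_sizes: Dict[str, int],
    buffer_bp: int = 100,
) -> Dict[str, int]:
    """Duplicate counts over a disjoint partition of the genome.

    Every key is assigned by precedence kept peak > blacklist-removed peak >
    buffer strip > non-peak, so the four counts sum exactly to the library's
    duplicates.
    """
    from .regions import nonpeak_complement  # local to avoid cycle

    kept = merge_intervals(kept_peaks)
    removed = merge_intervals(removed_peaks) if len(removed_peaks) else removed_peaks
    out = {"peaks": 0, "removed_peaks": 0, "buffer": 0, "nonpeak": 0}
    all_peaks = pd.concat(
        [kept_peaks[["chrom", "start", "end"]], removed_peaks[["chrom", "start", "end"]]],
        ignore_index=True,
    ) if len(removed_peaks) else kept_peaks[["chrom", "start", "end"]]
    nonpeak = nonpeak_complement(all_peaks, chrom_sizes, buffer_bp)

    kept_set = RegionSet("peaks", kept, chrom_sizes)
    removed_set = RegionSet("removed", removed, chrom_sizes) if len(removed_peaks) else None
    for key, t in tallies.items():
        chrom, pos = key_point(key)
        if kept_set.contains_point(chrom, pos):
            out["peaks"] += t.duplicates
        elif removed_set is not None and removed_set.contains_point(chrom, pos):
            out["removed_peaks"] += t.duplicates
        elif nonpeak.contains_point(chrom, pos):
            out["nonpeak"] += t.duplicates
        else:
            out["buffer"] += t.duplicates
    return out
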