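"""Produce the properly deduplicated alignment file.

The output keeps every nonredundant read everywhere, keeps the predicted
signal duplicates inside peaks (chosen by removing a uniform random sample
of N noise read ids from each peak's capped duplicate pool), and removes
all other duplicates: non-peak duplicates, blacklist-peak duplicates and
in-peak duplicates beyond the per-position cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import pysam

from .alignment_io import DUPLICATE, DupKey, PositionTally
from .dup_metrics import assign_keys
from .errors import PeakDedupError


@dataclass
class RewritePlan:
    """Per-peak keep/drop decision for duplicate read ids."""

    keep_ids: Dict[str, Set[str]] = field(default_factory=dict)  # peak_id -> ids
    drop_ids: Dict[str, Set[str]] = field(default_factory=dict)
    seed: int = 0

    def all_kept(self) -> Set[str]:
        out: Set[str] = set()
        for ids in self.keep_ids.values():
            out |= ids
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for peak_id in sorted(set(self.keep_ids) | set(self.drop_ids)):
            for rid in sorted(self.keep_ids.get(peak_id, ())):
                rows.append((peak_id, rid, "keep"))
            for rid in sorted(self.drop_ids.get(peak_id, ())):
                rows.append((peak_id, rid, "drop"))
        return pd.DataFrame(rows, columns=["peak_id", "read_id", "fate"])


def select_noise_reads(
    dup_ids: Sequence[str], n_noise: int, rng: np.random.Generator
) -> List[str]:
    """Uniform sample (without replacement) of read ids to drop as noise.

    Ids are sorted before sampling so the selection depends only on the id
    set and the generator state, not on input order.
    """
    ids = sorted(dup_ids)
    if n_noise > len(ids):
        raise PeakDedupError(
            f"asked to drop {n_noise} noise reads from a pool of {len(ids)}"
        )
    if n_noise == 0:
        return []
    picked = rng.choice(len(ids), size=n_noise, replace=False)
    return [ids[i] for i in sorted(picked)]


def build_rewrite_plan(
    peaks: pd.DataFrame,
    tallies: Dict[DupKey, PositionTally],
    flags: Dict[str, str],
    key_read_ids: Dict[DupKey, List[str]],
    partition: pd.DataFrame,
    cap: int = 5,
    seed: int = 0,
) -> RewritePlan:
    """Combine the partition's per-peak N with the duplicate pools.

    ``key_read_ids`` maps each duplicate key to all read ids at that key.
    Reads beyond the per-position cap are dropped as noise before sampling;
    sampling applies to the capped pool only.
    """
    rng = np.random.default_rng(seed)
    assignment = assign_keys(tallies, peaks)
    peak_ids = (
        peaks["name"].astype(str).tolist()
        if "name" in peaks.columns
        else [f"peak_{i}" for i in range(len(peaks))]
    )
    pools: Dict[str, List[str]] = {p: [] for p in peak_ids}
    overcap: Dict[str, List[str]] = {p: [] for p in peak_ids}
    for key, row in assignment.items():
        if row is None:
            continue
        pid = peak_ids[row]
        t = tallies[key]
        dups = sorted(r for r in key_read_ids[key] if r != t.representative_read_id)
        pools[pid].extend(dups[:cap])
        overcap[pid].extend(dups[cap:])
    n_by_peak = dict(zip(partition["peak_id"].astype(str), partition["N"].astype(int)))
    plan = RewritePlan(seed=seed)
    for pid in peak_ids:
        pool = pools[pid]
        n_noise = n_by_peak.get(pid, 0)
        dropped = set(select_noise_reads(pool, n_noise, rng)) | set(overcap[pid])
        plan.drop_ids[pid] = dropped
        plan.keep_ids[pid] = set(pool) - dropped
    return plan


def collect_key_read_ids(
    records, mode: str = "single"
) -> Dict[DupKey, List[str]]:
    """Map each duplicate key to the read ids observed at it."""
    from .alignment_io import dup_key

    out: Dict[DupKey, List[str]] = {}
    if mode == "single":
        for rec in records:
            out.setdefault(dup_key(rec), []).append(rec.query_name)
    else:
        pending = {}
        for rec in records:
            if rec.query_name in pending:
                first = pending.pop(rec.query_name)
                out.setdefault(dup_key(first, rec), []).append(rec.query_name)
            else:
                pending[rec.query_name] = rec
        if pending:
            raise PeakDedupError(f"{len(pending)} unpaired records")
    return out


def write_deduplicated(
    marked_path: str,
    out_path: str,
    plan: RewritePlan,
    flags: Dict[str, str],
    cap: int = 5,
    span: float = 2.0 / 3.0,
) -> Tuple[int, int]:
    """Write the properly deduplicated SAM/BAM.

    Keeps all nonredundant reads plus the plan's kept signal duplicates;
    every other duplicate is removed.  Returns (records written, records
    read).  A program-group header line records cap, span and seed.
    """
    kept_dups = plan.all_kept()
    known_dups = kept_dups | {r for ids in plan.drop_ids.values() for r in ids}
    missing = known_dups - set(flags)
    if missing:
        raise PeakDedupError(
            f"{len(missing)} plan read ids absent from the marked alignments "
            f"(e.g. {sorted(missing)[:3]})"
        )
    n_in = n_out = 0
    with pysam.AlignmentFile(marked_path) as fh:
        header = fh.header.to_dict()
        header.setdefault("PG", []).append(
            {
                "ID": "peakdedup",
                "PN": "peakdedup",
                "CL": f"dedup cap={cap} span={span:.4f} seed={plan.seed} rng=numpy-PCG64",
            }
        )
        write_mode = "wb" if out_path.endswith(".bam") else "w"
        with pysam.AlignmentFile(out_path, write_mode, header=header) as out:
            for rec in fh:
                n_in += 1
                fate = flags.get(rec.query_name)
                if fate is None:
                    continue  # filtered out before marking
                if fate == DUPLICATE and rec.query_name not in kept_dups:
                    continue
                rec.is_duplicate = False
                out.write(rec)
                n_out += 1
    if out_path.endswith(".bam"):
        pysam.index(out_path)
    return n_out, n_in


def peak_dup_table(
    partition: pd.DataFrame,
) -> pd.DataFrame:
    """Per-peak table of nonredundant reads, signal and noise duplicates."""
    out = partition[["peak_id"]].copy()
    if "n_nondup" in partition.columns:
        out["nonredundant"] = partition["n_nondup"].astype(int)
    elif {"nondup_per_kb", "length_kb"} <= set(partition.columns):
        out["nonredundant"] = (
            (partition["nondup_per_kb"] * partition["length_kb"]).round().astype(int)
        )
    out["signal_duplicates"] = partition["S"].astype(int)
    out["noise_duplicates"] = partition["N"].astype(int)
    return out
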