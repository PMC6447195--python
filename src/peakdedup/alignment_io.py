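"""Alignment filtering and duplicate marking.

A *duplicate* is a uniquely mapped read whose strand-aware 5' mapping
coordinate coincides with that of another read; for read pairs, both ends
must coincide.  The 5' coordinate is the *unclipped* position (soft- and
hard-clipped bases restored), so identical fragments that differ only in
clipping collide on the same key.  Per key holding ``n`` reads, ``n - 1``
are duplicates; the remaining representative is *nonredundant*.

Reads enter duplicate marking only after passing the uniqueness filters:
a minimum mapping quality and no mismatch within the first few sequenced
bases (read 5' end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple, Union

import pysam

from .errors import MissingEvidenceError, PeakDedupError, UnsortedInputError

NONREDUNDANT = "nonredundant"
DUPLICATE = "duplicate"

#: single-end key: (chrom, unclipped 5' position, strand)
#: paired key: (chrom, pos1, strand1, pos2, strand2), ends ordered by coordinate
DupKey = Union[Tuple[str, int, str], Tuple[str, int, str, int, str]]


@dataclass
class PositionTally:
    """Read count at one duplicate key; ``duplicates = n_reads - 1``."""

    key: DupKey
    n_reads: int
    representative_read_id: str

    @property
    def duplicates(self) -> int:
        return self.n_reads - 1


def unclipped_start(rec: pysam.AlignedSegment) -> int:
    """Leftmost reference position with leading soft/hard clips restored."""
    clip = 0
    for op, length in rec.cigartuples or ():
        if op in (4, 5):  # S, H
            clip += length
        else:
            break
    return rec.reference_start - clip


def unclipped_end(rec: pysam.AlignedSegment) -> int:
    """Rightmost aligned base (0-based, inclusive) with trailing clips restored."""
    clip = 0
    for op, length in reversed(rec.cigartuples or ()):
        if op in (4, 5):
            clip += length
        else:
            break
    return rec.reference_end - 1 + clip


def five_prime_pos(rec: pysam.AlignedSegment) -> int:
    """Unclipped 5' coordinate of a record (rightmost base for reverse strand)."""
    return unclipped_end(rec) if rec.is_reverse else unclipped_start(rec)


def _mismatch_query_positions(rec: pysam.AlignedSegment) -> List[int]:
    """Query positions (SEQ orientation) of substitution mismatches, from MD."""
    out = []
    for qpos, _rpos, ref_base in rec.get_aligned_pairs(matches_only=True, with_seq=True):
        if ref_base is not None and ref_base.islower():
            out.append(qpos)
    return out


def passes_filters(
    rec: pysam.AlignedSegment,
    min_mapq: int = 20,
    check_first_n: int = 5,
    strict: bool = True,
) -> bool:
    """Uniqueness filter: MAPQ and a clean read 5' end.

    The first ``check_first_n`` *sequenced* bases are checked for
    substitution mismatches.  For reverse-strand records SEQ is stored in
    reference orientation, so the sequenced 5' end corresponds to the last
    SEQ positions.  Mismatch evidence comes from the MD tag; without MD,
    strict mode raises and non-strict mode falls back to requiring an edit
    distance (NM) of zero.

    Secondary, supplementary and unmapped records never pass.
    """
    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
        return False
    if rec.mapping_quality < min_mapq:
        return False
    if check_first_n <= 0:
        return True
    if not rec.has_tag("MD"):
        if strict:
            raise MissingEvidenceError(
                f"record {rec.query_name!r} lacks an MD tag; cannot test the "
                f"first {check_first_n} sequenced bases (pass strict=False to "
                "fall back to NM == 0)"
            )
        if rec.has_tag("NM"):
            return rec.get_tag("NM") == 0
        raise MissingEvidenceError(
            f"record {rec.query_name!r} has neither MD nor NM tag"
        )
    mism = _mismatch_query_positions(rec)
    if not mism:
        return True
    qlen = rec.query_length or rec.infer_query_length() or 0
    if rec.is_reverse:
        first = set(range(qlen - check_first_n, qlen))
    else:
        first = set(range(check_first_n))
    return not any(q in first for q in mism)


def dup_key(
    rec: pysam.AlignedSegment,
    mate: Optional[pysam.AlignedSegment] = None,
) -> DupKey:
    """Strand-aware unclipped-5' duplicate key for a read or a pair.

    With ``mate`` given, the two ends are ordered canonically (smaller
    coordinate first) so the key does not depend on which end is seen first.
    """
    if rec.is_unmapped:
        raise PeakDedupError(f"record {rec.query_name!r} is unmapped")
    strand = "-" if rec.is_reverse else "+"
    single = (rec.reference_name, five_prime_pos(rec), strand)
    if mate is None:
        return single
    if mate.is_unmapped:
        raise PeakDedupError(f"mate of {rec.query_name!r} is unmapped")
    mstrand = "-" if mate.is_reverse else "+"
    other = (mate.reference_name, five_prime_pos(mate), mstrand)
    if single[0] != other[0]:
        # keep deterministic chromosome-then-position ordering across chroms
        ends = sorted([single, other])
    else:
        ends = sorted([single, other], key=lambda e: (e[1], e[2]))
    return (ends[0][0], ends[0][1], ends[0][2], ends[1][1], ends[1][2])


def _check_sorted(prev, rec) -> Tuple[int, int]:
    cur = (rec.reference_id, rec.reference_start)
    if prev is not None and cur[0] == prev[0] and cur[1] < prev[1]:
        raise UnsortedInputError(
            f"input not coordinate-sorted: record {rec.query_name!r} at "
            f"{rec.reference_name}:{rec.reference_start} follows position {prev[1]}"
        )
    return cur


def mark_duplicates(
    records: Iterable[pysam.AlignedSegment],
    mode: str = "single",
) -> Tuple[Dict[DupKey, PositionTally], Dict[str, str]]:
    """Group filtered records by duplicate key and flag one representative each.

    Returns ``(tallies, flags)`` where ``flags`` maps read id (query name;
    pair-level in paired mode) to ``"nonredundant"`` or ``"duplicate"``.
    The representative of a key is the first read id in ``(coordinate,
    read_id)`` order, which makes marking deterministic under shuffling of
    equally placed records.  Input must be coordinate-sorted.
    """
    if mode not in ("single", "paired"):
        raise PeakDedupError(f"unknown mode {mode!r}")
    groups: Dict[DupKey, List[str]] = {}
    prev = None
    if mode == "single":
        for rec in records:
            prev = _check_sorted(prev, rec)
            groups.setdefault(dup_key(rec), []).append(rec.query_name)
    else:
        pending: Dict[str, pysam.AlignedSegment] = {}
        for rec in records:
            prev = _check_sorted(prev, rec)
            name = rec.query_name
            if name in pending:
                first = pending.pop(name)
                groups.setdefault(dup_key(first, rec), []).append(name)
            else:
                pending[name] = rec
        if pending:
            missing = sorted(pending)[:3]
            raise PeakDedupError(
                f"{len(pending)} paired records without a mate (e.g. {missing})"
            )
    tallies: Dict[DupKey, PositionTally] = {}
    flags: Dict[str, str] = {}
    for key, ids in groups.items():
        rep = min(ids)
        tallies[key] = PositionTally(key=key, n_reads=len(ids), representative_read_id=rep)
        for rid in ids:
            flags[rid] = NONREDUNDANT if rid == rep else DUPLICATE
    return tallies, flags


def iter_filtered(
    aln: Union[str, pysam.AlignmentFile],
    min_mapq: int = 20,
    check_first_n: int = 5,
    strict: bool = True,
) -> Iterator[pysam.AlignedSegment]:
    """Yield primary mapped records passing :func:`passes_filters` from a SAM/BAM."""
    own = isinstance(aln, str)
    fh = pysam.AlignmentFile(aln) if own else aln
    try:
        for rec in fh:
            if passes_filters(rec, min_mapq=min_mapq, check_first_n=check_first_n, strict=strict):
                yield rec
    finally:
        if own:
            fh.close()


def mark_bam(
    in_path: str,
    out_path: Optional[str] = None,
    mode: str = "single",
    min_mapq: int = 20,
    check_first_n: int = 5,
    strict: bool = True,
) -> Tuple[Dict[DupKey, PositionTally], Dict[str, str]]:
    """Filter + mark a coordinate-sorted SAM/BAM; optionally write a flagged copy.

    The output (SAM or BAM by extension) contains only reads that passed the
    filters, with the standard duplicate FLAG bit (0x400) set on duplicates.
    Read ids are assumed unique per template (one record per read in
    single-end data); both ends of a pair share the pair's fate.
    """
    with pysam.AlignmentFile(in_path) as fh:
        records = [
            rec
            for rec in fh
            if passes_filters(rec, min_mapq=min_mapq, check_first_n=check_first_n, strict=strict)
        ]
        header = fh.header.to_dict()
    tallies, flags = mark_duplicates(iter(records), mode=mode)
    if out_path is not None:
        write_mode = "wb" if out_path.endswith(".bam") else "w"
        with pysam.AlignmentFile(out_path, write_mode, header=header) as out:
            for rec in records:
                rec.is_duplicate = flags[rec.query_name] == DUPLICATE
                out.write(rec)
        if out_path.endswith(".bam"):
            pysam.index(out_path)
    return tallies, flags


def tallies_to_frame(tallies: Dict[DupKey, PositionTally]):
    """Flatten tallies into a DataFrame (single-end keys only).

    Columns: chrom, pos, strand, n_reads, duplicates, representative.
    """
    import pandas as pd

    rows = []
    for key, t in tallies.items():
        if len(key) != 3:
            raise PeakDedupError("tallies_to_frame expects single-end keys")
        rows.append((key[0], key[1], key[2], t.n_reads, t.duplicates, t.representative_read_id))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "n_reads", "duplicates", "representative"]
    ).sort_values(["chrom", "pos", "strand"], ignore_index=True)
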