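import numpy as np
import pandas as pd
import pysam
import pytest

TOY_HEADER = pysam.AlignmentHeader.from_dict(
    {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chr1", "LN": 1_000_000}, {"SN": "chr2", "LN": 500_000}],
    }
)


def make_rec(
    name,
    chrom="chr1",
    pos=100,
    cigar="50M",
    reverse=False,
    mapq=60,
    nm=0,
    md=None,
    header=TOY_HEADER,
    flag_extra=0,
    seq_len=None,
):
    """Build an in-memory single-end alignment record."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = header.references.index(chrom)
    rec.flag = (16 if reverse else 0) | flag_extra
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigarstring = cigar
    qlen = seq_len or sum(l for op, l in rec.cigartuples if op in (0, 1, 4))
    rec.query_sequence = "A" * qlen
    rec.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    rec.set_tag("NM", nm)
    if md is not None:
        rec.set_tag("MD", md)
    elif nm == 0:
        aligned = sum(l for op, l in rec.cigartuples if op == 0)
        rec.set_tag("MD", str(aligned))
    return rec


@pytest.fixture(scope="session")
def toy_header():
    return TOY_HEADER


@pytest.fixture(scope="session")
def sim_library():
    """One moderately sized simulated library shared across tests."""
    from peakdedup.simdata import SimConfig, simulate_library

    cfg = SimConfig(seed=11, n_templates=20_000, n_peaks=30, pcr_rate=0.4)
    return simulate_library(cfg)


def random_single_end_records(rng, n_reads, n_positions, header=TOY_HEADER):
    """Random colliding single-end records (sorted), for oracle comparisons."""
    chroms = ["chr1", "chr2"]
    posset = [
        (chroms[int(rng.integers(0, 2))], int(rng.integers(200, 5000)))
        for _ in range(n_positions)
    ]
    recs = []
    for i in range(n_reads):
        chrom, key = posset[int(rng.integers(0, n_positions))]
        reverse = bool(rng.integers(0, 2))
        clip = int(rng.integers(0, 4))
        body = 50 - clip
        if not reverse:
            # leading soft clip shifts reference_start right of the key
            cigar = f"{clip}S{body}M" if clip else f"{body}M"
            pos = key + clip
        else:
            # trailing soft clip: unclipped 3' extends past the aligned end
            cigar = f"{body}M{clip}S" if clip else f"{body}M"
            pos = key - body + 1 - clip
        recs.append(
            make_rec(f"rd{i:05d}", chrom, pos, cigar, reverse=reverse, header=header)
        )
    recs.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    return recs


def oracle_flags_single(records):
    """Brute-force duplicate flags: group by (chrom, unclipped 5', strand).

    Independent of the package: parses CIGAR text directly.
    """
    import re

    groups = {}
    for rec in records:
        ops = re.findall(r"(\d+)([MIDNSHP=X])", rec.cigarstring)
        lead = 0
        for n, op in ops:
            if op in "SH":
                lead += int(n)
            else:
                break
        trail = 0
        for n, op in reversed(ops):
            if op in "SH":
                trail += int(n)
            else:
                break
        ref_span = sum(int(n) for n, op in ops if op in "MDN=X")
        if rec.is_reverse:
            key = (rec.reference_name, rec.reference_start + ref_span - 1 + trail, "-")
        else:
            key = (rec.reference_name, rec.reference_start - lead, "+")
        groups.setdefault(key, []).append(rec.query_name)
    flags = {}
    for ids in groups.values():
        rep = min(ids)
        for rid in ids:
            flags[rid] = "nonredundant" if rid == rep else "duplicate"
    return flags, groups
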