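import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peakdedup.alignment_io import PositionTally, mark_duplicates
from peakdedup.dup_metrics import (
    confidence_groups,
    count_regions,
    enrichment_level,
    feature_correlations,
    library_metrics,
    library_totals,
    mean_dups_per_position,
    partition_accounting,
    replicate_correlation,
    rpk10m,
    top_positions,
)
from peakdedup.errors import PeakDedupError
from peakdedup.regions import RegionSet

from conftest import random_single_end_records


def tally(chrom, pos, strand, n):
    key = (chrom, pos, strand)
    return key, PositionTally(key=key, n_reads=n, representative_read_id=f"{chrom}:{pos}{strand}")


def tallies_from(spec):
    return dict(tally(*s) for s in spec)


def regions_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"r{i}" for i in range(len(df))]
    return df


class TestCountRegions:
    def test_empty_region_zero(self):
        out = count_regions(regions_frame([("chr1", 0, 100)]), {})
        assert out[["n_total", "n_dup", "n_positions"]].sum().sum() == 0

    def test_single_key_counts(self):
        t = tallies_from([("chr1", 50, "+", 4)])
        out = count_regions(regions_frame([("chr1", 0, 100)]), t)
        assert out.loc[0, ["n_total", "n_nondup", "n_dup", "n_positions_with_dup"]].tolist() == [4, 1, 3, 1]

    def test_matches_membership_oracle(self):
        rng = np.random.default_rng(12)
        recs = random_single_end_records(rng, n_reads=500, n_positions=120)
        tallies, _ = mark_duplicates(iter(recs))
        edges = np.sort(rng.integers(0, 6000, 40))
        rows = [
            ("chr1", int(edges[i]), int(edges[i + 1]))
            for i in range(0, 38, 2)
            if edges[i] < edges[i + 1]
        ]
        regs = regions_frame(rows)
        out = count_regions(regs, tallies)
        for _, row in out.iterrows():
            keys = [
                k for k in tallies
                if k[0] == row["chrom"] and row["start"] <= k[1] < row["end"]
            ]
            assert row["n_positions"] == len(keys)
            assert row["n_total"] == sum(tallies[k].n_reads for k in keys)


class TestLibraryMetrics:
    def test_basic_rates(self):
        # 800 keys, 200 of them with one extra read -> 1000 reads
        spec = [("chr1", 10 + 2 * i, "+", 2 if i < 200 else 1) for i in range(800)]
        t = tallies_from(spec)
        peaks = regions_frame([("chr1", 0, 2000)])
        qc = library_metrics(t, peaks, {"chr1": 1_000_000})
        assert qc.n_uniq == 1000
        assert qc.dup_rate == pytest.approx(0.20)
        assert qc.nrf == pytest.approx(0.80)

    def test_frip_one_when_all_reads_in_peaks(self):
        t = tallies_from([("chr1", 100, "+", 3), ("chr1", 150, "-", 1)])
        qc = library_metrics(t, regions_frame([("chr1", 0, 1000)]), {"chr1": 10_000})
        assert qc.frip == 1.0 and qc.pct_dups_in_peaks == 1.0

    def test_zero_read_library_raises(self):
        with pytest.raises(PeakDedupError):
            library_metrics({}, regions_frame([("chr1", 0, 10)]), {"chr1": 100})

    def test_matches_simulator_bookkeeping(self, sim_library):
        tallies, flags = mark_duplicates(iter(sim_library.records))
        qc = library_metrics(tallies, sim_library.peaks, sim_library.config.chrom_sizes)
        assert qc.n_uniq == len(sim_library.truth)
        n_dup_truth = len(sim_library.truth) - len(tallies)
        assert qc.dup_rate == pytest.approx(n_dup_truth / len(sim_library.truth))


class TestRpk10m:
    def test_formula(self):
        assert rpk10m(10, 500, 20_000_000) == pytest.approx(10.0)
        assert rpk10m(0, 500, 20_000_000) == 0.0

    def test_linearity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            c = rng.uniform(1, 1e4)
            L = rng.uniform(100, 1e5)
            n = rng.uniform(1e5, 1e8)
            assert rpk10m(c, L, n) == pytest.approx(c / (L / 1e3) / (n / 1e7))
            assert rpk10m(2 * c, L, n) == pytest.approx(2 * rpk10m(c, L, n))
            assert rpk10m(c, 2 * L, n) == pytest.approx(rpk10m(c, L, n) / 2)


class TestEnrichment:
    def test_tenfold(self):
        assert enrichment_level(10, 100, 1, 100) == pytest.approx(10.0)

    def test_identity(self):
        assert enrichment_level(37, 500, 37, 500) == 1.0

    def test_zero_input_overlap_gives_inf(self):
        assert enrichment_level(10, 100, 0, 100) == float("inf")

    def test_increases_with_simulated_peak_intensity(self):
        from peakdedup.simdata import SimConfig, simulate_library

        ratios = []
        for frac in (0.3, 0.6, 0.9):
            cfg = SimConfig(seed=21, n_templates=8000, n_peaks=20, peak_template_fraction=frac)
            res = simulate_library(cfg)
            tallies, _ = mark_duplicates(iter(res.records))
            counts = count_regions(res.peaks, tallies)
            ip_in = int(counts["n_nondup"].sum())
            _, n_pos, _ = library_totals(tallies)
            # uniform input: expected in-peak share = peak bases / genome
            peak_bases = int((res.peaks["end"] - res.peaks["start"]).sum())
            genome = sum(cfg.chrom_sizes.values())
            ratios.append((ip_in / n_pos) / (peak_bases / genome))
        assert ratios[0] < ratios[1] < ratios[2]


class TestConfidenceGroups:
    def make_peaks(self, n, spacing=1000, length=200):
        df = regions_frame([("chr1", i * spacing, i * spacing + length) for i in range(n)])
        df["p_value"] = np.linspace(1e-9, 0.9, n)
        return df

    def test_one_peak_per_group(self):
        peaks = self.make_peaks(10)
        t = tallies_from([("chr1", i * 1000 + 50, "+", 1 + i) for i in range(10)])
        profs = confidence_groups(peaks, t, k=10)
        assert [p.n_peaks for p in profs] == [1] * 10
        assert profs[0].n_dup == 0  # smallest p -> first peak -> 1 read

    def test_remainder_goes_to_earliest_groups(self):
        peaks = self.make_peaks(23)
        t = tallies_from([("chr1", 50, "+", 1)])
        profs = confidence_groups(peaks, t, k=10)
        assert [p.n_peaks for p in profs] == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_missing_scores_raise(self):
        peaks = self.make_peaks(5).drop(columns=["p_value"])
        with pytest.raises(PeakDedupError):
            confidence_groups(peaks, {}, k=5)

    def test_group_duplicates_reconstitute_peak_total(self):
        rng = np.random.default_rng(8)
        peaks = self.make_peaks(37)
        spec = [
            ("chr1", int(rng.integers(0, 37) * 1000 + rng.integers(0, 200)), "+", int(rng.integers(1, 6)))
            for _ in range(300)
        ]
        t = {}
        for s in spec:
            k, v = tally(*s)
            t[k] = v
        profs = confidence_groups(peaks, t, k=10)
        total_in_groups = sum(p.n_dup for p in profs)
        in_peaks = count_regions(peaks, t)["n_dup"].sum()
        assert total_in_groups == in_peaks

    def test_most_confident_group_has_max_dup_rate_in_simulation(self):
        # PCR-free: duplicates are pure collisions, so the most intense
        # (most confident) peaks must carry the highest duplicate rate
        from peakdedup.simdata import SimConfig, simulate_library

        res = simulate_library(SimConfig(seed=22, n_templates=20_000, n_peaks=30))
        tallies, _ = mark_duplicates(iter(res.records))
        profs = confidence_groups(res.peaks, tallies, k=10)
        rates = [p.dup_rate_in_group for p in profs]
        assert rates[0] == max(rates)


class TestTopPositions:
    def test_tie_breaking_by_coordinate(self):
        t = tallies_from(
            [("chr1", 500, "+", 6), ("chr1", 300, "+", 4), ("chr1", 200, "+", 4), ("chr1", 900, "+", 2)]
        )
        out = top_positions(t, 2)
        assert out["pos"].tolist() == [500, 200]

    def test_equal_counts_pure_coordinate_order(self):
        t = tallies_from([("chr1", p, "+", 3) for p in (700, 100, 400)])
        out = top_positions(t, 3)
        assert out["pos"].tolist() == [100, 400, 700]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(6)
        t = tallies_from(
            [("chr1", int(p), "+", int(n)) for p, n in
             zip(rng.choice(10_000, 200, replace=False), rng.integers(1, 20, 200))]
        )
        out = top_positions(t, 50)
        oracle = sorted(
            ((k[1], v.duplicates) for k, v in t.items()),
            key=lambda x: (-x[1], x[0]),
        )[:50]
        assert list(zip(out["pos"], out["duplicates"])) == oracle

    def test_n_larger_than_positions_returns_all(self):
        t = tallies_from([("chr1", 1, "+", 2)])
        assert len(top_positions(t, 10)) == 1

    def test_peak_labelling(self):
        t = tallies_from([("chr1", 50, "+", 5), ("chr1", 500, "+", 5)])
        peaks = regions_frame([("chr1", 0, 100)])
        out = top_positions(t, 2, peaks)
        assert out["in_peak"].tolist() == [True, False]
        assert out.attrs["fraction_in_peaks"] == 0.5
        assert out.attrs["n_peaks_hit"] == 1


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        counts = [[1, 5, 9, 2], [1, 5, 9, 2]]
        r, lo, hi = replicate_correlation(counts, [200, 300, 150, 400], [1e7, 1e7])
        assert r == pytest.approx(1.0)

    def test_anti_ordered_negative(self):
        r, *_ = replicate_correlation([[1, 5, 9], [9, 5, 1]], [200, 200, 200], [1e7, 1e7])
        assert r < 0

    def test_known_rho_bivariate_lognormal(self):
        rng = np.random.default_rng(13)
        rho = 0.8
        cov = [[1, rho], [rho, 1]]
        z = rng.multivariate_normal([3, 3], cov, size=1000)
        counts = np.exp2(z)  # log2 counts correlate at rho
        r, lo, hi = replicate_correlation(
            [counts[:, 0], counts[:, 1]], np.full(1000, 1000.0), [1e7, 1e7], log2_offset=0
        )
        assert lo < rho < hi
        assert r == pytest.approx(rho, abs=0.05)

    def test_too_few_peaks_raise(self):
        with pytest.raises(PeakDedupError):
            replicate_correlation([[1, 2], [2, 1]], [100, 100], [1e7, 1e7])


class TestFeatureCorrelations:
    def make_table(self, rng, n=200):
        df = pd.DataFrame(
            {
                "dup_level": rng.gamma(2, 5, n),
                "nondup_level": rng.gamma(3, 4, n),
                "input_dup_level": rng.gamma(1, 2, n),
                "input_nondup_level": rng.gamma(2, 2, n),
                "gc": rng.uniform(0.3, 0.7, n),
                "pct_segdup": rng.uniform(0, 0.2, n),
                "pct_lowcomplex": rng.uniform(0, 0.1, n),
            }
        )
        return df

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(14)
        df = self.make_table(rng)
        df["nondup_level"] = df["dup_level"]
        assert feature_correlations(df)["nondup_level"] == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        rng = np.random.default_rng(15)
        df = self.make_table(rng)
        df["gc"] = -df["dup_level"]
        assert feature_correlations(df)["gc"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(16)
        df = self.make_table(rng)
        # inject ties to exercise average ranks
        df.loc[:20, "gc"] = 0.5
        out = feature_correlations(df)
        for col, rho in out.items():
            ra = stats.rankdata(df["dup_level"])
            rb = stats.rankdata(df[col])
            oracle = np.corrcoef(ra, rb)[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_column_gives_nan(self):
        rng = np.random.default_rng(17)
        df = self.make_table(rng)
        df["pct_segdup"] = 0.0
        assert np.isnan(feature_correlations(df)["pct_segdup"])


class TestMeanDupsPerPosition:
    def test_hand_example(self):
        t = tallies_from([("chr1", 10, "+", 3), ("chr1", 20, "+", 1), ("chr1", 30, "+", 2)])
        assert mean_dups_per_position(t) == pytest.approx(1.0)

    def test_all_singletons_zero(self):
        t = tallies_from([("chr1", i, "+", 1) for i in range(10)])
        assert mean_dups_per_position(t) == 0.0

    def test_blacklist_exclusion_matches_bruteforce(self):
        rng = np.random.default_rng(18)
        t = tallies_from(
            [("chr1", int(p), "+", int(n)) for p, n in
             zip(rng.choice(5000, 300, replace=False), rng.integers(1, 8, 300))]
        )
        bl = RegionSet.from_frame(
            "blacklist", pd.DataFrame([("chr1", 1000, 2000)], columns=["chrom", "start", "end"])
        )
        got = mean_dups_per_position(t, bl)
        keys = [k for k in t if not (1000 <= k[1] < 2000)]
        expect = sum(t[k].duplicates for k in keys) / len(keys)
        assert got == pytest.approx(expect)


def test_partition_accounting_is_exact(sim_library):
    tallies, _ = mark_duplicates(iter(sim_library.records))
    peaks = sim_library.peaks
    kept = peaks.iloc[: len(peaks) - 3]
    removed = peaks.iloc[len(peaks) - 3 :]
    acct = partition_accounting(tallies, kept, removed, sim_library.config.chrom_sizes)
    _, _, lib_dups = library_totals(tallies)
    assert sum(acct.values()) == lib_dups
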