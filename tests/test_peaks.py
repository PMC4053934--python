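"""Coverage, randomization FDR, significant intervals and contigs.

The FDR implementation is checked against an independent Monte-Carlo
oracle that counts exceedance positions by explicit position expansion
(np.bincount over covered positions), a different route from the
diff-array/cumsum used in the implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parclip import (
    AlignedRead,
    Interval,
    SimulationConfig,
    build_contigs,
    coverage_track,
    height_fdr,
    significant_intervals,
    simulate_reads,
)
from parclip.model import CoverageTrack, Substitution
from parclip.synthetic import truth_to_aligned


def _reads_at(starts, length=20, chrom="chrI", strand="+"):
    return [AlignedRead(chrom, s, s + length, strand) for s in starts]


FEATURE = Interval("chrI", 0, 1000, "+")


def mc_fdr_oracle(read_lengths, feature_len, observed_exceedance, n_iter, seed):
    """Independent randomization oracle; returns (mean count, sd count) per
    height 1..len(observed_exceedance)."""
    rng = np.random.default_rng(seed)
    max_h = len(observed_exceedance)
    lens = np.asarray(read_lengths)
    counts = np.empty((n_iter, max_h), dtype=np.int64)
    offs = [np.arange(l) for l in lens]
    for it in range(n_iter):
        starts = rng.integers(0, feature_len - lens + 1)
        pos = np.concatenate([s + o for s, o in zip(starts, offs)])
        cov = np.bincount(pos, minlength=feature_len)
        for h in range(1, max_h + 1):
            counts[it, h - 1] = int((cov >= h).sum())
    return counts.mean(axis=0), counts.std(axis=0, ddof=1)


class TestCoverageTrack:
    def test_single_read(self):
        track = coverage_track(_reads_at([100], 30), FEATURE)
        assert track.heights.sum() == 30
        assert (track.heights[100:130] == 1).all()
        assert track.heights[99] == 0 and track.heights[130] == 0

    def test_two_overlapping_reads(self):
        track = coverage_track(_reads_at([100, 110], 20), FEATURE)
        assert int((track.heights == 2).sum()) == 10

    def test_mass_conservation_against_interval_arithmetic(self):
        rng = np.random.default_rng(4)
        reads = _reads_at(rng.integers(0, 950, size=40), 25)
        track = coverage_track(reads, FEATURE)
        expect = sum(min(r.end, 1000) - max(r.start, 0) for r in reads)
        assert int(track.heights.sum()) == expect

    def test_strand_mismatch_ignored(self):
        reads = _reads_at([100], strand="-")
        track = coverage_track(reads, FEATURE)
        assert track.heights.sum() == 0


class TestHeightFdr:
    def test_stacked_reads_highly_significant(self):
        reads = _reads_at([500] * 50, 20)
        table = height_fdr(reads, FEATURE, n_iter=100, seed=0)
        assert table.fdr[49] < 0.01  # height 50
        assert table.h_min_at(0.01) is not None and table.h_min_at(0.01) <= 50

    def test_agrees_with_monte_carlo_oracle(self):
        reads = _reads_at([500] * 50, 20)
        table = height_fdr(reads, FEATURE, n_iter=100, seed=1)
        mean, sd = mc_fdr_oracle([20] * 50, 1000, table.observed, n_iter=20_000, seed=99)
        se = sd * np.sqrt(1 / 100 + 1 / 20_000) / table.observed
        oracle_fdr = np.minimum(mean / table.observed, 1.0)
        assert np.all(np.abs(table.fdr_raw - oracle_fdr) <= 3 * se + 1e-12)

    def test_zero_reads_empty_table(self):
        table = height_fdr([], FEATURE, n_iter=10, seed=0)
        assert table.empty
        assert table.h_min_at(0.01) is None

    def test_alpha_one_degenerate(self):
        reads = _reads_at([10], 20)
        table = height_fdr(reads, FEATURE, n_iter=10, seed=0, alpha=1.0)
        assert table.h_min_at(1.0) == 1

    def test_cleaned_fdr_monotone_non_increasing(self):
        rng = np.random.default_rng(5)
        reads = _reads_at(rng.integers(0, 950, size=60), 30)
        table = height_fdr(reads, FEATURE, n_iter=50, seed=2)
        assert np.all(np.diff(table.fdr) <= 1e-12)

    def test_determinism(self):
        reads = _reads_at([500] * 20, 20)
        a = height_fdr(reads, FEATURE, n_iter=50, seed=7)
        b = height_fdr(reads, FEATURE, n_iter=50, seed=7)
        assert np.array_equal(a.fdr, b.fdr)


def test_hmin_trend_with_read_depth():
    """h_min does not decrease as read depth grows (monotone trend averaged
    over seeds, not asserted per seed)."""
    depths = [20, 80, 320]
    means = []
    for n in depths:
        hmins = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            reads = _reads_at(rng.integers(0, 970, size=n), 30)
            table = height_fdr(reads, FEATURE, n_iter=50, seed=seed, alpha=0.05)
            hm = table.h_min_at(0.05)
            hmins.append(hm if hm is not None else table.heights[-1] + 1)
        means.append(np.mean(hmins))
    assert means[0] <= means[1] <= means[2]


class TestSignificantIntervals:
    def test_run_length_example(self):
        track = CoverageTrack("f", "chrI", 0, "+", np.array([0, 2, 2, 1, 3]))
        ivs = significant_intervals(track, 2)
        assert [(iv.start, iv.end) for iv in ivs] == [(1, 3), (4, 5)]

    def test_all_below_threshold(self):
        track = CoverageTrack("f", "chrI", 0, "+", np.array([1, 1, 0]))
        assert significant_intervals(track, 2) == []

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=60), st.integers(1, 5))
    def test_matches_run_length_oracle(self, heights, h_min):
        track = CoverageTrack("f", "chrI", 0, "+", np.array(heights))
        got = [(iv.start, iv.end) for iv in significant_intervals(track, h_min)]
        # oracle: explicit scan
        runs, start = [], None
        for i, h in enumerate(heights + [0]):
            if h >= h_min and start is None:
                start = i
            elif h < h_min and start is not None:
                runs.append((start, i))
                start = None
        assert got == runs
        # maximality: neighbours below threshold, members at or above
        for a, b in got:
            assert all(heights[i] >= h_min for i in range(a, b))
            if a > 0:
                assert heights[a - 1] < h_min
            if b < len(heights):
                assert heights[b] < h_min


class TestBuildContigs:
    GENOME = {"chrI": "ACGT" * 500}

    def test_tc_and_t_counts_direct(self):
        # position 103 is 'T' in the ACGT-repeat genome
        reads = [
            AlignedRead("chrI", 90, 120, "+", (Substitution(103, "T", "C"),)),
            AlignedRead("chrI", 95, 125, "+"),
            AlignedRead("chrI", 100, 130, "+"),
            AlignedRead("chrI", 85, 115, "+"),
        ]
        (contig,) = build_contigs([Interval("chrI", 100, 115, "+")], reads, self.GENOME)
        i = 103 - 100
        assert contig.tc_count[i] == 1
        assert contig.t_coverage[i] == 4
        assert contig.coverage[i] == 4

    def test_non_t_reference_contributes_no_t_coverage(self):
        reads = [AlignedRead("chrI", 100, 130, "+")]
        (contig,) = build_contigs([Interval("chrI", 100, 104, "+")], reads, self.GENOME)
        # genome positions 100..103 are A,C,G,T
        assert list(contig.t_coverage) == [0, 0, 0, 1]

    def test_minus_strand_counts_ag(self):
        reads = [AlignedRead("chrI", 100, 130, "-", (Substitution(104, "A", "G"),))]
        (contig,) = build_contigs([Interval("chrI", 100, 110, "-")], reads, self.GENOME)
        assert contig.tc_count[4] == 1
        # sense-strand T on "-" is genomic A (positions 100, 104, 108)
        assert contig.t_coverage[4] == 1 and contig.t_coverage[0] == 1

    def test_truth_table_tc_counts(self, scenario):
        """Per-position T-C counts equal the simulator's truth table."""
        cfg = SimulationConfig(n_reads=500, error_rate=0.0, duplication_rate=0.0, seed=17)
        _, truth = simulate_reads(scenario.genome, scenario.transcripts, scenario.sites, cfg)
        reads = truth_to_aligned(truth)
        for site in scenario.sites:
            iv = Interval(site.chrom, site.crosslink_position, site.crosslink_position + 1, site.strand)
            (contig,) = build_contigs([iv], reads, scenario.genome)
            expected = sum(
                1
                for t in truth
                if t.strand == site.strand
                and any(s.pos == site.crosslink_position for s in t.substitutions)
            )
            assert contig.tc_count[0] == expected
            assert contig.tc_count[0] <= contig.coverage[0]
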