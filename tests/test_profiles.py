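"""Metagene binning, anchor windows, T-C percentage profiles, k-means."""

import numpy as np
import pytest

from parclip import (
    Interval,
    ProfileConfig,
    TranscriptModel,
    anchor_profile,
    bin_density,
    binding_probability,
    kmeans_rows,
    tc_percentage_profile,
    transcript_anchors,
)
from parclip.model import BinProfile, Contig, MotifHit
from parclip.profiles import _segment_bins


def _mk_transcript(tid="t0", start=0, u5=100, cds=300, u3=100, strand="+", chrom="chrI"):
    if strand == "+":
        return TranscriptModel(tid, chrom, strand,
                               (start, start + u5),
                               (start + u5, start + u5 + cds),
                               (start + u5 + cds, start + u5 + cds + u3))
    return TranscriptModel(tid, chrom, strand,
                           (start + u3 + cds, start + u3 + cds + u5),
                           (start + u3, start + u3 + cds),
                           (start, start + u3))


def _oracle_bin_masses(L, B, offsets):
    """Per-nucleotide loop applying the documented mapping rule."""
    vals = np.zeros(B)
    for o in offsets:
        if L >= B:
            vals[o * B // L] += 1.0
        else:
            bins = [b for b in range(B) if b * L // B == o]
            for b in bins:
                vals[b] += 1.0 / len(bins)
    return vals


class TestBinDensity:
    def test_exact_identity_when_length_equals_bins(self):
        t = _mk_transcript(u5=10, cds=130, u3=10)
        cfg = ProfileConfig()
        # item at CDS position i must land in exon bin i exactly
        for i in (0, 64, 129):
            item = Interval("chrI", 10 + i, 11 + i, "+")
            prof = bin_density([item], [t], cfg)
            assert prof.values[cfg.utr5_bins + i] == 1.0
            assert prof.values.sum() == pytest.approx(1.0)

    def test_mass_conservation(self):
        rng = np.random.default_rng(7)
        ts, items = [], []
        pos = 0
        for i in range(20):
            u5, cds, u3 = (int(rng.integers(5, 60)), 3 * int(rng.integers(20, 120)), int(rng.integers(5, 60)))
            t = _mk_transcript(f"t{i}", pos, u5, cds, u3, strand="+" if i % 2 else "-")
            ts.append(t)
            for _ in range(3):
                a = int(rng.integers(t.start, t.end - 4))
                items.append(Interval("chrI", a, a + 4, t.strand))
            pos = t.end + 10
        prof = bin_density(items, ts, ProfileConfig())
        assert prof.values.sum() == pytest.approx(4 * len(items))

    def test_short_segment_fractional_split_matches_oracle(self):
        # 65-nt exon against 130 bins: every nucleotide spans two bins
        t = _mk_transcript(u5=10, cds=66, u3=10)  # cds multiple of 3
        cfg = ProfileConfig()
        item = Interval("chrI", 10, 76, "+")  # whole CDS
        prof = bin_density([item], [t], cfg)
        oracle = _oracle_bin_masses(66, 130, range(66))
        assert np.allclose(prof.values[10:140], oracle)

    def test_random_lengths_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            L = int(rng.integers(1, 50))
            B = int(rng.integers(1, 40))
            offsets = rng.integers(0, L, size=10)
            direct = _oracle_bin_masses(L, B, offsets)
            vectorised = np.zeros(B)
            for o in offsets:
                bins, mass = _segment_bins(L, B, int(o))
                vectorised[bins] += mass
            assert np.allclose(direct, vectorised)
            assert direct.sum() == pytest.approx(10.0)

    def test_per_gene_matrix_row_mass(self):
        t0 = _mk_transcript("t0", 0)
        t1 = _mk_transcript("t1", 1000)
        items = [Interval("chrI", 50, 54, "+"), Interval("chrI", 1050, 1054, "+")]
        prof, matrix = bin_density(items, [t0, t1], ProfileConfig(), per_gene=True)
        assert list(matrix.index) == ["t0", "t1"]
        assert matrix.sum(axis=1).tolist() == pytest.approx([4.0, 4.0])
        assert np.allclose(matrix.sum(axis=0).to_numpy(), prof.values)


class TestBindingProbability:
    def test_ratio(self):
        a = BinProfile(np.array([2.0, 0.0]), boundaries={"x": 0})
        b = BinProfile(np.array([8.0, 0.0]), boundaries={"x": 0})
        out = binding_probability(a, b)
        assert out.values[0] == pytest.approx(0.25)
        assert out.values[1] == 0.0 and out.mask[1]

    def test_subset_ratios_bounded(self):
        rng = np.random.default_rng(9)
        denom = rng.integers(1, 10, size=20).astype(float)
        numer = denom * rng.random(20)
        out = binding_probability(BinProfile(numer), BinProfile(denom))
        assert ((out.values >= 0) & (out.values <= 1)).all()

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binding_probability(BinProfile(np.zeros(3)), BinProfile(np.zeros(4)))

    def test_five_prime_planting_recovered(self):
        """Cross-linked motifs only in 5'UTRs give higher ratios in 5' bins
        than in 3' bins."""
        ts = [_mk_transcript(f"t{i}", i * 600) for i in range(10)]
        all_hits, xl_hits = [], []
        for t in ts:
            u5_hit = Interval("chrI", t.utr5[0] + 10, t.utr5[0] + 14, "+")
            u3_hit = Interval("chrI", t.utr3[0] + 10, t.utr3[0] + 14, "+")
            all_hits += [u5_hit, u3_hit]
            xl_hits.append(u5_hit)
        cfg = ProfileConfig()
        prob = binding_probability(bin_density(xl_hits, ts, cfg), bin_density(all_hits, ts, cfg))
        b = cfg.boundaries()
        mean_5p = prob.values[: cfg.utr5_bins].mean()
        mean_3p = prob.values[b["utr3"] :].mean()
        assert mean_5p > mean_3p


class TestAnchorProfile:
    def test_item_at_anchor_center_bin(self):
        item = Interval("chrI", 500, 501, "+")
        prof = anchor_profile([item], [("chrI", 500, "+")], flank=50)
        assert prof.values[50] == 1.0
        assert prof.values.sum() == 1.0

    def test_symmetric_items_symmetric_profile(self):
        items = [Interval("chrI", 490, 495, "+"), Interval("chrI", 506, 511, "+")]
        prof = anchor_profile(items, [("chrI", 500, "+")], flank=20)
        assert np.allclose(prof.values, prof.values[::-1])

    def test_minus_strand_flip(self):
        """An item 10 nt transcriptionally downstream of a minus-strand
        anchor lands in bin flank+10."""
        anchor = ("chrI", 500, "-")
        item = Interval("chrI", 490, 491, "-")  # 10 nt 3' in transcript orientation
        prof = anchor_profile([item], [anchor], flank=50)
        assert prof.values[60] == 1.0

    def test_items_beyond_window_excluded(self):
        item = Interval("chrI", 600, 601, "+")
        prof = anchor_profile([item], [("chrI", 500, "+")], flank=50)
        assert prof.values.sum() == 0.0

    def test_anchor_matrix_rows(self):
        from parclip.profiles import anchor_matrix

        t0 = _mk_transcript("t0", 0)
        t1 = _mk_transcript("t1", 1000)
        items = [Interval("chrI", 20, 24, "+")]  # only in t0, 20 nt from its TSS
        m = anchor_matrix(items, [t0, t1], flank=100)
        assert list(m.index) == ["t0", "t1"]
        assert m.loc["t0"].sum() == pytest.approx(4.0)
        assert m.loc["t0"].iloc[120] == 1.0
        assert m.loc["t1"].sum() == 0.0

    def test_transcript_anchor_positions(self):
        t = _mk_transcript()
        (tss,) = transcript_anchors([t], "tss")
        (pa,) = transcript_anchors([t], "pa_site")
        assert tss == ("chrI", 0, "+") and pa == ("chrI", 499, "+")
        tm = _mk_transcript(strand="-")
        (tss_m,) = transcript_anchors([tm], "tss")
        assert tss_m == ("chrI", 499, "-")


class TestTcPercentageProfile:
    def test_simple_percentage(self):
        n = 104
        cov = np.full(n, 4)
        tc = np.zeros(n, dtype=int)
        tcov = np.full(n, 4)
        tc[50] = 1  # one substitution over 4 covered Ts at the motif start
        contig = Contig("chrI", 0, n, "+", cov, tc, tcov, "f", "A" * n)
        hit = MotifHit("chrI", 50, 54, "+", "UCUU", "Nab3")
        prof = tc_percentage_profile([contig], [hit], flank=50)
        assert prof.n_bins == 104
        assert prof.values[50] == pytest.approx(25.0)

    def test_bounds_and_mask(self):
        rng = np.random.default_rng(10)
        n = 300
        cov = rng.integers(0, 6, size=n)
        tcov = np.minimum(cov, rng.integers(0, 6, size=n))
        tc = np.minimum(tcov, rng.integers(0, 3, size=n))
        contig = Contig("chrI", 0, n, "+", cov, tc, tcov, "f", "T" * n)
        hits = [MotifHit("chrI", s, s + 4, "+", "UCUU", "Nab3") for s in (60, 120, 200)]
        prof = tc_percentage_profile([contig], hits, flank=50)
        assert ((prof.values >= 0) & (prof.values <= 100)).all()
        assert (prof.values[prof.mask] == 0).all()


class TestKmeansRows:
    def test_degenerate_k1(self):
        X = np.random.default_rng(0).random((8, 5))
        assert set(kmeans_rows(X, 1, seed=0)) == {0}

    def test_separable_groups(self):
        rng = np.random.default_rng(1)
        left = np.zeros((10, 20)); left[:, :3] = 5 + rng.random((10, 3))
        right = np.zeros((10, 20)); right[:, -3:] = 5 + rng.random((10, 3))
        labels = kmeans_rows(np.vstack([left, right]), 2, seed=0)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_deterministic(self):
        X = np.random.default_rng(2).random((30, 10))
        a = kmeans_rows(X, 3, seed=5)
        b = kmeans_rows(X, 3, seed=5)
        assert np.array_equal(a, b)

    def test_k_exceeds_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans_rows(np.zeros((2, 3)), 5)
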