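import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from cistrokit import (
    ConsensusMotif,
    Gene,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    annotate_location,
    classify_dependency,
    gc_matched_background,
    merge_within,
    motif_enrichment,
    motif_foldchange_between_sets,
    partition_overlap,
    signal_matrix,
)
from cistrokit.synthetic import gen_genome, gen_two_condition_cistrome

from conftest import make_store


def iv(start, end, chrom="chr1", **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestMergeWithin:
    def test_gap_of_500_merges(self):
        merged = merge_within(PeakSet("x", [iv(100, 200), iv(700, 800)]), maxgap=500)
        assert [(p.start, p.end) for p in merged] == [(100, 800)]

    def test_gap_of_501_does_not_merge(self):
        merged = merge_within(PeakSet("x", [iv(100, 200), iv(701, 800)]), maxgap=500)
        assert len(merged) == 2

    def test_overlapping_peaks_merge(self):
        merged = merge_within(PeakSet("x", [iv(100, 300), iv(250, 400)]))
        assert [(p.start, p.end) for p in merged] == [(100, 400)]

    def test_idempotent_and_coverage_monotone(self, rng):
        for _ in range(10):
            ivs = []
            for _ in range(rng.integers(1, 30)):
                s = int(rng.integers(0, 5000))
                ivs.append(iv(s, s + int(rng.integers(1, 400)),
                              chrom=f"chr{rng.integers(1, 3)}"))
            peaks = PeakSet("x", ivs)
            once = merge_within(peaks)
            twice = merge_within(once)
            assert [(p.chrom, p.start, p.end) for p in once] == \
                   [(p.chrom, p.start, p.end) for p in twice]
            assert len(once) <= len(peaks)
            assert once.total_bp() >= _union_bp(peaks)

    def test_empty(self):
        assert len(merge_within(PeakSet("x"))) == 0


def _union_bp(peaks):
    per_chrom = {}
    for p in peaks:
        per_chrom.setdefault(p.chrom, set()).update(range(p.start, p.end))
    return sum(len(s) for s in per_chrom.values())


class TestPartitionOverlap:
    def test_one_bp_overlap_is_shared(self):
        part = partition_overlap(PeakSet("a", [iv(100, 200)]),
                                 PeakSet("b", [iv(199, 300)]))
        assert part.counts == {"a_only": 0, "b_only": 0, "shared_a": 1, "shared_b": 1}

    def test_halfopen_abutment_is_disjoint(self):
        part = partition_overlap(PeakSet("a", [iv(100, 200)]),
                                 PeakSet("b", [iv(200, 300)]))
        assert part.counts == {"a_only": 1, "b_only": 1, "shared_a": 0, "shared_b": 0}

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(10):
            def random_set(label):
                ivs = []
                for _ in range(rng.integers(1, 15)):
                    s = int(rng.integers(0, 2000))
                    ivs.append(iv(s, s + int(rng.integers(1, 150))))
                return merge_within(PeakSet(label, ivs), maxgap=0)

            a, b = random_set("a"), random_set("b")
            part = partition_overlap(a, b)

            def overlaps(x, y):
                return x.chrom == y.chrom and x.start < y.end and y.start < x.end

            shared_a = sum(1 for x in a if any(overlaps(x, y) for y in b))
            shared_b = sum(1 for y in b if any(overlaps(x, y) for x in a))
            assert part.counts["shared_a"] == shared_a
            assert part.counts["shared_b"] == shared_b
            assert part.counts["a_only"] == len(a) - shared_a
            assert part.counts["b_only"] == len(b) - shared_b

    def test_partition_covers_every_peak_once(self, rng):
        a = PeakSet("a", [iv(i * 100, i * 100 + 80) for i in range(10)])
        b = PeakSet("b", [iv(i * 150, i * 150 + 80) for i in range(10)])
        part = partition_overlap(a, b)
        c = part.counts
        assert c["a_only"] + c["shared_a"] == len(a)
        assert c["b_only"] + c["shared_b"] == len(b)


class TestClassifyDependency:
    def test_fraction_lost_arithmetic(self):
        wt = PeakSet("wt", [iv(i * 1000, i * 1000 + 100) for i in range(10)])
        ko = PeakSet("ko", wt.intervals[6:])
        classes = classify_dependency(wt, ko)
        assert classes.fraction_lost == 0.6
        assert classes.counts == {"lost": 6, "retained": 4, "gained": 0}

    def test_identical_sets_lose_and_gain_nothing(self):
        wt = PeakSet("wt", [iv(0, 100), iv(1000, 1100)])
        classes = classify_dependency(wt, PeakSet("ko", list(wt.intervals)))
        assert classes.counts == {"lost": 0, "retained": 2, "gained": 0}

    def test_empty_wildtype_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_dependency(PeakSet("wt"), PeakSet("ko", [iv(0, 10)]))

    def test_synthetic_dependent_fraction_recovered_exactly(self):
        wt, ko, _, manifest = gen_two_condition_cistrome(
            seed=11, n_wt=200, dependent_frac=0.65)
        classes = classify_dependency(merge_within(wt), merge_within(ko))
        assert classes.fraction_lost == manifest.records["true_dependent_frac"] == 0.65


class TestAnnotateLocation:
    GENES = [
        Gene("chr1", 10_000, 20_000, "+", "geneA",
             exons=((10_000, 11_000), (15_000, 16_000))),
    ]

    @pytest.mark.parametrize("center,expected", [
        (9_100, "promoter"),        # 900 bp upstream of the TSS
        (8_900, "distal_intergenic"),  # 1100 bp upstream: outside +/-1 kb
        (10_800, "promoter"),       # inside an exon but near the TSS: promoter wins
        (15_500, "exon"),
        (13_000, "intron"),
        (50_000, "distal_intergenic"),
    ])
    def test_precedence_and_boundaries(self, center, expected):
        peaks = PeakSet("p", [iv(center - 50, center + 50)])
        df = annotate_location(peaks, self.GENES, promoter_dist=1000)
        assert df["category"].iloc[0] == expected

    def test_chromosome_without_genes_is_distal(self):
        peaks = PeakSet("p", [iv(100, 200, chrom="chr9")])
        assert annotate_location(peaks, self.GENES)["category"].iloc[0] == \
            "distal_intergenic"

    def test_minus_strand_tss_at_gene_end(self):
        genes = [Gene("chr1", 10_000, 20_000, "-", "geneB")]
        peaks = PeakSet("p", [iv(20_850, 20_950)])  # 900 bp past the 3' coord
        assert annotate_location(peaks, genes)["category"].iloc[0] == "promoter"


class TestGcMatchedBackground:
    def test_lengths_match_and_no_fg_overlap(self):
        genome = gen_genome(seed=5, chrom_len=200_000, gc=0.5)
        fg = PeakSet("fg", [iv(i * 2000, i * 2000 + 200) for i in range(20)])
        bg = gc_matched_background(fg, genome, n_per_fg=2, seed=3)
        assert len(bg) == 40
        assert all(len(b) == 200 for b in bg)
        for b in bg:
            assert not any(p.start < b.end and b.start < p.end for p in fg)

    def test_gc_bins_match_foreground(self):
        genome = gen_genome(seed=5, chrom_len=200_000, gc=0.5)
        fg = PeakSet("fg", [iv(i * 2000, i * 2000 + 200) for i in range(10)])
        bg = gc_matched_background(fg, genome, n_per_fg=1, gc_bin_width=0.05, seed=3)

        def gc_bin(p):
            seq = genome.fetch(p.chrom, p.start, p.end)
            return int(sum(c in "GC" for c in seq) / len(seq) / 0.05)

        fg_bins = sorted(gc_bin(p) for p in fg)
        bg_bins = sorted(gc_bin(p) for p in bg)
        assert fg_bins == bg_bins

    def test_seeded_determinism(self):
        genome = gen_genome(seed=5, chrom_len=100_000, gc=0.5)
        fg = PeakSet("fg", [iv(i * 2000, i * 2000 + 200) for i in range(5)])
        one = gc_matched_background(fg, genome, seed=9)
        two = gc_matched_background(fg, genome, seed=9)
        assert one.intervals == two.intervals

    def test_impossible_request_reports_deficit(self):
        genome = make_store(chr1="AT" * 300)
        fg = PeakSet("fg", [iv(0, 600)])  # whole chromosome: nothing left
        with pytest.raises(RuntimeError, match="GC bin"):
            gc_matched_background(fg, genome, n_per_fg=1, seed=1, max_tries=50)


class TestMotifEnrichment:
    @staticmethod
    def _planted_sets(n_fg_pos, n_fg, n_bg_pos, n_bg, seed=0):
        """Peak sets over a genome where presence is planted deterministically."""
        motif = ConsensusMotif("site", "TGTTTACGGAGAACA", 2)
        wt, ko, genome, _ = gen_two_condition_cistrome(
            seed=seed, n_wt=n_fg + n_bg, dependent_frac=n_fg / (n_fg + n_bg),
            motif_dependent=motif,
            purity_dependent=n_fg_pos / n_fg, cross_frac=n_bg_pos / n_bg)
        classes = classify_dependency(merge_within(wt), merge_within(ko))
        return classes.lost, classes.retained, genome, motif

    def test_hypergeometric_tail_equals_direct_summation(self):
        fg, bg, genome, motif = self._planted_sets(8, 10, 2, 10)
        df = motif_enrichment(fg, bg, genome, [motif])
        row = df.iloc[0]
        assert (row.fg_hits, row.bg_hits) == (8, 2)
        # direct combinatorial summation over the upper tail
        M, n, N = 20, 10, 10
        expected = sum(
            comb(n, k, exact=True) * comb(M - n, N - k, exact=True)
            for k in range(8, min(n, N) + 1)
        ) / comb(M, N, exact=True)
        assert row.p_value == pytest.approx(expected, rel=1e-12)

    def test_fold_change_of_planted_fractions(self):
        fg, bg, genome, motif = self._planted_sets(40, 100, 10, 100, seed=2)
        df = motif_enrichment(fg, bg, genome, [motif])
        row = df.iloc[0]
        assert row.fg_fraction == 0.40 and row.bg_fraction == 0.10
        assert row.fg_fraction / row.bg_fraction == pytest.approx(4.0)

    def test_label_exchange_flips_tail(self):
        fg, bg, genome, motif = self._planted_sets(8, 10, 2, 10)
        p_fwd = motif_enrichment(fg, bg, genome, [motif]).iloc[0].p_value
        p_rev = motif_enrichment(bg, fg, genome, [motif]).iloc[0].p_value
        # on fixed margins, the swapped upper tail P(X_bg >= 2) equals the
        # original lower tail P(X_fg <= 8)
        expected = float(stats.hypergeom.cdf(8, 20, 10, 10))
        assert p_rev == pytest.approx(expected, rel=1e-12)
        assert p_fwd + float(stats.hypergeom.cdf(7, 20, 10, 10)) == pytest.approx(1.0)

    def test_bh_qvalues_monotone_and_bounded(self):
        motifs = [ConsensusMotif(f"m{i}", c, 1) for i, c in enumerate(
            ["TGTTTACG", "AGAACATG", "CCGGAATT", "TTGACGTC"])]
        genome = gen_genome(seed=8, chrom_len=60_000)
        fg = PeakSet("fg", [iv(i * 1000, i * 1000 + 200) for i in range(25)])
        bg = PeakSet("bg", [iv(30_000 + i * 1000, 30_000 + i * 1000 + 200)
                            for i in range(25)])
        df = motif_enrichment(fg, bg, genome, motifs)
        assert (df["q_value"] <= 1).all()
        assert (df["q_value"] >= df["p_value"]).all()
        assert df["q_value"].is_monotonic_increasing  # df sorted by p

    def test_empty_sets_rejected(self):
        genome = gen_genome(seed=1, chrom_len=1000)
        with pytest.raises(ValueError):
            motif_enrichment(PeakSet("fg"), PeakSet("bg", [iv(0, 100)]), genome, [])


class TestMotifFoldchange:
    def test_equal_fractions_give_zero_log2fc(self):
        fg, bg, genome, motif = TestMotifEnrichment._planted_sets(5, 10, 5, 10, seed=4)
        df = motif_foldchange_between_sets(fg, bg, genome, [motif])
        assert df.iloc[0].log2_fold_change == 0.0

    def test_planted_40_vs_2_percent_recovered_exactly(self):
        fg, bg, genome, motif = TestMotifEnrichment._planted_sets(40, 100, 2, 100,
                                                                  seed=6)
        df = motif_foldchange_between_sets(fg, bg, genome, [motif])
        row = df.iloc[0]
        assert row.a_fraction == 0.40
        assert row.b_fraction == 0.02
        assert row.log2_fold_change > 0

    def test_motif_only_in_a_is_finite_positive(self):
        fg, bg, genome, motif = TestMotifEnrichment._planted_sets(10, 10, 0, 10,
                                                                  seed=7)
        df = motif_foldchange_between_sets(fg, bg, genome, [motif])
        assert np.isfinite(df.iloc[0].log2_fold_change)
        assert df.iloc[0].log2_fold_change > 3


class TestSignalMatrix:
    def test_constant_track_fills_matrix(self):
        track = SignalTrack({"chr1": [(0, 10_000, 1.0)]})
        peaks = PeakSet("p", [iv(4000, 4200), iv(6000, 6200)])
        mat = signal_matrix(track, peaks, half_width=500, bin=25)
        assert mat.shape == (2, 40)
        assert (mat.values == 1.0).all()

    def test_histone_convention_bin_count(self):
        track = SignalTrack({"chr1": [(0, 100_000, 1.0)]})
        peaks = PeakSet("p", [iv(50_000, 50_200)])
        mat = signal_matrix(track, peaks, half_width=2500, bin=25)
        assert mat.shape[1] == 200

    def test_step_track_matches_per_bp_oracle(self, rng):
        steps = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(10, 200))
            width = int(rng.integers(5, 150))
            steps.append((pos, pos + width, float(rng.integers(1, 20))))
            pos += width
        track = SignalTrack({"chr1": steps})
        peaks = PeakSet("p", [iv(1000, 1400), iv(2000, 2500)])
        mat = signal_matrix(track, peaks, half_width=400, bin=20)
        for r, p in enumerate(peaks):
            base = p.center - 400
            per_bp = np.zeros(800)
            for s, e, v in steps:
                for b in range(max(s, base), min(e, base + 800)):
                    per_bp[b - base] = v
            expected = per_bp.reshape(40, 20).mean(axis=1)
            np.testing.assert_allclose(mat.values[r], expected)

    def test_bin_must_divide_window(self):
        track = SignalTrack({"chr1": [(0, 1000, 1.0)]})
        with pytest.raises(ValueError, match="divide"):
            signal_matrix(track, PeakSet("p", [iv(100, 200)]), half_width=500, bin=33)
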