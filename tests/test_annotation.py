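"""Breakpoint-flank annotation: windows, repeat categories, random null,
score means, permutation test and microhomology."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnveval.annotation import (
    classify_repeat_content,
    count_permutation_test,
    enrichment_table,
    flank_windows,
    kmer_null_space,
    microhomology_scan,
    sample_random_regions,
    score_summary,
    track_mean,
)
from cnveval.model import AnnotationTrack, GenomeModel, ScoreTrack


@pytest.fixture(scope="module")
def genome():
    return GenomeModel((("chr1", 10_000_000), ("chr2", 5_000_000)))


class TestFlankWindows:
    def test_plain_windows(self, genome):
        pair = flank_windows(("chr1", 10_000, 50_000), 1_000, genome)
        assert pair.start_window == (9_000, 11_000)
        assert pair.end_window == (49_000, 51_000)
        assert not pair.clipped

    def test_clipped_at_chromosome_start(self, genome):
        pair = flank_windows(("chr1", 300, 50_000), 500, genome)
        assert pair.start_window == (0, 800)
        assert pair.clipped

    def test_windows_nest_with_width(self, genome):
        small = flank_windows(("chr1", 10_000, 50_000), 500, genome)
        large = flank_windows(("chr1", 10_000, 50_000), 1_000, genome)
        assert large.start_window[0] <= small.start_window[0]
        assert large.start_window[1] >= small.start_window[1]
        assert large.end_window[0] <= small.end_window[0]
        assert large.end_window[1] >= small.end_window[1]

    def test_unknown_chromosome(self, genome):
        with pytest.raises(KeyError):
            flank_windows(("chr9", 10_000, 50_000), 500, genome)


def _track(cls, intervals):
    return AnnotationTrack(cls, cls, intervals)


class TestRepeatCategories:
    def _pair(self, genome):
        return flank_windows(("chr1", 100_000, 200_000), 1_000, genome)

    def test_line_in_both_windows_only(self, genome):
        tracks = [_track("LINE", [("chr1", 99_500, 100_100),
                                  ("chr1", 199_900, 200_300)]),
                  _track("segdup", []), _track("SINE", []), _track("LTR", [])]
        flags = classify_repeat_content(self._pair(genome), tracks)
        assert flags.only_LINE and flags.interspersed_all_both
        assert not flags.only_SINE and not flags.only_LTR
        assert not flags.segdup_both
        assert flags.segdup_or_interspersed_both

    def test_segdup_one_side_only(self, genome):
        tracks = [_track("segdup", [("chr1", 99_500, 100_100)])]
        flags = classify_repeat_content(self._pair(genome), tracks)
        assert not flags.segdup_both

    def test_mixed_classes_clear_only_flags(self, genome):
        tracks = [_track("LINE", [("chr1", 99_500, 100_100)]),
                  _track("SINE", [("chr1", 199_900, 200_300)])]
        flags = classify_repeat_content(self._pair(genome), tracks)
        assert flags.interspersed_all_both
        assert not (flags.only_LINE or flags.only_SINE or flags.only_LTR)

    def test_no_tracks_is_an_error(self, genome):
        with pytest.raises(ValueError):
            classify_repeat_content(self._pair(genome), [])


class TestRandomRegions:
    def test_length_preserved_and_in_bounds(self, genome):
        out = sample_random_regions(genome, [5_000] * 50, 1)
        for chrom, s, e in out:
            assert e - s == 5_000
            assert 0 <= s < e <= genome.length(chrom)

    def test_deterministic_given_seed(self, genome):
        assert sample_random_regions(genome, [1_000] * 20, 42) == \
            sample_random_regions(genome, [1_000] * 20, 42)

    def test_exclusions_respected(self, genome):
        excl = [("chr1", 0, 9_900_000), ("chr2", 0, 4_900_000)]
        out = sample_random_regions(genome, [10_000] * 20, 3, exclusions=excl)
        for chrom, s, e in out:
            for ec, es, ee in excl:
                if ec == chrom:
                    assert e <= es or s >= ee

    def test_hit_rate_matches_analytic_coverage(self, genome):
        # track of fixed-length elements at density d: a window of width W
        # hits one with P = 1 - exp(-d (W + L))
        rng = np.random.default_rng(5)
        d, L = 5e-5, 1_000
        intervals = []
        for chrom, length in genome.chromosomes:
            n = rng.poisson(d * length)
            starts = rng.integers(0, length - L, size=n)
            intervals += [(chrom, int(s), int(s) + L) for s in starts]
        track = _track("segdup", intervals)
        W = 2_000
        n_draws = 10_000
        draws = sample_random_regions(genome, [W] * n_draws, rng)
        hits = sum(track.intersects(c, s, e) for c, s, e in draws)
        p = 1 - math.exp(-d * (W + L))
        se = math.sqrt(p * (1 - p) / n_draws)
        assert abs(hits / n_draws - p) < 3 * se


class TestEnrichmentTable:
    def test_constructed_segdups_in_every_flank(self, genome):
        cnvs = [("chr1", s, s + 50_000) for s in range(1_000_000, 2_000_000, 100_000)]
        intervals = []
        for _, s, e in cnvs:
            intervals += [("chr1", s - 100, s + 100), ("chr1", e - 100, e + 100)]
        tracks = [_track("segdup", intervals)]
        df = enrichment_table({"CNV": cnvs}, tracks, (500,), genome, seed=1,
                              include_random=False)
        got = df[(df.category == "segdup_both")]["percent"].item()
        assert got == 100.0

    def test_empty_tracks_give_zero_everywhere(self, genome):
        cnvs = [("chr1", 1_000_000, 1_050_000)]
        tracks = [_track("segdup", []), _track("LINE", [])]
        df = enrichment_table({"CNV": cnvs}, tracks, (500, 1000), genome, seed=1)
        assert (df["percent"] == 0).all()

    def test_only_categories_partition_all(self, genome):
        rng = np.random.default_rng(9)
        tracks = []
        for cls, d, L in (("LINE", 8e-5, 600), ("SINE", 1e-4, 300),
                          ("LTR", 4e-5, 500)):
            intervals = []
            for chrom, length in genome.chromosomes:
                n = rng.poisson(d * length)
                starts = rng.integers(0, length - L, size=n)
                intervals += [(chrom, int(s), int(s) + L) for s in starts]
            tracks.append(_track(cls, intervals))
        cnvs = sample_random_regions(genome, [30_000] * 200, rng)
        df = enrichment_table({"CNV": cnvs}, tracks, (1000,), genome, seed=2,
                              include_random=False)
        by_cat = df.set_index("category")["percent"]
        only_sum = by_cat["only_SINE"] + by_cat["only_LINE"] + by_cat["only_LTR"]
        assert only_sum <= by_cat["interspersed_all_both"] + 1e-9

    def test_wider_flank_never_lowers_containment(self, genome):
        rng = np.random.default_rng(10)
        intervals = [("chr1", int(s), int(s) + 500)
                     for s in rng.integers(0, 9_900_000, size=600)]
        tracks = [_track("LINE", intervals)]
        cnvs = sample_random_regions(genome, [20_000] * 150, rng)
        df = enrichment_table({"CNV": cnvs}, tracks, (500, 1000), genome,
                              seed=3, include_random=False)
        wide = df[df.flank_bp == 1000].set_index("category")["percent"]
        narrow = df[df.flank_bp == 500].set_index("category")["percent"]
        assert (wide >= narrow - 1e-9).all()


class TestTrackMean:
    def test_constant_track(self):
        track = ScoreTrack("t", [("chr1", 0, 10_000, 7.5)])
        tm = track_mean(("chr1", 2_000, 3_000), track)
        assert tm.mean == 7.5 and tm.coverage == 1.0

    def test_half_and_half(self):
        track = ScoreTrack("t", [("chr1", 0, 500, 0.0), ("chr1", 500, 1_000, 100.0)])
        tm = track_mean(("chr1", 0, 1_000), track)
        assert tm.mean == 50.0

    def test_uncovered_window_flagged(self):
        track = ScoreTrack("t", [("chr1", 0, 100, 1.0)])
        tm = track_mean(("chr1", 5_000, 6_000), track)
        assert not tm.defined and np.isnan(tm.mean)

    @pytest.mark.parametrize("instance_seed", range(10))
    def test_equals_per_base_oracle(self, instance_seed):
        rng = np.random.default_rng(6000 + instance_seed)
        # random stepwise track with gaps, windows <= 10 kb
        records, cursor = [], 0
        while cursor < 40_000:
            span = int(rng.integers(50, 900))
            if rng.random() < 0.75:
                records.append(("chr1", cursor, cursor + span,
                                float(rng.normal(50, 20))))
            cursor += span
        track = ScoreTrack("t", records)
        per_base = np.full(50_000, np.nan)
        for _, s, e, v in records:
            per_base[s:e] = v
        for _ in range(5):
            ws = int(rng.integers(0, 39_000))
            we = ws + int(rng.integers(100, 10_000))
            tm = track_mean(("chr1", ws, we), track)
            window = per_base[ws:we]
            covered = np.isfinite(window)
            if covered.any():
                assert tm.mean == pytest.approx(float(np.nanmean(window)))
                assert tm.covered_bp == int(covered.sum())
            else:
                assert not tm.defined


class TestScoreSummary:
    def test_constant_track_every_set(self, genome):
        track = ScoreTrack("t", [(c, 0, l, 42.0) for c, l in genome.chromosomes])
        cnvs = [("chr1", 1_000_000, 1_050_000), ("chr2", 200_000, 230_000)]
        df = score_summary({"A": cnvs, "B": cnvs}, track, (500, 1000), genome,
                           seed=1)
        assert np.allclose(df["start_mean"], 42.0)
        assert np.allclose(df["end_mean"], 42.0)

    def test_order_invariance(self, genome):
        track = ScoreTrack("t", [("chr1", 0, 10_000_000, 10.0)])
        cnvs = [("chr1", s, s + 40_000) for s in range(1_000_000, 3_000_000, 200_000)]
        a = score_summary({"CNV": cnvs}, track, (500,), genome, seed=7)
        b = score_summary({"CNV": list(reversed(cnvs))}, track, (500,), genome,
                          seed=7)
        assert a[["set", "start_mean", "end_mean"]].equals(
            b[["set", "start_mean", "end_mean"]])


class TestPermutationTest:
    def _windows(self, genome, regions, w=1_000):
        out = []
        for iv in regions:
            out.extend(flank_windows(iv, w, genome).windows)
        return out

    def test_empty_feature_track(self, genome):
        track = _track("CpG_island", [])
        regions = [("chr1", 1_000_000, 1_050_000)]
        res = count_permutation_test(self._windows(genome, regions), genome,
                                     [50_000], 1_000, track, n_perm=100, seed=1)
        assert res.observed == 0 and res.p_value == 1.0

    def test_deterministic_given_seed(self, genome):
        rng = np.random.default_rng(11)
        track = _track("CpG_island",
                       [("chr1", int(s), int(s) + 500)
                        for s in rng.integers(0, 9_000_000, size=300)])
        regions = sample_random_regions(genome, [30_000] * 40, rng)
        windows = self._windows(genome, regions)
        r1 = count_permutation_test(windows, genome, [30_000] * 40, 1_000,
                                    track, n_perm=100, seed=5)
        r2 = count_permutation_test(windows, genome, [30_000] * 40, 1_000,
                                    track, n_perm=100, seed=5)
        assert r1.p_value == r2.p_value and r1.observed == r2.observed

    def test_pvalues_superuniform_under_null(self, genome):
        # features placed independently of the windows: P(p <= 0.05) must
        # not exceed 0.05 by more than 3 SE over 200 replicates
        rng = np.random.default_rng(12)
        regions = sample_random_regions(genome, [30_000] * 40, rng)
        windows = self._windows(genome, regions)
        n_rep, alpha = 200, 0.05
        hits = 0
        for _ in range(n_rep):
            starts = rng.integers(0, 9_000_000, size=200)
            track = _track("CpG_island",
                           [("chr1", int(s), int(s) + 500) for s in starts])
            res = count_permutation_test(windows, genome, [30_000] * 40,
                                         1_000, track, n_perm=100, seed=rng)
            if res.p_value <= alpha:
                hits += 1
        se = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert hits / n_rep <= alpha + 3 * se


class TestMicrohomology:
    def test_identical_sequences_share_all_kmers(self):
        s = "ACGTACGTGG"
        res = microhomology_scan(s, s, 3)
        distinct = {s[i:i + 3] for i in range(len(s) - 2)}
        assert res.count == len(distinct)

    def test_disjoint_alphabets_share_nothing(self):
        assert microhomology_scan("AAAA", "CCCC", 2).count == 0

    def test_n_containing_kmers_excluded(self):
        res = microhomology_scan("AANAA", "AANAA", 2)
        assert set(res.shared) == {"AA"}

    def test_k_longer_than_sequence_errors(self):
        with pytest.raises(ValueError):
            microhomology_scan("ACG", "ACGTACGT", 4)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True)
    def test_agrees_with_set_oracle(self, instance_seed):
        rng = np.random.default_rng(instance_seed)
        bases = np.array(list("ACGTN"))
        a = "".join(rng.choice(bases, size=1_000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        b = "".join(rng.choice(bases, size=1_000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        res = microhomology_scan(a, b, 5)
        valid = set("ACGT")
        ka = {a[i:i + 5] for i in range(996) if set(a[i:i + 5]) <= valid}
        kb = {b[i:i + 5] for i in range(996) if set(b[i:i + 5]) <= valid}
        assert set(res.shared) == (ka & kb)


class TestKmerNullSpace:
    def test_pentamer_universe(self):
        assert kmer_null_space(4, 5) == 1024

    @pytest.mark.parametrize("k, expected", [(1, 4), (10, 1_048_576)])
    def test_powers(self, k, expected):
        assert kmer_null_space(4, k) == expected

    def test_arbitrary_precision(self):
        assert kmer_null_space(4, 200) == 4 ** 200
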