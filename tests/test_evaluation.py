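"""Concordance statistics: trivial identities, oracle agreement, and
generator-parameter recovery."""

import numpy as np
import pytest

from cnveval.evaluation import (
    length_distribution,
    mendelian_inconsistency,
    pairwise_similarity,
    pooled_overlap_ratio,
    reference_sensitivity,
    stability_rate,
)
from cnveval.model import CallSet, CNVSegment, GenomeModel, PedigreeTable
from conftest import brute_force_match, random_segments, small_config
from cnveval.simulate import ProgramModel, generate_world


def seg(chrom, start, end, cnv_type="loss", sample="s1", program="P", array="a1"):
    return CNVSegment(chrom, start, end, cnv_type, sample, program, array)


class TestStability:
    def test_identical_replicates_are_fully_stable(self):
        segs = [seg("chr1", 0, 1000, array=a) for a in ("a1", "a2", "a3", "a4", "a5")]
        cs = CallSet(segs)
        rep = stability_rate(cs, "s1", ["a1", "a2", "a3", "a4", "a5"], "P")
        assert rep.value == 1.0
        assert rep.n_excluded == 0

    def test_opposite_types_are_unstable_under_strict_policy(self):
        cs = CallSet([seg("chr1", 0, 100, "gain", array="a1"),
                      seg("chr1", 0, 100, "loss", array="a2")])
        rep = stability_rate(cs, "s1", ["a1", "a2"], "P", type_policy="strict")
        assert rep.value == 0.0

    def test_requires_two_replicates(self):
        cs = CallSet([seg("chr1", 0, 100)])
        with pytest.raises(ValueError):
            stability_rate(cs, "s1", ["a1"], "P")

    def test_invariant_under_replicate_relabelling(self, small_world):
        w = small_world
        sample = "S001"
        arrays = w.pedigree.replicate_groups[sample]
        prog = sorted(w.callset.programs)[0]
        forward = stability_rate(w.callset, sample, arrays, prog)
        backward = stability_rate(w.callset, sample, list(reversed(arrays)), prog)
        assert forward.value == pytest.approx(backward.value)

    def test_recovers_detection_probability(self):
        # independent per-replicate detection at p, no jitter/false calls:
        # expected stability = p
        p = 0.9
        cfg = small_config(
            911,
            n_chromosomes=4, chrom_length=30_000_000,
            n_regions=250, freq_min=1.0, freq_max=1.0,
            n_unrelated=1, n_trios=0,
            n_replicate_samples=1, n_replicates=5,
            programs={"P": ProgramModel(p, 0.0, 0.0)},
        )
        w = generate_world(cfg)
        rep = stability_rate(w.callset, "S001",
                             w.pedigree.replicate_groups["S001"], "P")
        se = np.sqrt(p * (1 - p) / cfg.n_regions)
        assert abs(rep.value - p) < 3 * se


class TestMendelian:
    def _trio_callset(self, off_segs, fa_segs, mo_segs):
        segs = ([s for s in off_segs] + [s for s in fa_segs] + [s for s in mo_segs])
        return CallSet(segs, samples=["off", "fa", "mo"])

    def test_offspring_matching_father_is_consistent(self):
        off = [seg("chr1", 0, 1000, sample="off"), seg("chr2", 0, 500, sample="off")]
        fa = [seg("chr1", 0, 1000, sample="fa"), seg("chr2", 0, 500, sample="fa")]
        cs = self._trio_callset(off, fa, [])
        ped = PedigreeTable(trios=[("off", "fa", "mo")])
        for thr in (0.0, 0.5, 0.8):
            assert mendelian_inconsistency(cs, ped, "P", thr).value == 0.0

    def test_one_of_four_matched_gives_three_quarters(self):
        off = [seg("chr1", i * 10_000, i * 10_000 + 1000, sample="off")
               for i in range(4)]
        fa = [seg("chr1", 0, 1000, sample="fa")]
        cs = self._trio_callset(off, fa, [])
        ped = PedigreeTable(trios=[("off", "fa", "mo")])
        assert mendelian_inconsistency(cs, ped, "P", 0.8).value == 0.75

    def test_absent_member_is_an_error_naming_the_sample(self):
        cs = CallSet([seg("chr1", 0, 100, sample="off")], samples=["off", "fa"])
        ped = PedigreeTable(trios=[("off", "fa", "mo")])
        with pytest.raises(KeyError, match="mo"):
            mendelian_inconsistency(cs, ped, "P", 0.8)

    def test_recovers_parental_dropout(self):
        # all offspring calls inherited; parents detected at p=0.9: the
        # inconsistency rate estimates 1 - p (second-parent rescue is rare
        # at carrier frequency 0.05)
        p = 0.9
        cfg = small_config(
            912,
            n_chromosomes=4, chrom_length=30_000_000,
            n_regions=250, freq_min=0.05, freq_max=0.05,
            n_unrelated=0, n_trios=50, n_replicate_samples=0,
            programs={"P": ProgramModel(p, 0.0, 0.0)},
        )
        w = generate_world(cfg)
        rep = mendelian_inconsistency(w.callset, w.pedigree, "P", 0.8)
        se = np.sqrt(0.1 * 0.9 / rep.denominator)
        assert abs(rep.value - (1 - p)) < 3 * se


class TestPairwiseSimilarity:
    def test_superset_program_gives_one(self):
        a = [seg("chr1", 0, 1000, program="A")]
        b = [seg("chr1", 0, 1000, program="B"), seg("chr2", 0, 500, program="B")]
        rep = pairwise_similarity(CallSet(a + b), "A", "B", 0.8)
        assert rep.value == 1.0

    def test_disjoint_placements_give_zero(self):
        a = [seg("chr1", 0, 1000, program="A")]
        b = [seg("chr2", 0, 1000, program="B")]
        rep = pairwise_similarity(CallSet(a + b), "A", "B", 0.0)
        assert rep.value == 0.0

    def test_no_shared_samples_is_an_error(self):
        a = [seg("chr1", 0, 1000, sample="x", program="A")]
        b = [seg("chr1", 0, 1000, sample="y", program="B")]
        with pytest.raises(ValueError, match="shared"):
            pairwise_similarity(CallSet(a + b), "A", "B", 0.8)

    @pytest.mark.parametrize("instance_seed", range(5))
    def test_agrees_with_all_pairs_oracle(self, instance_seed, toy_genome):
        rng = np.random.default_rng(1000 + instance_seed)
        a = random_segments(rng, 60, toy_genome, program="A")
        b = random_segments(rng, 60, toy_genome, program="B")
        cs = CallSet(a + b)
        rep = pairwise_similarity(cs, "A", "B", 0.5)
        # oracle: per shared sample, brute-force matched fraction
        samples = sorted({s.sample_id for s in a} & {s.sample_id for s in b})
        fractions, num, den = [], 0, 0
        for sample in samples:
            q = sorted((s for s in a if s.sample_id == sample),
                       key=lambda s: (s.chrom, s.start, s.end))
            t = [s for s in b if s.sample_id == sample]
            if not q:
                continue
            flags = brute_force_match(q, t, 0.5)
            fractions.append(flags.mean())
            num += int(flags.sum())
            den += len(q)
        assert rep.value == pytest.approx(float(np.mean(fractions)))
        assert (rep.numerator, rep.denominator) == (num, den)


class TestReferenceComparisons:
    def test_identical_calls_and_reference(self):
        calls = CallSet([seg("chr1", 0, 1000, program="A")])
        ref = CallSet([seg("chr1", 0, 1000, program="truth")])
        sens, spec = reference_sensitivity(calls, ref, "A")
        assert sens.value == 1.0 and spec.value == 1.0

    def test_empty_calls_give_zero_sensitivity_undefined_specificity(self):
        calls = CallSet([], samples=["s1"])
        ref = CallSet([seg("chr1", 0, 1000, program="truth")])
        sens, spec = reference_sensitivity(calls, ref, "A",
                                           shared_samples=["s1"])
        assert sens.value == 0.0
        assert spec.value is None and spec.n_excluded == 1

    def test_pooled_overlap_ignores_sample_identity(self):
        calls = CallSet([seg("chr1", 0, 1000, sample="x")])
        ref = CallSet([seg("chr1", 0, 1000, sample="completely-different")])
        rep = pooled_overlap_ratio(calls, ref, 0.8)
        assert rep.value == 1.0

    def test_pooled_overlap_empty_calls_flagged_undefined(self):
        rep = pooled_overlap_ratio(CallSet([]), CallSet([]), 0.8)
        assert rep.value is None

    def test_no_shared_chromosome_gives_zero(self):
        calls = CallSet([seg("chr1", 0, 1000)])
        ref = CallSet([seg("chr9", 0, 1000)])
        assert pooled_overlap_ratio(calls, ref, 0.0).value == 0.0


class TestThresholdMonotonicity:
    """Direction of the threshold grids: inconsistency can only grow with
    the overlap threshold, stability and similarity can only shrink."""

    def test_on_simulated_world(self, small_world):
        w = small_world
        prog = sorted(w.callset.programs)[0]
        grid = (0.0, 0.5, 0.8)
        mi = [mendelian_inconsistency(w.callset, w.pedigree, prog, t).value
              for t in grid]
        assert mi == sorted(mi)
        sample = "S001"
        arrays = w.pedigree.replicate_groups[sample]
        st = [stability_rate(w.callset, sample, arrays, prog, t).value
              for t in grid]
        assert st == sorted(st, reverse=True)
        progs = sorted(w.callset.programs)
        sim = [pairwise_similarity(w.callset, progs[0], progs[1], t).value
               for t in grid]
        assert sim == sorted(sim, reverse=True)

    def test_collapse_policy_never_below_strict(self, small_world):
        w = small_world
        progs = sorted(w.callset.programs)
        strict = pairwise_similarity(w.callset, progs[0], progs[1], 0.5,
                                     type_policy="strict").value
        collapse = pairwise_similarity(w.callset, progs[0], progs[1], 0.5,
                                       type_policy="collapse").value
        assert collapse >= strict


class TestLengthDistribution:
    def test_single_segment_lands_in_first_bin(self):
        cs = CallSet([seg("chr1", 0, 5000)])
        df = length_distribution(cs, [1_000, 10_000, 100_000])
        first = df[(df.program == "P") & (df.bin_left == 1_000)]
        assert first["count"].item() == 1
        assert df["count"].sum() == 1

    def test_empty_callset_gives_empty_frame(self):
        df = length_distribution(CallSet([]), [1_000, 10_000])
        assert df["count"].sum() if not df.empty else 0 == 0

    def test_histogram_mode_tracks_generator_median(self, small_world):
        # log-normal lengths with median 50 kb: the modal bin of a decade
        # histogram must be the one containing 50 kb
        df = length_distribution(small_world.callset,
                                 [1_000, 10_000, 100_000, 1_000_000])
        prog = sorted(small_world.callset.programs)[0]
        sub = df[df.program == prog].set_index("bin_left")["count"]
        assert sub.idxmax() == 10_000
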