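"""Breakpoint-flank characterisation of CNV regions.

Array probes are sparse, so the true breakpoints of a called CNV are only
known to within a window around the reported start and end.  Each CNV
therefore contributes a *flank pair*: the interval ±w bp around its start
and ±w bp around its end (w ∈ {500, 800, 1000} conventionally), clipped at
chromosome ends.

Within those windows this module measures

* repeat-class containment (segmental duplications; LINE / SINE / LTR
  interspersed repeats, singly and pooled) against a length-matched
  random-region null;
* length-weighted means of stepwise score tracks (conservation,
  recombination rate);
* feature counts (CpG islands) with a permutation test against random
  length-matched draws;
* shared k-mers between the two flank sequences (microhomology), whose
  null space is the 4^k k-mer universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    INTERSPERSED_CLASSES,
    AnnotationTrack,
    GenomeModel,
    ScoreTrack,
)

DEFAULT_FLANK_WIDTHS = (500, 800, 1000)


# ---------------------------------------------------------------------------
# flank windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlankPair:
    """The ±w windows around a CNV's start and end breakpoints."""

    chrom: str
    start_window: tuple[int, int]
    end_window: tuple[int, int]
    w: int
    clipped: bool = False

    @property
    def windows(self) -> tuple[tuple[str, int, int], tuple[str, int, int]]:
        return ((self.chrom, *self.start_window), (self.chrom, *self.end_window))


def flank_windows(item, w: int, genome: GenomeModel) -> FlankPair:
    """±w windows around start and end of a segment/region/interval.

    Windows are clipped to [0, chromosome length); clipping is recorded.
    The two windows may overlap for CNVs shorter than 2w — that is allowed.
    """
    if w <= 0:
        raise ValueError("flank half-width must be positive")
    if isinstance(item, tuple):
        chrom, start, end = item
    else:
        chrom, start, end = item.chrom, item.start, item.end
    length = genome.length(chrom)
    sw = (max(0, start - w), min(length, start + w))
    ew = (max(0, end - w), min(length, end + w))
    clipped = sw != (start - w, start + w) or ew != (end - w, end + w)
    if sw[0] >= sw[1] or ew[0] >= ew[1]:
        raise ValueError(f"empty flank window for {chrom}:{start}-{end}")
    return FlankPair(chrom, sw, ew, w, clipped)


# ---------------------------------------------------------------------------
# repeat-content categories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatCategoryFlags:
    """Per-CNV containment categories over the two flank windows.

    ``only_*`` flags require interspersed repeats in both windows *and* that
    the single class named is the only interspersed class present in either
    window, so they are mutually exclusive and each implies
    ``interspersed_all_both``.
    """

    segdup_both: bool
    interspersed_all_both: bool
    only_SINE: bool
    only_LINE: bool
    only_LTR: bool
    segdup_or_interspersed_both: bool

    CATEGORIES = ("segdup_both", "interspersed_all_both", "only_SINE",
                  "only_LINE", "only_LTR", "segdup_or_interspersed_both")

    def as_dict(self) -> dict[str, bool]:
        return {c: getattr(self, c) for c in self.CATEGORIES}


def classify_repeat_content(pair: FlankPair,
                            tracks: Sequence[AnnotationTrack]) -> RepeatCategoryFlags:
    """Classify a flank pair by which repeat classes hit both windows.

    A class is *present* in a window iff at least one track interval of that
    class intersects it.
    """
    if not tracks:
        raise ValueError("no annotation tracks given")
    win_s, win_e = pair.windows
    present_s: set[str] = set()
    present_e: set[str] = set()
    for track in tracks:
        if track.intersects(*win_s):
            present_s.add(track.feature_class)
        if track.intersects(*win_e):
            present_e.add(track.feature_class)

    inter_s = present_s & set(INTERSPERSED_CLASSES)
    inter_e = present_e & set(INTERSPERSED_CLASSES)
    segdup_both = "segdup" in present_s and "segdup" in present_e
    interspersed_all_both = bool(inter_s) and bool(inter_e)
    inter_either = inter_s | inter_e

    def only(cls: str) -> bool:
        return interspersed_all_both and inter_either == {cls}

    broad_s = present_s & ({"segdup"} | set(INTERSPERSED_CLASSES))
    broad_e = present_e & ({"segdup"} | set(INTERSPERSED_CLASSES))
    return RepeatCategoryFlags(
        segdup_both=segdup_both,
        interspersed_all_both=interspersed_all_both,
        only_SINE=only("SINE"),
        only_LINE=only("LINE"),
        only_LTR=only("LTR"),
        segdup_or_interspersed_both=bool(broad_s) and bool(broad_e),
    )


# ---------------------------------------------------------------------------
# random-region null
# ---------------------------------------------------------------------------


def sample_random_regions(
    genome: GenomeModel,
    lengths: Sequence[int],
    rng: np.random.Generator | int,
    exclusions: Sequence[tuple[str, int, int]] | None = None,
    max_tries: int = 1000,
) -> list[tuple[str, int, int]]:
    """One uniformly placed random interval per requested length.

    The chromosome is drawn with probability proportional to its length
    (restricted to chromosomes long enough); the start is uniform in
    [0, L - length].  Placements intersecting ``exclusions`` are rejected
    and redrawn, erroring after ``max_tries`` failures.  Deterministic for a
    given generator/seed.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    names = list(genome.names)
    chrom_lengths = np.array([genome.length(c) for c in names], dtype=float)

    excl_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if exclusions:
        tmp: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in exclusions:
            tmp.setdefault(chrom, []).append((s, e))
        for chrom, ivs in tmp.items():
            ivs.sort()
            es = np.array([s for s, _ in ivs], dtype=np.int64)
            ee = np.array([e for _, e in ivs], dtype=np.int64)
            # running max of ends makes the overlap check O(log n) even for
            # overlapping, variable-length exclusions
            excl_by_chrom[chrom] = (es, np.maximum.accumulate(ee))

    def _hits_exclusion(chrom: str, start: int, end: int) -> bool:
        if chrom not in excl_by_chrom:
            return False
        es, ee_cummax = excl_by_chrom[chrom]
        i = int(np.searchsorted(es, end, side="left")) - 1
        return i >= 0 and ee_cummax[i] > start

    out: list[tuple[str, int, int]] = []
    lengths_arr = np.asarray(lengths, dtype=np.int64)
    if lengths_arr.size and np.any(lengths_arr >= chrom_lengths.max()):
        bad = int(lengths_arr[lengths_arr >= chrom_lengths.max()][0])
        raise ValueError(f"no chromosome can host a {bad} bp interval")
    every_chrom_fits = lengths_arr.size == 0 or bool(
        (chrom_lengths > lengths_arr.max()).all())
    if not exclusions and every_chrom_fits:
        # fully vectorised path (the common case: intervals much shorter
        # than any chromosome)
        probs = chrom_lengths / chrom_lengths.sum()
        cis = rng.choice(len(names), size=lengths_arr.size, p=probs)
        highs = chrom_lengths[cis].astype(np.int64) - lengths_arr + 1
        starts = (rng.random(lengths_arr.size) * highs).astype(np.int64)
        for ci, start, length in zip(cis, starts, lengths_arr):
            out.append((names[ci], int(start), int(start) + int(length)))
        return out

    for length in lengths:
        placed = False
        for _ in range(max_tries):
            ok = chrom_lengths > length
            if not ok.any():
                raise ValueError(f"no chromosome can host a {length} bp interval")
            probs = np.where(ok, chrom_lengths, 0.0)
            probs /= probs.sum()
            ci = int(rng.choice(len(names), p=probs))
            start = int(rng.integers(0, int(chrom_lengths[ci]) - int(length) + 1))
            if not _hits_exclusion(names[ci], start, start + int(length)):
                out.append((names[ci], start, start + int(length)))
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place a {length} bp interval in "
                               f"{max_tries} tries (exclusions too dense)")
    return out


def _item_interval(item) -> tuple[str, int, int]:
    if isinstance(item, tuple):
        return item
    return (item.chrom, item.start, item.end)


# ---------------------------------------------------------------------------
# enrichment table (Table-6 style)
# ---------------------------------------------------------------------------


def enrichment_table(
    cnv_sets: Mapping[str, Sequence],
    tracks: Sequence[AnnotationTrack],
    flank_widths: Sequence[int],
    genome: GenomeModel,
    seed: int | np.random.Generator = 0,
    include_random: bool = True,
    random_name: str = "Random",
) -> pd.DataFrame:
    """Percentage of CNVs positive for each repeat category, per set and
    flank width.

    A random set matched in lengths and count to the pooled input CNVs is
    generated and reported first when ``include_random``.  Percentages are
    on the 0–100 scale; empty sets yield NaN percentages with n = 0.
    """
    sets: dict[str, list[tuple[str, int, int]]] = {}
    if include_random:
        pooled_lengths = [
            e - s for items in cnv_sets.values()
            for (_, s, e) in map(_item_interval, items)
        ]
        rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
        sets[random_name] = sample_random_regions(genome, pooled_lengths, rng)
    for name, items in cnv_sets.items():
        sets[name] = [_item_interval(x) for x in items]

    rows = []
    for name, intervals in sets.items():
        for w in flank_widths:
            flags = [
                classify_repeat_content(flank_windows(iv, w, genome), tracks)
                for iv in intervals
            ]
            n = len(flags)
            for cat in RepeatCategoryFlags.CATEGORIES:
                pct = (100.0 * np.mean([f.as_dict()[cat] for f in flags])
                       if n else float("nan"))
                rows.append({"set": name, "flank_bp": w, "category": cat,
                             "percent": pct, "n": n})
    return pd.DataFrame(rows, columns=["set", "flank_bp", "category", "percent", "n"])


# ---------------------------------------------------------------------------
# score-track summaries (Table-7 style)
# ---------------------------------------------------------------------------


@dataclass
class TrackMean:
    mean: float
    covered_bp: int
    window_bp: int

    @property
    def defined(self) -> bool:
        return self.covered_bp > 0

    @property
    def coverage(self) -> float:
        return self.covered_bp / self.window_bp if self.window_bp else 0.0


def track_mean(window: tuple[str, int, int], track: ScoreTrack) -> TrackMean:
    """Length-weighted mean of the track over covered bases of the window;
    uncovered bases are excluded from the weighting."""
    chrom, start, end = window
    if start >= end:
        raise ValueError("empty window")
    mean, covered = track.window_mean(chrom, start, end)
    return TrackMean(mean=mean, covered_bp=covered, window_bp=end - start)


def score_summary(
    cnv_sets: Mapping[str, Sequence],
    track: ScoreTrack,
    flank_widths: Sequence[int],
    genome: GenomeModel,
    seed: int | np.random.Generator = 0,
    include_random: bool = True,
    random_name: str = "Random",
) -> pd.DataFrame:
    """Mean of per-CNV window means, start and end flanks separately.

    Windows with no covered base are excluded from the mean and counted.
    The random set is length-matched to the pooled inputs as in
    :func:`enrichment_table`.
    """
    sets: dict[str, list[tuple[str, int, int]]] = {}
    if include_random:
        pooled_lengths = [
            e - s for items in cnv_sets.values()
            for (_, s, e) in map(_item_interval, items)
        ]
        rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
        sets[random_name] = sample_random_regions(genome, pooled_lengths, rng)
    for name, items in cnv_sets.items():
        sets[name] = [_item_interval(x) for x in items]

    rows = []
    for name, intervals in sets.items():
        for w in flank_widths:
            start_means, end_means = [], []
            n_undef_start = n_undef_end = 0
            for iv in intervals:
                pair = flank_windows(iv, w, genome)
                tm_s = track_mean(pair.windows[0], track)
                tm_e = track_mean(pair.windows[1], track)
                if tm_s.defined:
                    start_means.append(tm_s.mean)
                else:
                    n_undef_start += 1
                if tm_e.defined:
                    end_means.append(tm_e.mean)
                else:
                    n_undef_end += 1
            rows.append({
                "set": name,
                "flank_bp": w,
                "start_mean": float(np.mean(start_means)) if start_means else float("nan"),
                "end_mean": float(np.mean(end_means)) if end_means else float("nan"),
                "n": len(intervals),
                "n_undefined_start": n_undef_start,
                "n_undefined_end": n_undef_end,
            })
    return pd.DataFrame(rows, columns=["set", "flank_bp", "start_mean", "end_mean",
                                       "n", "n_undefined_start", "n_undefined_end"])


# ---------------------------------------------------------------------------
# feature-count permutation test (CpG islands)
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    observed: int
    p_value: float
    direction: str          # "depleted" | "enriched" | "none"
    null_mean: float
    null_sd: float
    n_perm: int


def count_permutation_test(
    cnv_windows: Sequence[tuple[str, int, int]],
    genome: GenomeModel,
    matched_lengths: Sequence[int],
    flank_w: int,
    feature_track: AnnotationTrack,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Permutation test on the number of features intersecting CNV windows.

    The observed statistic counts track features intersecting at least one
    of ``cnv_windows``.  The null redraws, ``n_perm`` times, length-matched
    random intervals (one per length in ``matched_lengths``), takes their
    ±``flank_w`` windows and recounts.  Two-sided
    p = (1 + #{null at least as extreme}) / (n_perm + 1), with extremeness
    measured as absolute deviation from the null mean.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    observed = feature_track.count_intersecting(cnv_windows)
    null = np.empty(n_perm, dtype=float)
    lengths = list(matched_lengths)
    for i in range(n_perm):
        draws = sample_random_regions(genome, lengths, rng)
        windows = []
        for iv in draws:
            pair = flank_windows(iv, flank_w, genome)
            windows.extend(pair.windows)
        null[i] = feature_track.count_intersecting(windows)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    dev = abs(observed - null_mean)
    n_extreme = int(np.sum(np.abs(null - null_mean) >= dev))
    p = (1 + n_extreme) / (n_perm + 1)
    if observed < null_mean:
        direction = "depleted"
    elif observed > null_mean:
        direction = "enriched"
    else:
        direction = "none"
    return PermutationResult(observed=observed, p_value=p, direction=direction,
                             null_mean=null_mean, null_sd=null_sd, n_perm=n_perm)


# ---------------------------------------------------------------------------
# microhomology
# ---------------------------------------------------------------------------

_VALID_BASES = set("ACGT")


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) <= _VALID_BASES:
            pos.setdefault(kmer, []).append(i)
    return pos


@dataclass
class MicrohomologyResult:
    k: int
    shared: dict[str, tuple[tuple[int, ...], tuple[int, ...]]]

    @property
    def count(self) -> int:
        return len(self.shared)


def microhomology_scan(start_window_seq: str, end_window_seq: str,
                       k: int) -> MicrohomologyResult:
    """Distinct k-mers shared by the two breakpoint flank sequences.

    Sequences are uppercased; k-mers containing N (or any non-ACGT symbol)
    are excluded.  Positions of each shared k-mer in both sequences are
    returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    a = start_window_seq.upper()
    b = end_window_seq.upper()
    if k > len(a) or k > len(b):
        raise ValueError(f"k={k} longer than a window sequence "
                         f"({len(a)} / {len(b)} bp)")
    pos_a = _kmer_positions(a, k)
    pos_b = _kmer_positions(b, k)
    shared = {
        kmer: (tuple(pos_a[kmer]), tuple(pos_b[kmer]))
        for kmer in sorted(set(pos_a) & set(pos_b))
    }
    return MicrohomologyResult(k=k, shared=shared)


def kmer_null_space(alphabet_size: int = 4, k: int = 5) -> int:
    """Size of the k-mer universe, alphabet_size**k — the null-model space
    against which shared breakpoint k-mers are judged (4^5 = 1024).
    Exact arbitrary-precision integer arithmetic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be >= 1")
    return alphabet_size ** k
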