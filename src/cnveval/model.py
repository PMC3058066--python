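"""Core data model for CNV call-set evaluation.

Coordinates are 0-based half-open (BED convention) everywhere, in memory and
on disk.  A *segment* is one individual's called interval on one array by one
detection program; gains (duplications) and losses (deletions) are
discriminated but integer copy numbers are optional and never required.

File formats handled here are plain tab-separated text:

* call sets     — chrom, start, end, type(gain|loss), sample, program, array
                  [, copy_number], header line allowed;
* probe maps    — chrom, position;
* genomes       — chrom, length;
* pedigrees     — offspring, father, mother;
* replicates    — sample, comma-separated array ids;
* annotations   — BED4 with the repeat class in the name column;
* score tracks  — bedGraph (chrom, start, end, value).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

GAIN = "gain"
LOSS = "loss"
CNV_TYPES = (GAIN, LOSS)

#: Repeat / feature classes understood by the annotation machinery.
FEATURE_CLASSES = (
    "segdup",
    "LINE",
    "SINE",
    "LTR",
    "simple_repeat",
    "mobile_element",
    "CpG_island",
)
#: Transposon-derived classes pooled into the "ALL interspersed" category.
INTERSPERSED_CLASSES = ("LINE", "SINE", "LTR")


class FormatError(ValueError):
    """A file did not conform to the expected tabular layout."""


class RecordError(ValueError):
    """A single record violated an invariant (carries the line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


# ---------------------------------------------------------------------------
# genome & probes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass
class ProbeMap:
    """Sorted array probe positions per chromosome (0-based bp).

    Probe *rank* — the number of probes at or before a position — is the
    distance unit for region clustering: array resolution, not bp, determines
    whether two boundary estimates are "the same".
    """

    positions: dict[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError("probe positions must be 1-D")
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError(f"probe positions not strictly increasing on {chrom}")
            if arr.size and arr[0] < 0:
                raise ValueError(f"negative probe position on {chrom}")
            clean[chrom] = arr
        self.positions = clean

    def validate_against(self, genome: GenomeModel) -> None:
        for chrom, arr in self.positions.items():
            if arr.size and arr[-1] >= genome.length(chrom):
                raise ValueError(f"probe beyond chromosome end on {chrom}")

    def n_probes(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.positions[chrom].size)
        return int(sum(a.size for a in self.positions.values()))


# ---------------------------------------------------------------------------
# segments and call sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNVSegment:
    """One called copy-number segment (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    cnv_type: str
    sample_id: str
    program_id: str
    array_id: str = "0"
    copy_number: int | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"start >= end ({self.start} >= {self.end})")
        if self.start < 0:
            raise ValueError("negative start")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be one of {CNV_TYPES}, got {self.cnv_type!r}")
        if self.copy_number is not None:
            # diploid baseline: gains are >2 copies, losses <2
            if self.cnv_type == GAIN and self.copy_number <= 2:
                raise ValueError(f"gain with copy_number {self.copy_number} <= 2")
            if self.cnv_type == LOSS and self.copy_number >= 2:
                raise ValueError(f"loss with copy_number {self.copy_number} >= 2")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.program_id, self.array_id)


class CallSet:
    """A collection of :class:`CNVSegment` indexed by (sample, program, array).

    ``samples`` may declare the full roster (so a sample with zero calls is
    still *present*, which the trio statistics need to distinguish from a
    sample that was never run).
    """

    def __init__(self, segments: Iterable[CNVSegment], samples: Iterable[str] | None = None):
        self._segments: list[CNVSegment] = list(segments)
        self._index: dict[tuple[str, str, str], list[CNVSegment]] = {}
        for seg in self._segments:
            self._index.setdefault(seg.key, []).append(seg)
        for segs in self._index.values():
            segs.sort(key=lambda s: (s.chrom, s.start, s.end))
        declared = set(samples) if samples is not None else set()
        self._samples = declared | {s.sample_id for s in self._segments}

    def __len__(self) -> int:
        return len(self._segments)

    def __iter__(self) -> Iterator[CNVSegment]:
        return iter(self._segments)

    @property
    def segments(self) -> list[CNVSegment]:
        return list(self._segments)

    @property
    def samples(self) -> set[str]:
        return set(self._samples)

    @property
    def programs(self) -> set[str]:
        return {s.program_id for s in self._segments}

    def arrays_for(self, sample_id: str, program_id: str | None = None) -> set[str]:
        return {
            a
            for (s, p, a) in self._index
            if s == sample_id and (program_id is None or p == program_id)
        }

    def get(
        self,
        sample_id: str | None = None,
        program_id: str | None = None,
        array_id: str | None = None,
        cnv_type: str | None = None,
    ) -> list[CNVSegment]:
        """Segments matching every given key, sorted by (chrom, start)."""
        out = [
            seg
            for seg in self._segments
            if (sample_id is None or seg.sample_id == sample_id)
            and (program_id is None or seg.program_id == program_id)
            and (array_id is None or seg.array_id == array_id)
            and (cnv_type is None or seg.cnv_type == cnv_type)
        ]
        out.sort(key=lambda s: (s.chrom, s.start, s.end))
        return out

    def counts_by_type(self) -> dict[str, int]:
        counts = {GAIN: 0, LOSS: 0}
        for seg in self._segments:
            counts[seg.cnv_type] += 1
        return counts

    def count_per_sample(self, program_id: str) -> dict[str, int]:
        counts: dict[str, int] = {s: 0 for s in self._samples}
        for seg in self._segments:
            if seg.program_id == program_id:
                counts[seg.sample_id] += 1
        return counts

    def subset(self, **kwargs) -> "CallSet":
        return CallSet(self.get(**kwargs))


@dataclass
class PedigreeTable:
    """Trio structure plus replicate-array grouping of a cohort."""

    trios: list[tuple[str, str, str]] = field(default_factory=list)  # (offspring, father, mother)
    replicate_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for off, fa, mo in self.trios:
            if off in (fa, mo):
                raise ValueError(f"sample {off!r} is its own parent")
        for sample, arrays in self.replicate_groups.items():
            if not arrays:
                raise ValueError(f"empty replicate list for sample {sample!r}")


# ---------------------------------------------------------------------------
# annotation and score tracks
# ---------------------------------------------------------------------------


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of possibly-overlapping sorted intervals."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    ms, me = [s[0]], [e[0]]
    for i in range(1, s.size):
        if s[i] <= me[-1]:
            me[-1] = max(me[-1], e[i])
        else:
            ms.append(s[i])
            me.append(e[i])
    return np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64)


class AnnotationTrack:
    """A class-labelled set of genomic intervals (e.g. RepeatMasker LINEs)."""

    def __init__(self, name: str, feature_class: str,
                 intervals: Iterable[tuple[str, int, int]]):
        if feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {feature_class!r}")
        self.name = name
        self.feature_class = feature_class
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end or start < 0:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e in ivs], dtype=np.int64)
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._merged[chrom] = _merge_intervals(starts, ends)

    def __len__(self) -> int:
        return int(sum(a.size for a in self._starts.values()))

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._starts):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append((chrom, int(s), int(e)))
        return out

    def intersects(self, chrom: str, start: int, end: int) -> bool:
        """True iff any interval of the track overlaps [start, end)."""
        if chrom not in self._merged:
            return False
        ms, me = self._merged[chrom]
        i = int(np.searchsorted(ms, end, side="left")) - 1
        # merged intervals are disjoint, so ends are increasing too: the
        # rightmost interval starting before `end` is the only candidate.
        return i >= 0 and me[i] > start

    def count_intersecting(self, windows: Sequence[tuple[str, int, int]]) -> int:
        """Number of *track features* that overlap at least one window."""
        win_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in windows:
            win_by_chrom.setdefault(chrom, []).append((s, e))
        total = 0
        for chrom, wins in win_by_chrom.items():
            if chrom not in self._starts:
                continue
            wins.sort()
            ws = np.array([s for s, _ in wins], dtype=np.int64)
            we = np.array([e for _, e in wins], dtype=np.int64)
            mws, mwe = _merge_intervals(ws, we)
            fs, fe = self._starts[chrom], self._ends[chrom]
            idx = np.searchsorted(mws, fe, side="left") - 1
            ok = idx >= 0
            hit = np.zeros(fs.size, dtype=bool)
            hit[ok] = mwe[idx[ok]] > fs[ok]
            total += int(hit.sum())
        return total

    def min_length_filtered(self, min_length: int) -> "AnnotationTrack":
        """A copy keeping only intervals of at least ``min_length`` bp."""
        kept = [(c, s, e) for c, s, e in self.intervals() if e - s >= min_length]
        return AnnotationTrack(self.name, self.feature_class, kept)


class ScoreTrack:
    """Stepwise numeric genomic track (bedGraph semantics).

    Records are non-overlapping per chromosome; bases not covered by any
    record are missing and excluded from averages.
    """

    def __init__(self, name: str,
                 records: Iterable[tuple[str, int, int, float]]):
        self.name = name
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if start >= end or start < 0:
                raise ValueError(f"invalid record {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping score records on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = np.array([r[2] for r in recs], dtype=float)

    def records(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in sorted(self._starts):
            for s, e, v in zip(self._starts[chrom], self._ends[chrom], self._values[chrom]):
                out.append((chrom, int(s), int(e), float(v)))
        return out

    def window_mean(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """Length-weighted mean over covered bases of [start, end).

        Returns ``(mean, covered_bp)``; mean is ``nan`` when nothing is
        covered.
        """
        if chrom not in self._starts or start >= end:
            return float("nan"), 0
        s, e, v = self._starts[chrom], self._ends[chrom], self._values[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        if lo >= hi:
            return float("nan"), 0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        ov = np.clip(ov, 0, None)
        covered = int(ov.sum())
        if covered == 0:
            return float("nan"), 0
        return float(np.dot(ov, v[lo:hi]) / covered), covered


# ---------------------------------------------------------------------------
# interval primitives
# ---------------------------------------------------------------------------

IntervalLike = tuple[str, int, int]


def _as_interval(x) -> IntervalLike:
    if isinstance(x, tuple):
        return x
    return (x.chrom, x.start, x.end)


def overlap_bp(a, b) -> int:
    """Length of the intersection of two intervals in bp (0 if disjoint
    or on different chromosomes)."""
    ca, sa, ea = _as_interval(a)
    cb, sb, eb = _as_interval(b)
    if ca != cb:
        return 0
    return max(0, min(ea, eb) - max(sa, sb))


def overlap_fraction(query, target, mode: str = "query") -> float:
    """Overlap as a fraction of the query length, or (reciprocal mode) the
    minimum of both directions."""
    ov = overlap_bp(query, target)
    _, qs, qe = _as_interval(query)
    _, ts, te = _as_interval(target)
    if mode == "query":
        return ov / (qe - qs)
    if mode == "reciprocal":
        return min(ov / (qe - qs), ov / (te - ts))
    raise ValueError(f"unknown overlap mode {mode!r}")


def _type_compatible(q: CNVSegment, t: CNVSegment, type_policy: str) -> bool:
    if type_policy == "strict":
        return q.cnv_type == t.cnv_type
    if type_policy == "collapse":
        return True
    raise ValueError(f"unknown type_policy {type_policy!r}")


def build_target_index(targets: Sequence[CNVSegment]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over target segments."""
    trees: dict[str, IntervalTree] = {}
    for seg in targets:
        trees.setdefault(seg.chrom, IntervalTree()).addi(seg.start, seg.end, seg)
    return trees


def match_segments(
    query: Sequence[CNVSegment],
    target: Sequence[CNVSegment],
    threshold: float,
    mode: str = "query",
    type_policy: str = "strict",
    target_index: Mapping[str, IntervalTree] | None = None,
) -> np.ndarray:
    """Boolean flag per query segment: is it matched by some target segment
    of compatible type with overlap fraction strictly greater than
    ``threshold``?

    Matching is independent per query: one target may match many queries.
    The strict inequality reproduces the "> 80%" concordance rule; at
    threshold 0 any 1-bp overlap matches.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    trees = target_index if target_index is not None else build_target_index(target)
    flags = np.zeros(len(query), dtype=bool)
    for i, q in enumerate(query):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(q.start, q.end):
            t: CNVSegment = iv.data
            if not _type_compatible(q, t, type_policy):
                continue
            if overlap_fraction(q, t, mode) > threshold:
                flags[i] = True
                break
    return flags


def merge_same_type_segments(segments: Sequence[CNVSegment]) -> list[CNVSegment]:
    """Optional pre-merge: union overlapping same-type segments within one
    (sample, program, array).  Merging changes counts, so it is never
    applied implicitly."""
    groups: dict[tuple, list[CNVSegment]] = {}
    for seg in segments:
        groups.setdefault((seg.key, seg.chrom, seg.cnv_type), []).append(seg)
    out: list[CNVSegment] = []
    for (key, chrom, cnv_type), segs in groups.items():
        segs.sort(key=lambda s: s.start)
        cur_s, cur_e = segs[0].start, segs[0].end
        proto = segs[0]
        for seg in segs[1:]:
            if seg.start <= cur_e:
                cur_e = max(cur_e, seg.end)
            else:
                out.append(CNVSegment(chrom, cur_s, cur_e, cnv_type,
                                      proto.sample_id, proto.program_id, proto.array_id))
                cur_s, cur_e = seg.start, seg.end
        out.append(CNVSegment(chrom, cur_s, cur_e, cnv_type,
                              proto.sample_id, proto.program_id, proto.array_id))
    out.sort(key=lambda s: (s.sample_id, s.program_id, s.array_id, s.chrom, s.start))
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_CALLSET_COLUMNS = ("chrom", "start", "end", "type", "sample", "program", "array")


def _open_text(path) -> io.TextIOBase:
    return open(path, "r", encoding="utf-8")


def read_callset(path, samples: Iterable[str] | None = None) -> CallSet:
    """Read a tab-separated BED-like call file.

    Columns: chrom, start, end, type(gain|loss), sample, program, array
    [, copy_number].  A header line naming the columns is allowed and
    detected by the literal column names.
    """
    segments: list[CNVSegment] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[: len(_CALLSET_COLUMNS)] == list(_CALLSET_COLUMNS):
                continue
            if len(fields) < len(_CALLSET_COLUMNS):
                missing = _CALLSET_COLUMNS[len(fields)]
                raise FormatError(
                    f"{path}: line {lineno}: missing column {missing!r}"
                )
            chrom, start, end, cnv_type, sample, program, array = fields[:7]
            copy_number = None
            if len(fields) > 7 and fields[7] not in ("", "."):
                copy_number = int(fields[7])
            try:
                seg = CNVSegment(chrom, int(start), int(end), cnv_type,
                                 sample, program, array, copy_number)
            except ValueError as exc:
                raise RecordError(str(exc), line=lineno) from exc
            segments.append(seg)
    return CallSet(segments, samples=samples)


def write_callset(callset: CallSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CALLSET_COLUMNS + ("copy_number",)) + "\n")
        segs = sorted(callset, key=lambda s: (s.sample_id, s.program_id,
                                              s.array_id, s.chrom, s.start, s.end))
        for s in segs:
            cn = "" if s.copy_number is None else str(s.copy_number)
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.cnv_type}\t"
                     f"{s.sample_id}\t{s.program_id}\t{s.array_id}\t{cn}\n")


def read_probe_map(path) -> ProbeMap:
    by_chrom: dict[str, list[int]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: need chrom and position")
            by_chrom.setdefault(fields[0], []).append(int(fields[1]))
    return ProbeMap({c: np.array(sorted(p), dtype=np.int64) for c, p in by_chrom.items()})


def write_probe_map(probes: ProbeMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tposition\n")
        for chrom in sorted(probes.positions):
            for pos in probes.positions[chrom]:
                fh.write(f"{chrom}\t{pos}\n")


def read_genome(path) -> GenomeModel:
    chroms: list[tuple[str, int]] = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            name, length = line.split("\t")[:2]
            chroms.append((name, int(length)))
    return GenomeModel(tuple(chroms))


def write_genome(genome: GenomeModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tlength\n")
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_pedigree(trios_path, replicates_path=None) -> PedigreeTable:
    trios: list[tuple[str, str, str]] = []
    with _open_text(trios_path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("offspring\t"):
                continue
            off, fa, mo = line.split("\t")[:3]
            trios.append((off, fa, mo))
    groups: dict[str, list[str]] = {}
    if replicates_path is not None:
        with _open_text(replicates_path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#") or line.startswith("sample\t"):
                    continue
                sample, arrays = line.split("\t")[:2]
                groups[sample] = arrays.split(",")
    return PedigreeTable(trios=trios, replicate_groups=groups)


def write_pedigree(ped: PedigreeTable, trios_path, replicates_path=None) -> None:
    with open(trios_path, "w", encoding="utf-8") as fh:
        fh.write("offspring\tfather\tmother\n")
        for off, fa, mo in ped.trios:
            fh.write(f"{off}\t{fa}\t{mo}\n")
    if replicates_path is not None:
        with open(replicates_path, "w", encoding="utf-8") as fh:
            fh.write("sample\tarrays\n")
            for sample in sorted(ped.replicate_groups):
                fh.write(f"{sample}\t{','.join(ped.replicate_groups[sample])}\n")


def read_annotation_track(path, feature_class: str, name: str | None = None) -> AnnotationTrack:
    """BED4 reader; the name column is informational, the class is declared."""
    intervals: list[tuple[str, int, int]] = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return AnnotationTrack(name or feature_class, feature_class, intervals)


def write_annotation_track(track: AnnotationTrack, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, (chrom, s, e) in enumerate(track.intervals()):
            fh.write(f"{chrom}\t{s}\t{e}\t{track.feature_class}_{i}\n")


def read_score_track(path, name: str | None = None) -> ScoreTrack:
    records: list[tuple[str, int, int, float]] = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return ScoreTrack(name or str(path), records)


def write_score_track(track: ScoreTrack, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, s, e, v in track.records():
            fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def write_regions_bed(regions, path) -> None:
    """BED5: chrom, start, end, region id, individual count."""
    with open(path, "w", encoding="utf-8") as fh:
        for region in regions:
            fh.write(f"{region.chrom}\t{region.start}\t{region.end}\t"
                     f"{region.region_id}\t{region.n_individuals}\n")


def read_regions_bed(path) -> list[tuple[str, int, int, str, int]]:
    out = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            chrom, s, e, name, score = line.split("\t")[:5]
            out.append((chrom, int(s), int(e), name, int(score)))
    return out
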