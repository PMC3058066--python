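"""Population-level CNV region clustering on the probe-rank scale.

Individual call boundaries jitter by a few array probes, so segments from
different individuals that describe the same variant rarely share exact
coordinates.  Segments are therefore clustered by *probe-rank* distance:
two same-chromosome, same-type segments link when both their start ranks
and their end ranks differ by at most ``k_probes`` (default 20 — boundary
agreement is judged in units of array resolution, not bp).  Single-linkage
components become CNV regions whose consensus interval is the member-wise
median start/end.

Selectors derive the commonality strata used downstream:

* ``select_common1`` — regions detected by at least two programs;
* ``select_common2`` — anchor-program regions seen in at least five
  individuals and corroborated by at least one other program;
* ``stratify_by_individual_count`` — regions in strictly more than k
  individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import CallSet, CNVSegment, ProbeMap


@dataclass(frozen=True)
class CNVRegion:
    """A clustered population CNV region."""

    region_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    members: tuple[CNVSegment, ...]
    n_individuals: int
    programs: frozenset[str]
    frequency: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def sample_ids(self) -> frozenset[str]:
        return frozenset(s.sample_id for s in self.members)


def probe_rank(probe_map: ProbeMap, chrom: str, position: int) -> int:
    """Number of probes at position <= the query position (0 before the
    first probe)."""
    try:
        positions = probe_map.positions[chrom]
    except KeyError:
        raise KeyError(f"unknown chromosome {chrom!r} in probe map") from None
    return int(np.searchsorted(positions, position, side="right"))


def _lower_median(values: np.ndarray) -> int:
    """Median with ties broken toward the smaller coordinate."""
    s = np.sort(values)
    return int(s[(s.size - 1) // 2])


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _cluster_items(
    chroms: Sequence[str],
    types: Sequence[str],
    start_ranks: np.ndarray,
    end_ranks: np.ndarray,
    k_probes: int,
) -> list[list[int]]:
    """Single-linkage components under the two-sided rank rule.

    Items are processed in sorted (chrom, type, start rank) order; since a
    link requires |Δ start rank| <= k, only neighbours within k start ranks
    need inspection, which keeps the scan near-linear and makes the result
    independent of input order.
    """
    n = len(chroms)
    order = sorted(range(n), key=lambda i: (chroms[i], types[i],
                                            start_ranks[i], end_ranks[i]))
    uf = _UnionFind(n)
    for ii, i in enumerate(order):
        for j in order[ii + 1:]:
            if chroms[j] != chroms[i] or types[j] != types[i]:
                break
            if start_ranks[j] - start_ranks[i] > k_probes:
                break
            if abs(int(end_ranks[j]) - int(end_ranks[i])) <= k_probes:
                uf.union(i, j)
    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)
    return list(components.values())


def cluster_regions(
    segments: Sequence[CNVSegment],
    probe_map: ProbeMap,
    k_probes: int = 20,
    cohort_size: int | None = None,
    id_prefix: str = "region",
) -> list[CNVRegion]:
    """Cluster per-individual segments into population CNV regions.

    Two segments belong to the same region when a single-linkage chain of
    pairs connects them, where a pair links iff same chromosome, same
    gain/loss type, |Δ probe rank of start| <= k AND |Δ probe rank of end|
    <= k.  The consensus interval is the member-wise median start / median
    end (ties toward the smaller coordinate).  Output is sorted by
    (chrom, start) and region ids are assigned in that order.
    """
    segments = list(segments)
    if not segments:
        return []
    chroms = [s.chrom for s in segments]
    types = [s.cnv_type for s in segments]
    start_ranks = np.array([probe_rank(probe_map, s.chrom, s.start) for s in segments])
    end_ranks = np.array([probe_rank(probe_map, s.chrom, s.end - 1) for s in segments])
    components = _cluster_items(chroms, types, start_ranks, end_ranks, k_probes)

    regions = []
    for comp in components:
        members = tuple(sorted((segments[i] for i in comp),
                               key=lambda s: (s.sample_id, s.program_id,
                                              s.array_id, s.start, s.end)))
        starts = np.array([m.start for m in members])
        ends = np.array([m.end for m in members])
        start = _lower_median(starts)
        end = _lower_median(ends)
        if end <= start:  # degenerate after medians of crossing members
            end = int(ends.max())
        samples = {m.sample_id for m in members}
        regions.append(CNVRegion(
            region_id="",
            chrom=members[0].chrom,
            start=start,
            end=end,
            cnv_type=members[0].cnv_type,
            members=members,
            n_individuals=len(samples),
            programs=frozenset(m.program_id for m in members),
            frequency=len(samples) / cohort_size if cohort_size else None,
        ))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end, r.cnv_type))
    return [
        CNVRegion(**{**r.__dict__, "region_id": f"{id_prefix}_{i + 1}"})
        for i, r in enumerate(regions)
    ]


def _region_ranks(regions: Sequence[CNVRegion], probe_map: ProbeMap):
    start_ranks = np.array([probe_rank(probe_map, r.chrom, r.start) for r in regions])
    end_ranks = np.array([probe_rank(probe_map, r.chrom, r.end - 1) for r in regions])
    return start_ranks, end_ranks


def regions_linked(a: CNVRegion, b: CNVRegion, probe_map: ProbeMap,
                   k_probes: int = 20) -> bool:
    """Do two regions satisfy the same-region linkage rule?"""
    if a.chrom != b.chrom or a.cnv_type != b.cnv_type:
        return False
    return (
        abs(probe_rank(probe_map, a.chrom, a.start)
            - probe_rank(probe_map, b.chrom, b.start)) <= k_probes
        and abs(probe_rank(probe_map, a.chrom, a.end - 1)
                - probe_rank(probe_map, b.chrom, b.end - 1)) <= k_probes
    )


def select_common1(
    regions_by_program: Mapping[str, Sequence[CNVRegion]],
    probe_map: ProbeMap,
    k_probes: int = 20,
    cohort_size: int | None = None,
) -> list[CNVRegion]:
    """Regions detected by at least two programs.

    Per-program regions are pooled and re-clustered with the same linkage
    rule; merged clusters whose member segments come from >= 2 distinct
    programs are kept.  The returned regions are the merged clusters (their
    members are the union of the contributing per-program members).
    """
    if len(regions_by_program) < 2:
        raise ValueError("select_common1 needs regions from at least 2 programs")
    pooled = [r for regs in regions_by_program.values() for r in regs]
    if not pooled:
        return []
    chroms = [r.chrom for r in pooled]
    types = [r.cnv_type for r in pooled]
    start_ranks, end_ranks = _region_ranks(pooled, probe_map)
    components = _cluster_items(chroms, types, start_ranks, end_ranks, k_probes)
    merged = []
    for comp in components:
        cluster = [pooled[i] for i in comp]
        programs = frozenset(p for r in cluster for p in r.programs)
        if len(programs) < 2:
            continue
        members = tuple(sorted((m for r in cluster for m in r.members),
                               key=lambda s: (s.sample_id, s.program_id,
                                              s.array_id, s.start, s.end)))
        starts = np.array([r.start for r in cluster])
        ends = np.array([r.end for r in cluster])
        samples = {m.sample_id for m in members}
        merged.append(CNVRegion(
            region_id="",
            chrom=cluster[0].chrom,
            start=_lower_median(starts),
            end=max(_lower_median(ends), _lower_median(starts) + 1),
            cnv_type=cluster[0].cnv_type,
            members=members,
            n_individuals=len(samples),
            programs=programs,
            frequency=len(samples) / cohort_size if cohort_size else None,
        ))
    merged.sort(key=lambda r: (r.chrom, r.start, r.end, r.cnv_type))
    return [
        CNVRegion(**{**r.__dict__, "region_id": f"common1_{i + 1}"})
        for i, r in enumerate(merged)
    ]


def select_common2(
    regions_by_program: Mapping[str, Sequence[CNVRegion]],
    probe_map: ProbeMap,
    anchor_program: str = "PennCNV-like",
    min_individuals: int = 5,
    k_probes: int = 20,
) -> list[CNVRegion]:
    """Anchor-program regions seen in >= ``min_individuals`` individuals and
    corroborated (linkage rule) by at least one region of another program."""
    if anchor_program not in regions_by_program:
        raise ValueError(f"anchor program {anchor_program!r} absent")
    anchors = list(regions_by_program[anchor_program])
    others = [r for prog, regs in regions_by_program.items()
              if prog != anchor_program for r in regs]
    selected = []
    for region in anchors:
        if region.n_individuals < min_individuals:
            continue
        if any(regions_linked(region, other, probe_map, k_probes) for other in others):
            selected.append(region)
    selected.sort(key=lambda r: (r.chrom, r.start, r.end, r.cnv_type))
    return selected


def stratify_by_individual_count(
    regions: Sequence[CNVRegion],
    min_individuals: int,
) -> list[CNVRegion]:
    """Regions present in strictly more than ``min_individuals``
    individuals ("more than k" is a strict inequality)."""
    return [r for r in regions if r.n_individuals > min_individuals]


def regions_to_callset(regions: Sequence[CNVRegion],
                       program_id: str = "regions",
                       sample_id: str = "pooled") -> CallSet:
    """Flatten region consensus intervals into a pooled pseudo call set,
    e.g. for whole-level overlap-ratio comparisons."""
    segs = [
        CNVSegment(r.chrom, r.start, r.end, r.cnv_type,
                   sample_id, program_id, "0")
        for r in regions
    ]
    return CallSet(segs)
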