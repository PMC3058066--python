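"""Concordance statistics for CNV call sets.

The statistics here quantify how well array-based CNV calls agree with
themselves and with external truth:

* replicate **stability** — fraction of one replicate array's segments found
  again on another replicate of the same individual;
* trio **Mendelian inconsistency** — fraction of an offspring's CNVs not
  detected in either parent (an inherited CNV must come from one parent, so
  a match in *either* parent counts as consistent);
* **pairwise similarity** between detection programs (the asymmetric
  sensitivity of program A's calls against program B's);
* **sensitivity/specificity** against a reference call set treated as a gold
  standard, per individual;
* **pooled overlap ratio** — the same comparison with sample identity
  ignored (all segments pooled across the cohort);
* per-program CNV **length distributions**.

All matching goes through :func:`cnveval.model.match_segments` with a strict
"> threshold" overlap rule; the conventional threshold grid is
{0, 0.5, 0.8}.  Rates with empty denominators are excluded from averages and
counted, never coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CallSet,
    CNVSegment,
    LOSS,
    PedigreeTable,
    build_target_index,
    match_segments,
)

#: Overlap thresholds used throughout the concordance tables.
DEFAULT_THRESHOLDS = (0.0, 0.5, 0.8)


@dataclass
class EvaluationReport:
    """One evaluation statistic with its provenance.

    ``value`` is ``None`` when the denominator is zero (undefined, never
    silently 0).  ``group`` carries the grouping keys (program, threshold,
    subset, ...); ``extra`` carries secondary numbers such as the pooled
    variant of a per-sample mean.
    """

    statistic: str
    value: float | None
    numerator: float
    denominator: float
    n_excluded: int = 0
    group: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.value is not None

    def as_row(self) -> dict:
        row = {"statistic": self.statistic}
        row.update(self.group)
        row.update(
            value=self.value,
            numerator=self.numerator,
            denominator=self.denominator,
            n_excluded=self.n_excluded,
        )
        return row


def _matched_fraction(
    query: Sequence[CNVSegment],
    target: Sequence[CNVSegment],
    threshold: float,
    mode: str,
    type_policy: str,
) -> tuple[int, int]:
    """(matched, total) for query against target."""
    if not query:
        return 0, 0
    flags = match_segments(query, target, threshold, mode, type_policy)
    return int(flags.sum()), len(query)


# ---------------------------------------------------------------------------
# replicate stability (Table-1 style)
# ---------------------------------------------------------------------------


def stability_rate(
    callset: CallSet,
    sample_id: str,
    array_ids: Sequence[str],
    program_id: str,
    threshold: float = 0.8,
    mode: str = "query",
    type_policy: str = "strict",
) -> EvaluationReport:
    """Mean concordance over all ordered pairs of replicate arrays.

    For each ordered pair (A, B) of distinct replicates the rate is the
    fraction of A's segments matched in B; pairs whose query array has no
    segments are excluded from the mean and counted.
    """
    if len(array_ids) < 2:
        raise ValueError(f"need at least 2 replicate arrays for {sample_id!r}, "
                         f"got {len(array_ids)}")
    per_array = {
        a: callset.get(sample_id=sample_id, program_id=program_id, array_id=a)
        for a in array_ids
    }
    indexes = {a: build_target_index(segs) for a, segs in per_array.items()}
    rates: list[float] = []
    num = den = 0
    n_excluded = 0
    for a in array_ids:
        for b in array_ids:
            if a == b:
                continue
            query = per_array[a]
            if not query:
                n_excluded += 1
                continue
            flags = match_segments(query, per_array[b], threshold, mode,
                                   type_policy, target_index=indexes[b])
            rates.append(float(flags.mean()))
            num += int(flags.sum())
            den += len(query)
    value = float(np.mean(rates)) if rates else None
    return EvaluationReport(
        statistic="stability_rate",
        value=value,
        numerator=num,
        denominator=den,
        n_excluded=n_excluded,
        group={"program": program_id, "sample": sample_id, "threshold": threshold},
        extra={"n_pairs": len(rates), "mode": mode, "type_policy": type_policy},
    )


def stability_table(
    callset: CallSet,
    pedigree: PedigreeTable,
    programs: Sequence[str] | None = None,
    threshold: float = 0.8,
    mode: str = "query",
    type_policy: str = "strict",
) -> pd.DataFrame:
    """Per-program average stability over all replicate groups (Table-1
    shape).  Samples with fewer than 2 replicate arrays are skipped."""
    programs = sorted(programs or callset.programs)
    rows = []
    for program in programs:
        per_sample = []
        for sample, arrays in sorted(pedigree.replicate_groups.items()):
            if len(arrays) < 2:
                continue
            rep = stability_rate(callset, sample, arrays, program,
                                 threshold, mode, type_policy)
            if rep.defined:
                per_sample.append(rep.value)
        rows.append({
            "program": program,
            "threshold": threshold,
            "value": float(np.mean(per_sample)) if per_sample else None,
            "n_samples": len(per_sample),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mendelian inconsistency (Table-2 style)
# ---------------------------------------------------------------------------


def mendelian_inconsistency(
    callset: CallSet,
    trios: PedigreeTable,
    program_id: str,
    threshold: float = 0.8,
    mode: str = "query",
    type_policy: str = "strict",
) -> EvaluationReport:
    """Mean per-trio rate of offspring CNVs detected in neither parent.

    An offspring segment is consistent iff a compatible-type segment in the
    father *or* the mother matches it at the threshold ("not detected in
    both parents" is read as detected in neither; an inherited CNV comes
    from one parent).  Offspring with zero segments are excluded from the
    mean and counted.  Arrays are pooled per sample.
    """
    if not trios.trios:
        raise ValueError("pedigree has no trios")
    rates = []
    num = den = 0
    n_excluded = 0
    for off, fa, mo in trios.trios:
        for member in (off, fa, mo):
            if member not in callset.samples:
                raise KeyError(f"trio member {member!r} absent from call set")
        off_segs = callset.get(sample_id=off, program_id=program_id)
        if not off_segs:
            n_excluded += 1
            continue
        parent_segs = (callset.get(sample_id=fa, program_id=program_id)
                       + callset.get(sample_id=mo, program_id=program_id))
        flags = match_segments(off_segs, parent_segs, threshold, mode, type_policy)
        inconsistent = len(off_segs) - int(flags.sum())
        rates.append(inconsistent / len(off_segs))
        num += inconsistent
        den += len(off_segs)
    value = float(np.mean(rates)) if rates else None
    return EvaluationReport(
        statistic="mendelian_inconsistency",
        value=value,
        numerator=num,
        denominator=den,
        n_excluded=n_excluded,
        group={"program": program_id, "threshold": threshold},
        extra={"n_trios": len(rates), "averaging": "per-trio",
               "consistency_rule": "match in either parent"},
    )


def mendelian_table(
    callset: CallSet,
    trios: PedigreeTable,
    programs: Sequence[str] | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    mode: str = "query",
    type_policy: str = "strict",
) -> pd.DataFrame:
    """Program × threshold grid of Mendelian inconsistency (Table-2 shape)."""
    programs = sorted(programs or callset.programs)
    rows = []
    for program in programs:
        for thr in thresholds:
            rep = mendelian_inconsistency(callset, trios, program, thr,
                                          mode, type_policy)
            rows.append(rep.as_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise program similarity (Table-3 style)
# ---------------------------------------------------------------------------


def pairwise_similarity(
    callset: CallSet,
    program_a: str,
    program_b: str,
    threshold: float = 0.8,
    subset: str = "all",
    mode: str = "query",
    type_policy: str = "strict",
) -> EvaluationReport:
    """Fraction of program A's segments matched by program B, per shared
    sample.  Asymmetric by construction: this is the sensitivity of B with
    A's calls as queries.  ``subset="deletions"`` restricts to losses.
    ``value`` is the per-sample mean; the pooled fraction is in
    ``extra["pooled"]``.
    """
    if subset not in ("all", "deletions"):
        raise ValueError(f"unknown subset {subset!r}")
    for p in (program_a, program_b):
        if p not in callset.programs:
            raise ValueError(f"program {p!r} not present in call set")
    samples_a = {s.sample_id for s in callset if s.program_id == program_a}
    samples_b = {s.sample_id for s in callset if s.program_id == program_b}
    shared = sorted(samples_a & samples_b)
    if not shared:
        raise ValueError(f"no shared samples between {program_a!r} and {program_b!r}")
    cnv_type = LOSS if subset == "deletions" else None
    per_sample = []
    num = den = 0
    n_excluded = 0
    for sample in shared:
        query = callset.get(sample_id=sample, program_id=program_a, cnv_type=cnv_type)
        target = callset.get(sample_id=sample, program_id=program_b)
        if not query:
            n_excluded += 1
            continue
        matched, total = _matched_fraction(query, target, threshold, mode, type_policy)
        per_sample.append(matched / total)
        num += matched
        den += total
    value = float(np.mean(per_sample)) if per_sample else None
    return EvaluationReport(
        statistic="pairwise_similarity",
        value=value,
        numerator=num,
        denominator=den,
        n_excluded=n_excluded,
        group={"program_a": program_a, "program_b": program_b,
               "threshold": threshold, "subset": subset},
        extra={"pooled": num / den if den else None, "n_samples": len(per_sample)},
    )


def similarity_matrix(
    callset: CallSet,
    programs: Sequence[str] | None = None,
    threshold: float = 0.8,
    subset: str = "all",
    mode: str = "query",
    type_policy: str = "strict",
) -> pd.DataFrame:
    """All ordered program pairs (Table-3 shape); rows are queries."""
    programs = sorted(programs or callset.programs)
    rows = []
    for a in programs:
        for b in programs:
            if a == b:
                continue
            rep = pairwise_similarity(callset, a, b, threshold, subset,
                                      mode, type_policy)
            rows.append(rep.as_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity against a reference call set (Table-4 style)
# ---------------------------------------------------------------------------


def reference_sensitivity(
    callset: CallSet,
    reference: CallSet,
    program_id: str,
    shared_samples: Sequence[str] | None = None,
    threshold: float = 0.8,
    mode: str = "query",
    type_policy: str = "strict",
) -> tuple[EvaluationReport, EvaluationReport]:
    """Per-sample sensitivity and specificity against a reference standard.

    Sensitivity: fraction of reference segments matched by the program's
    calls, averaged over shared samples.  Specificity: fraction of the
    program's segments matched by the reference.  Samples contributing an
    empty denominator are excluded and counted; a statistic with no defined
    sample at all is flagged undefined (value ``None``).
    """
    if shared_samples is None:
        shared_samples = sorted(callset.samples & reference.samples)
    if not shared_samples:
        raise ValueError("no shared samples between calls and reference")

    def _one_direction(stat: str, queries_from: CallSet, targets_from: CallSet):
        per_sample, num, den, n_excluded = [], 0, 0, 0
        for sample in shared_samples:
            q_prog = program_id if queries_from is callset else None
            t_prog = program_id if targets_from is callset else None
            query = queries_from.get(sample_id=sample, program_id=q_prog)
            target = targets_from.get(sample_id=sample, program_id=t_prog)
            if not query:
                n_excluded += 1
                continue
            matched, total = _matched_fraction(query, target, threshold, mode, type_policy)
            per_sample.append(matched / total)
            num += matched
            den += total
        value = float(np.mean(per_sample)) if per_sample else None
        return EvaluationReport(
            statistic=stat, value=value, numerator=num, denominator=den,
            n_excluded=n_excluded,
            group={"program": program_id, "threshold": threshold},
            extra={"pooled": num / den if den else None,
                   "n_samples": len(per_sample)},
        )

    sens = _one_direction("reference_sensitivity", reference, callset)
    spec = _one_direction("reference_specificity", callset, reference)
    return sens, spec


def pooled_overlap_ratio(
    callset: CallSet,
    reference: CallSet,
    threshold: float = 0.8,
    mode: str = "query",
    type_policy: str = "strict",
) -> EvaluationReport:
    """Overlap ratio at the whole-cohort level (Table-5 style).

    All call segments are pooled with sample identity ignored and matched
    against the pooled reference.  Stratified variants (regions detected by
    ≥2 programs, in > k individuals) are produced by pre-filtering the call
    set through the region-clustering selectors and passing the result here.
    """
    query = callset.segments
    target = reference.segments
    if not query:
        return EvaluationReport(
            statistic="pooled_overlap_ratio", value=None, numerator=0,
            denominator=0, group={"threshold": threshold},
        )
    matched, total = _matched_fraction(query, target, threshold, mode, type_policy)
    return EvaluationReport(
        statistic="pooled_overlap_ratio",
        value=matched / total,
        numerator=matched,
        denominator=total,
        group={"threshold": threshold},
        extra={"averaging": "pooled"},
    )


# ---------------------------------------------------------------------------
# length distributions (Figure-1 style)
# ---------------------------------------------------------------------------


def length_distribution(callset: CallSet, bins: Sequence[int]) -> pd.DataFrame:
    """Per-program histogram of segment lengths.

    Returns a tidy frame with columns program, bin_left, bin_right, count and
    per_individual_mean (count divided by the number of samples with any
    call from that program).  ``bins`` are increasing bp edges.
    """
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be increasing edges with at least 2 values")
    rows = []
    for program in sorted(callset.programs) or []:
        segs = callset.get(program_id=program)
        lengths = np.array([s.length for s in segs], dtype=float)
        counts, _ = np.histogram(lengths, bins=edges)
        n_ind = len({s.sample_id for s in segs})
        for i in range(edges.size - 1):
            rows.append({
                "program": program,
                "bin_left": edges[i],
                "bin_right": edges[i + 1],
                "count": int(counts[i]),
                "per_individual_mean": counts[i] / n_ind if n_ind else 0.0,
            })
    columns = ["program", "bin_left", "bin_right", "count", "per_individual_mean"]
    return pd.DataFrame(rows, columns=columns)
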