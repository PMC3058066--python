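"""Array-level quality control for SNP-array CNV cohorts.

Noisy arrays produce inflated CNV counts, so cohorts are filtered on two
signals: the standard deviation of per-probe log2 intensity ratios against a
reference panel, and the per-program CNV count.  Samples whose count exceeds
a per-program ceiling on *any* program are removed (strict >); the default
ceilings are the conventional ones for the five common callers
(PennCNV 250, Birdseye 400, Canary 500, DNAcopy 100, CGHseg 100).

The intensity matrix is probes x arrays of strictly positive raw
intensities; quantile normalization equalises the per-array distributions
before log2 ratios are taken against a reference profile (typically a panel
mean).  Genotype calling and caller-specific normalisation are out of
scope — the call rate, when used, is an externally supplied column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: Conventional per-program CNV-count ceilings (strict >) used to drop
#: noisy individuals.
DEFAULT_COUNT_THRESHOLDS: dict[str, int] = {
    "PennCNV": 250,
    "Birdseye": 400,
    "Canary": 500,
    "DNAcopy": 100,
    "CGHseg": 100,
}


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (arrays) of a probes x arrays matrix.

    Each column's sorted values are replaced by the across-column mean of
    the values at the same rank; ties receive the mean over their rank range
    (implemented as linear interpolation of the reference distribution at
    average ranks, which coincides with the rank-range mean).  Column rank
    order is preserved and the operation is idempotent up to floating
    error.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    values = matrix.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("intensities must be strictly positive")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_ratio(target: pd.Series, reference_profile: pd.Series) -> pd.Series:
    """Per-probe log2 of target intensity over a reference profile
    (e.g. the mean of a normalized reference panel)."""
    if not target.index.equals(reference_profile.index):
        raise ValueError("probe sets of target and reference differ")
    t = target.to_numpy(dtype=float)
    r = reference_profile.to_numpy(dtype=float)
    if np.any(t <= 0) or np.any(r <= 0):
        raise ValueError("intensities must be strictly positive")
    return pd.Series(np.log2(t / r), index=target.index)


def array_sd(log2ratios) -> float:
    """Sample standard deviation (n-1 denominator) of an array's log2
    ratios — the array noise metric."""
    arr = np.asarray(log2ratios, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 probes")
    return float(np.std(arr, ddof=1))


@dataclass
class FilterResult:
    kept: list[str]
    removed: dict[str, list[str]] = field(default_factory=dict)  # sample -> reasons


def filter_individuals(
    counts: Mapping[str, Mapping[str, int]],
    thresholds: Mapping[str, int] | None = None,
) -> FilterResult:
    """Remove samples whose CNV count exceeds the per-program ceiling.

    ``counts`` maps sample -> {program: CNV count}.  A sample is removed iff
    its count strictly exceeds the threshold for any program; a count at the
    threshold is kept.  A program present in ``counts`` but missing from
    ``thresholds`` is an error.
    """
    thresholds = dict(thresholds) if thresholds is not None else dict(DEFAULT_COUNT_THRESHOLDS)
    kept: list[str] = []
    removed: dict[str, list[str]] = {}
    for sample in sorted(counts):
        reasons = []
        for program in sorted(counts[sample]):
            if program not in thresholds:
                raise ValueError(f"no count threshold for program {program!r}")
            count = counts[sample][program]
            limit = thresholds[program]
            if count > limit:
                reasons.append(f"{program} {count} > {limit}")
        if reasons:
            removed[sample] = reasons
        else:
            kept.append(sample)
    return FilterResult(kept=kept, removed=removed)


def qc_report(
    intensities: pd.DataFrame,
    reference_profile: pd.Series,
    counts: Mapping[str, Mapping[str, int]],
    array_to_sample: Mapping[str, str],
    thresholds: Mapping[str, int] | None = None,
    call_rates: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-array QC table: log2-ratio SD, optional call rate, per-program
    CNV counts of the owning sample, and the pass/fail decision."""
    normalized = quantile_normalize(intensities)
    filt = filter_individuals(counts, thresholds)
    rows = []
    for array_id in intensities.columns:
        sample = array_to_sample.get(array_id, array_id)
        ratios = log2_ratio(normalized[array_id], reference_profile)
        row = {
            "array": array_id,
            "sample": sample,
            "log2ratio_sd": array_sd(ratios),
            "call_rate": (call_rates or {}).get(array_id, float("nan")),
            "pass": sample in filt.kept,
            "fail_reasons": ";".join(filt.removed.get(sample, [])),
        }
        for program, count in sorted(counts.get(sample, {}).items()):
            row[f"count_{program}"] = count
        rows.append(row)
    return pd.DataFrame(rows)
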