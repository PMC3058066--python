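"""End-to-end orchestration: simulate -> qc -> evaluate -> cluster -> annotate.

``run_pipeline`` drives every stage on a simulated cohort (or on files
supplied by path), collects tidy DataFrames, and writes both machine TSVs
and human-readable text tables shaped like the seven conventional report
tables of a CNV evaluation study:

1. replicate stability per program,
2. Mendelian inconsistency per program x overlap threshold,
3. pairwise program similarity,
4. per-individual sensitivity/specificity against the reference standard,
5. pooled overlap ratio with commonality stratification,
6. breakpoint-flank repeat containment vs the random null,
7. breakpoint-flank score-track means vs the random null.

In the simulated setting the generator's ground-truth regions play the
reference experiment of tables 4 and 5.  Every output embeds the seed, a
hash of the configuration and the tool version; nothing embeds a
timestamp, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    count_permutation_test,
    enrichment_table,
    flank_windows,
    score_summary,
)
from .clustering import (
    cluster_regions,
    regions_to_callset,
    select_common1,
    select_common2,
    stratify_by_individual_count,
)
from .evaluation import (
    DEFAULT_THRESHOLDS,
    length_distribution,
    mendelian_table,
    pooled_overlap_ratio,
    reference_sensitivity,
    similarity_matrix,
    stability_table,
)
from .model import CallSet, write_regions_bed
from .qc import filter_individuals, qc_report
from .simulate import (
    SimulationConfig,
    World,
    emit_fixture,
    generate_world,
    truth_reference_per_sample,
    truth_regions_as_reference,
)

logger = logging.getLogger("cnveval")

DEFAULT_LENGTH_BINS = (1_000, 10_000, 100_000, 1_000_000, 10_000_000)


@dataclass
class PipelineConfig:
    """Top-level run configuration; per-command CLI flags override it."""

    seed: int
    out_dir: str
    sim: SimulationConfig | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    stability_threshold: float = 0.8
    flank_widths: tuple[int, ...] = (500, 800, 1000)
    k_probes: int = 20
    mode: str = "query"
    type_policy: str = "strict"
    n_perm: int = 300
    anchor_program: str = "PennCNV-like"
    common2_min_individuals: int = 5
    strata: tuple[int, ...] = (2, 9)
    qc_count_threshold: int = 250           # per-program ceiling unless overridden
    qc_thresholds: dict | None = None
    apply_qc_filter: bool = True
    emit_fixture_files: bool = False
    length_bins: tuple[int, ...] = DEFAULT_LENGTH_BINS

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        d.update(overrides)
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return (f"# cnveval v{__version__} seed={config.seed} "
            f"config={config.config_hash()}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def _write_text(df: pd.DataFrame, path: Path, config: PipelineConfig,
                title: str, percent_cols: tuple[str, ...] = ()) -> None:
    shown = df.copy()
    for col in percent_cols:
        if col in shown.columns:
            shown[col] = shown[col].map(
                lambda v: f"{100 * v:.1f}" if pd.notna(v) else "NA")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(config))
        fh.write(f"# {title}\n")
        if shown.empty:
            fh.write("(empty)\n")
        else:
            fh.write(shown.to_string(index=False,
                                     float_format=lambda v: f"{v:.3f}") + "\n")


def run_pipeline(config: PipelineConfig, world: World | None = None) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the report dict (name -> DataFrame, plus the ``world``).
    Deterministic given the config: reports embed the seed and config hash
    but no timestamps.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict = {}

    # ---- stage: simulate -------------------------------------------------
    if world is None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        logger.info("simulate: generating world (seed=%d)", config.seed)
        world = generate_world(sim)
    reports["world"] = world
    logger.info("simulate: %d segments, %d samples, %d true regions",
                len(world.callset), len(world.callset.samples),
                len(world.truth.regions))
    if config.emit_fixture_files:
        emit_fixture(world, out / "fixture")

    callset = world.callset
    programs = sorted(callset.programs)

    # ---- stage: qc -------------------------------------------------------
    counts = {s: {p: callset.count_per_sample(p)[s] for p in programs}
              for s in sorted(callset.samples)}
    thresholds = config.qc_thresholds or {p: config.qc_count_threshold
                                          for p in programs}
    normalized_reference = world.intensities.mean(axis=1)
    qc = qc_report(world.intensities, normalized_reference, counts,
                   world.array_to_sample, thresholds)
    reports["qc"] = qc
    filt = filter_individuals(counts, thresholds)
    logger.info("qc: %d arrays, %d samples kept, %d removed",
                qc.shape[0], len(filt.kept), len(filt.removed))
    if config.apply_qc_filter and filt.removed:
        callset = CallSet([s for s in callset if s.sample_id in set(filt.kept)],
                          samples=filt.kept)

    # ---- stage: evaluate -------------------------------------------------
    t1 = stability_table(callset, world.pedigree, programs,
                         config.stability_threshold, config.mode,
                         config.type_policy)
    reports["table1_stability"] = t1
    t2 = mendelian_table(callset, world.pedigree, programs, config.thresholds,
                         config.mode, config.type_policy)
    reports["table2_mendelian"] = t2
    t3 = similarity_matrix(callset, programs, config.stability_threshold,
                           "all", config.mode, config.type_policy)
    reports["table3_similarity"] = t3

    reference = truth_reference_per_sample(world)
    rows = []
    for program in programs:
        sens, spec = reference_sensitivity(
            callset, reference, program,
            threshold=config.stability_threshold, mode=config.mode,
            type_policy=config.type_policy)
        row = sens.as_row()
        row["specificity"] = spec.value
        rows.append(row)
    t4 = pd.DataFrame(rows)
    reports["table4_sensitivity"] = t4
    logger.info("evaluate: tables 1-4 done (%d programs)", len(programs))

    reports["length_distribution"] = length_distribution(
        callset, config.length_bins)

    # ---- stage: cluster --------------------------------------------------
    cohort_size = len(callset.samples)
    regions_by_program = {
        p: cluster_regions(callset.get(program_id=p), world.probes,
                           config.k_probes, cohort_size, id_prefix=p)
        for p in programs
    }
    common1 = select_common1(regions_by_program, world.probes,
                             config.k_probes, cohort_size)
    try:
        common2 = select_common2(regions_by_program, world.probes,
                                 config.anchor_program,
                                 config.common2_min_individuals,
                                 config.k_probes)
    except ValueError:
        logger.warning("cluster: anchor program %r absent; Common2 empty",
                       config.anchor_program)
        common2 = []
    reports["regions_by_program"] = regions_by_program
    reports["common1"] = common1
    reports["common2"] = common2
    logger.info("cluster: %s regions/program, %d Common1, %d Common2",
                {p: len(r) for p, r in regions_by_program.items()},
                len(common1), len(common2))
    write_regions_bed(common1, out / "common1.bed")
    write_regions_bed(common2, out / "common2.bed")

    # ---- stage: pooled overlap (table 5) ---------------------------------
    pooled_reference = truth_regions_as_reference(world)
    rows = []
    for program in programs:
        variants = {
            "all segments": CallSet(callset.get(program_id=program)),
            ">=2 programs": regions_to_callset(
                [r for r in common1 if program in r.programs], program),
        }
        for cutoff in config.strata:
            strat = stratify_by_individual_count(
                regions_by_program[program], cutoff)
            variants[f">{cutoff} individuals"] = regions_to_callset(strat, program)
        for variant, cs in variants.items():
            rep = pooled_overlap_ratio(cs, pooled_reference,
                                       config.stability_threshold,
                                       config.mode, config.type_policy)
            row = rep.as_row()
            row.update(program=program, variant=variant)
            rows.append(row)
    t5 = pd.DataFrame(rows)
    reports["table5_pooled_overlap"] = t5

    # ---- stage: annotate -------------------------------------------------
    tracks = list(world.tracks.values())
    cnv_sets = {"Common1": common1, "Common2": common2}
    t6 = enrichment_table(cnv_sets, tracks, config.flank_widths, world.genome,
                          seed=config.seed)
    reports["table6_enrichment"] = t6
    t7_frames = []
    for name, track in sorted(world.scores.items()):
        frame = score_summary(cnv_sets, track, config.flank_widths,
                              world.genome, seed=config.seed)
        frame.insert(0, "track", name)
        t7_frames.append(frame)
    t7 = pd.concat(t7_frames, ignore_index=True)
    reports["table7_scores"] = t7

    perm_source = common1 if common1 else list(world.truth.regions)
    flank_w = max(config.flank_widths)
    windows = []
    for region in perm_source:
        windows.extend(flank_windows(region, flank_w, world.genome).windows)
    perm = count_permutation_test(
        windows, world.genome,
        [r.length for r in perm_source],
        flank_w, world.cpg_track, n_perm=config.n_perm, seed=config.seed)
    reports["cpg_permutation"] = pd.DataFrame([{
        "feature": "CpG_island", "flank_bp": flank_w,
        "observed": perm.observed, "null_mean": perm.null_mean,
        "null_sd": perm.null_sd, "p_value": perm.p_value,
        "direction": perm.direction, "n_perm": perm.n_perm,
    }])
    logger.info("annotate: enrichment, scores and CpG permutation (p=%.4f, %s)",
                perm.p_value, perm.direction)

    render_tables(reports, config)
    return reports


def render_tables(reports: dict, config: PipelineConfig) -> None:
    """Write machine TSVs and text tables for the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "table1_stability": ("Average replicate stability rate per program",
                             ("value",)),
        "table2_mendelian": ("Mendelian inconsistency rate per program and "
                             "overlap threshold", ()),
        "table3_similarity": ("Pairwise program similarity (query program in "
                              "rows)", ("value",)),
        "table4_sensitivity": ("Sensitivity/specificity against the reference "
                               "standard", ("value", "specificity")),
        "table5_pooled_overlap": ("Pooled overlap ratio with the reference, "
                                  "by commonality stratum", ("value",)),
        "table6_enrichment": ("Repeat containment of breakpoint flanks (%)",
                              ()),
        "table7_scores": ("Mean score-track values in breakpoint flanks", ()),
        "qc": ("Array QC report", ()),
        "length_distribution": ("CNV length histogram per program", ()),
        "cpg_permutation": ("CpG-island count permutation test", ()),
    }
    for name, (title, pct_cols) in tables.items():
        df = reports.get(name)
        if df is None:
            continue
        _write_tsv(df, out / f"{name}.tsv", config)
        _write_text(df, out / f"{name}.txt", config, title, pct_cols)
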