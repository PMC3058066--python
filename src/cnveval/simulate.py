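"""Synthetic multi-program CNV cohort generator with published ground truth.

The generator emulates the statistical structure of an array-based CNV
study at desk scale, so every statistic in this package can be exercised
and checked against known parameters without any external data:

* a small genome (a few chromosomes of tens of Mb) carrying a sparse probe
  map, since boundary uncertainty and clustering operate in probe ranks;
* true CNV regions with log-normal lengths and population frequencies;
  carriers drawn per region frequency;
* a cohort of unrelated individuals plus trios with Mendelian transmission
  (each parental copy transmitted with probability 1/2) and an optional
  de novo rate (default 0 — germline copy-number mutation rates of
  ~1e-6..1e-4 per gamete are negligible at this cohort size);
* several detection "programs", each an imperfect observer: a carried
  segment is detected with probability ``detection_p``, both boundaries are
  jittered by rounded Gaussian offsets in probe ranks, and false calls
  arrive as a Poisson stream placed away from true regions;
* replicate arrays for a subset of individuals (five sets of five by
  default) whose per-array noise SD scales the false-call rate, tying the
  QC noise metric to CNV-count inflation;
* annotation tracks per repeat class: uniform background elements plus,
  with probability ``breakpoint_prob`` per true region, an element in both
  breakpoint flanks;
* stepwise score tracks: a conservation-like track whose values drop by
  ``score_depression`` inside true breakpoint flanks, and a flat
  recombination-like track;
* CpG-island-like point features depleted inside breakpoint flanks;
* a probes x arrays intensity matrix whose per-array log2-ratio SD matches
  the array's configured noise.

Every emitted call either descends from a true region or is labelled a
false positive in the ground truth.  One seed drives everything; identical
seeds give byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    GAIN,
    LOSS,
    AnnotationTrack,
    CallSet,
    CNVSegment,
    GenomeModel,
    PedigreeTable,
    ProbeMap,
    ScoreTrack,
    read_annotation_track,
    read_callset,
    read_genome,
    read_pedigree,
    read_probe_map,
    read_score_track,
    write_annotation_track,
    write_callset,
    write_genome,
    write_pedigree,
    write_probe_map,
    write_score_track,
)


@dataclass
class ProgramModel:
    """Detection behaviour of one simulated CNV caller."""

    detection_p: float = 0.9       # per-segment, per-array detection probability
    jitter_sd_probes: float = 2.0  # Gaussian SD of boundary offset, in probe ranks
    false_rate: float = 2.0        # mean false calls per array (scaled by noise)

    def validate(self):
        if not 0 <= self.detection_p <= 1:
            raise ValueError("detection_p must be in [0, 1]")
        if self.jitter_sd_probes < 0 or self.false_rate < 0:
            raise ValueError("jitter and false rate must be non-negative")


@dataclass
class RepeatClassModel:
    """Annotation model for one repeat class."""

    element_length: int            # bp, fixed per class for analytic nulls
    background_density: float      # elements per bp, uniform over the genome
    breakpoint_prob: float = 0.0   # per true region: P(element in BOTH flanks)

    def validate(self):
        if self.element_length <= 0 or self.background_density < 0:
            raise ValueError("invalid repeat class model")
        if not 0 <= self.breakpoint_prob <= 1:
            raise ValueError("breakpoint_prob must be in [0, 1]")


def default_programs() -> dict[str, ProgramModel]:
    # stabilities roughly 0.9 / 0.9 / 0.8, mirroring the spread between
    # HMM-based and segmentation-based callers
    return {
        "PennCNV-like": ProgramModel(0.90, 2.0, 2.0),
        "Birdseye-like": ProgramModel(0.90, 2.0, 3.0),
        "CBS-like": ProgramModel(0.80, 4.0, 2.0),
    }


def default_repeat_classes() -> dict[str, RepeatClassModel]:
    # background densities chosen so a random ±1 kb flank pair hits segdups
    # in both windows a few percent of the time while interspersed classes
    # are an order of magnitude denser, as in the human genome
    return {
        "segdup": RepeatClassModel(1500, 5.3e-5, 0.33),
        "LINE": RepeatClassModel(600, 1.1e-4, 0.20),
        "SINE": RepeatClassModel(300, 1.5e-4, 0.03),
        "LTR": RepeatClassModel(500, 4.0e-5, 0.05),
        "simple_repeat": RepeatClassModel(200, 8.0e-5, 0.0),
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator.  The seed is mandatory: no operation
    reads ambient randomness."""

    seed: int

    # genome / probes
    n_chromosomes: int = 3
    chrom_length: int = 20_000_000
    probe_spacing: int = 2_000           # mean bp between probes

    # true regions
    n_regions: int = 120
    median_length: float = 50_000.0      # log-normal median, bp
    length_sigma: float = 0.6            # log-normal sigma
    gain_fraction: float = 0.4
    freq_min: float = 0.02
    freq_max: float = 0.30
    min_region_gap_probes: int = 60      # separation between true regions
    min_region_probes: int = 5

    # cohort
    n_unrelated: int = 20
    n_trios: int = 8
    n_replicate_samples: int = 5
    n_replicates: int = 5
    de_novo_rate: float = 0.0            # expected de novo regions per offspring

    # detection
    programs: dict[str, ProgramModel] = field(default_factory=default_programs)

    # annotation
    repeat_classes: dict[str, RepeatClassModel] = field(default_factory=default_repeat_classes)
    flank_bp: int = 1_000                # breakpoint zone half-width (placement,
                                         # score depression, CpG depletion)
    placement_jitter_bp: int = 200       # placed element centre offset from breakpoint

    # score tracks
    score_baseline_mean: float = 70.0
    score_baseline_sd: float = 8.0
    score_step_bp: int = 1_000
    score_depression: float = 20.0       # subtracted inside breakpoint zones
    recomb_mean: float = 1.17
    recomb_sd: float = 0.40
    recomb_step_bp: int = 50_000

    # CpG-like features
    cpg_density: float = 2.0e-5          # features per bp
    cpg_length: int = 500
    cpg_depletion_factor: float = 0.5    # keep probability inside breakpoint zones

    # intensity matrix / QC
    n_qc_probes: int = 1_500
    noise_sd_min: float = 0.08
    noise_sd_max: float = 0.12
    intensity_log_mean: float = math.log(1000.0)
    intensity_log_sd: float = 0.3

    def validate(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.gain_fraction, self.freq_min, self.freq_max,
                  self.cpg_depletion_factor):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.freq_min > self.freq_max:
            raise ValueError("freq_min > freq_max")
        if self.de_novo_rate < 0:
            raise ValueError("de_novo_rate must be non-negative")
        for pm in self.programs.values():
            pm.validate()
        for rc in self.repeat_classes.values():
            rc.validate()

    # -- flat YAML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "programs" in d:
            d["programs"] = {k: ProgramModel(**v) if isinstance(v, dict) else v
                             for k, v in d["programs"].items()}
        if "repeat_classes" in d:
            d["repeat_classes"] = {k: RepeatClassModel(**v) if isinstance(v, dict) else v
                                   for k, v in d["repeat_classes"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class TrueRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    frequency: float
    start_idx: int   # probe index of the start boundary
    end_idx: int     # probe index of the end boundary

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    regions: list[TrueRegion]
    carriers: dict[str, frozenset[str]]                    # region_id -> samples
    inheritance: dict[tuple[str, str], str]                # (offspring, region_id) -> source
    call_origins: list[tuple[CNVSegment, str | None]]      # segment, region_id or None (false call)
    array_noise_sd: dict[str, float]                       # "sample:array" -> sd
    breakpoint_zones: list[tuple[str, int, int]]           # depression/depletion windows

    def region_by_id(self, region_id: str) -> TrueRegion:
        return next(r for r in self.regions if r.region_id == region_id)

    @property
    def n_false_calls(self) -> int:
        return sum(1 for _, rid in self.call_origins if rid is None)


@dataclass
class World:
    """A fully consistent simulated input bundle."""

    config: SimulationConfig
    genome: GenomeModel
    probes: ProbeMap
    callset: CallSet
    pedigree: PedigreeTable
    tracks: dict[str, AnnotationTrack]      # feature class -> track
    scores: dict[str, ScoreTrack]           # "conservation", "recombination"
    cpg_track: AnnotationTrack
    intensities: pd.DataFrame               # probes x arrays
    array_to_sample: dict[str, str]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _make_probes(cfg: SimulationConfig, rng: np.random.Generator,
                 genome: GenomeModel) -> ProbeMap:
    positions = {}
    for chrom, length in genome.chromosomes:
        n = length // cfg.probe_spacing
        jitter = rng.uniform(0.0, 1.0, size=n)
        pos = np.floor((np.arange(n) + jitter) * cfg.probe_spacing).astype(np.int64)
        pos = np.unique(pos)
        pos = pos[pos < length]
        positions[chrom] = pos
    return ProbeMap(positions)


def _place_regions(cfg: SimulationConfig, rng: np.random.Generator,
                   probes: ProbeMap) -> list[TrueRegion]:
    chroms = sorted(probes.positions)
    weights = np.array([probes.positions[c].size for c in chroms], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    gap = cfg.min_region_gap_probes
    regions: list[TrueRegion] = []
    tries = 0
    while len(regions) < cfg.n_regions:
        tries += 1
        if tries > cfg.n_regions * 200:
            raise RuntimeError("could not place all true regions; genome too "
                               "small for n_regions at the configured gap")
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = probes.positions[chrom]
        length = float(np.exp(rng.normal(math.log(cfg.median_length), cfg.length_sigma)))
        start_idx = int(rng.integers(0, pos.size))
        end_idx = int(np.searchsorted(pos, pos[start_idx] + length))
        if end_idx >= pos.size:
            continue
        if end_idx - start_idx < cfg.min_region_probes:
            end_idx = start_idx + cfg.min_region_probes
            if end_idx >= pos.size:
                continue
        span = (start_idx - gap, end_idx + gap)
        if any(not (span[1] < s or span[0] > e) for s, e in occupied[chrom]):
            continue
        occupied[chrom].append(span)
        cnv_type = GAIN if rng.random() < cfg.gain_fraction else LOSS
        freq = float(rng.uniform(cfg.freq_min, cfg.freq_max))
        regions.append(TrueRegion(
            region_id="",
            chrom=chrom,
            start=int(pos[start_idx]),
            end=int(pos[end_idx]) + 1,
            cnv_type=cnv_type,
            frequency=freq,
            start_idx=start_idx,
            end_idx=end_idx,
        ))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return [dataclasses.replace(r, region_id=f"true_{i + 1}")
            for i, r in enumerate(regions)]


def _cohort(cfg: SimulationConfig) -> tuple[list[str], PedigreeTable]:
    unrelated = [f"S{i + 1:03d}" for i in range(cfg.n_unrelated)]
    trios = []
    samples = list(unrelated)
    for t in range(cfg.n_trios):
        fa, mo, off = f"T{t + 1:02d}F", f"T{t + 1:02d}M", f"T{t + 1:02d}C"
        samples += [fa, mo, off]
        trios.append((off, fa, mo))
    groups: dict[str, list[str]] = {}
    for i, sample in enumerate(samples):
        n_arr = cfg.n_replicates if i < cfg.n_replicate_samples else 1
        groups[sample] = [f"a{j + 1}" for j in range(n_arr)]
    return samples, PedigreeTable(trios=trios, replicate_groups=groups)


def _draw_carriers(cfg: SimulationConfig, rng: np.random.Generator,
                   regions: list[TrueRegion], samples: list[str],
                   pedigree: PedigreeTable):
    offspring = {off for off, _, _ in pedigree.trios}
    founders = [s for s in samples if s not in offspring]
    carriers: dict[str, set[str]] = {r.region_id: set() for r in regions}
    for region in regions:
        for sample in founders:
            if rng.random() < region.frequency:
                carriers[region.region_id].add(sample)
    inheritance: dict[tuple[str, str], str] = {}
    for off, fa, mo in pedigree.trios:
        for region in regions:
            rid = region.region_id
            sources = []
            if fa in carriers[rid] and rng.random() < 0.5:
                sources.append("father")
            if mo in carriers[rid] and rng.random() < 0.5:
                sources.append("mother")
            if sources:
                carriers[rid].add(off)
                inheritance[(off, rid)] = "both" if len(sources) == 2 else sources[0]
        if cfg.de_novo_rate > 0:
            non_carried = [r.region_id for r in regions
                           if off not in carriers[r.region_id]]
            n_dn = int(rng.poisson(cfg.de_novo_rate))
            if non_carried and n_dn:
                chosen = rng.choice(non_carried,
                                    size=min(n_dn, len(non_carried)),
                                    replace=False)
                for rid in chosen:
                    carriers[rid].add(off)
                    inheritance[(off, rid)] = "de_novo"
    return {rid: frozenset(s) for rid, s in carriers.items()}, inheritance


def _jittered_segment(region: TrueRegion, probes: np.ndarray,
                      jitter_sd: float, rng: np.random.Generator,
                      sample: str, program: str, array: str) -> CNVSegment:
    if jitter_sd > 0:
        ds = int(np.rint(rng.normal(0, jitter_sd)))
        de = int(np.rint(rng.normal(0, jitter_sd)))
    else:
        ds = de = 0
    s_idx = int(np.clip(region.start_idx + ds, 0, probes.size - 1))
    e_idx = int(np.clip(region.end_idx + de, 0, probes.size - 1))
    if e_idx <= s_idx:
        e_idx = min(s_idx + 1, probes.size - 1)
        s_idx = e_idx - 1
    return CNVSegment(region.chrom, int(probes[s_idx]), int(probes[e_idx]) + 1,
                      region.cnv_type, sample, program, array)


def _false_call(cfg: SimulationConfig, rng: np.random.Generator,
                probes: ProbeMap, true_spans: dict[str, list[tuple[int, int]]],
                sample: str, program: str, array: str) -> CNVSegment | None:
    chroms = sorted(probes.positions)
    weights = np.array([probes.positions[c].size for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(200):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = probes.positions[chrom]
        length = float(np.exp(rng.normal(math.log(cfg.median_length), cfg.length_sigma)))
        s_idx = int(rng.integers(0, pos.size))
        e_idx = int(np.searchsorted(pos, pos[s_idx] + length))
        if e_idx >= pos.size:
            continue
        if e_idx - s_idx < 2:
            e_idx = s_idx + 2
            if e_idx >= pos.size:
                continue
        margin = cfg.min_region_gap_probes // 2
        span = (s_idx - margin, e_idx + margin)
        if any(not (span[1] < s or span[0] > e) for s, e in true_spans.get(chrom, [])):
            continue
        cnv_type = GAIN if rng.random() < cfg.gain_fraction else LOSS
        return CNVSegment(chrom, int(pos[s_idx]), int(pos[e_idx]) + 1,
                          cnv_type, sample, program, array)
    return None


def _breakpoint_zones(cfg: SimulationConfig, regions: list[TrueRegion],
                      genome: GenomeModel) -> list[tuple[str, int, int]]:
    zones = []
    for r in regions:
        L = genome.length(r.chrom)
        zones.append((r.chrom, max(0, r.start - cfg.flank_bp),
                      min(L, r.start + cfg.flank_bp)))
        zones.append((r.chrom, max(0, r.end - cfg.flank_bp),
                      min(L, r.end + cfg.flank_bp)))
    return zones


def _uniform_elements(rng: np.random.Generator, genome: GenomeModel,
                      density: float, elem_len: int) -> list[tuple[str, int, int]]:
    out = []
    for chrom, length in genome.chromosomes:
        n = rng.poisson(density * length)
        if n == 0:
            continue
        starts = np.sort(rng.integers(0, max(1, length - elem_len), size=n))
        for s in starts:
            out.append((chrom, int(s), int(s) + elem_len))
    return out


def _make_tracks(cfg: SimulationConfig, rng: np.random.Generator,
                 genome: GenomeModel, regions: list[TrueRegion]):
    tracks: dict[str, AnnotationTrack] = {}
    for cls in sorted(cfg.repeat_classes):
        model = cfg.repeat_classes[cls]
        intervals = _uniform_elements(rng, genome, model.background_density,
                                      model.element_length)
        if model.breakpoint_prob > 0:
            half = model.element_length // 2
            for region in regions:
                if rng.random() >= model.breakpoint_prob:
                    continue
                L = genome.length(region.chrom)
                for bp in (region.start, region.end):
                    centre = bp + int(rng.integers(-cfg.placement_jitter_bp,
                                                   cfg.placement_jitter_bp + 1))
                    s = max(0, centre - half)
                    e = min(L, s + model.element_length)
                    if e > s:
                        intervals.append((region.chrom, s, e))
        tracks[cls] = AnnotationTrack(cls, cls, intervals)
    return tracks


def _make_cpg_track(cfg: SimulationConfig, rng: np.random.Generator,
                    genome: GenomeModel,
                    zones: list[tuple[str, int, int]]) -> AnnotationTrack:
    zone_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in zones:
        zone_by_chrom.setdefault(chrom, []).append((s, e))
    for v in zone_by_chrom.values():
        v.sort()

    def in_zone(chrom: str, s: int, e: int) -> bool:
        for zs, ze in zone_by_chrom.get(chrom, []):
            if zs < e and ze > s:
                return True
        return False

    intervals = []
    for chrom, s, e in _uniform_elements(rng, genome, cfg.cpg_density, cfg.cpg_length):
        if in_zone(chrom, s, e) and rng.random() >= cfg.cpg_depletion_factor:
            continue
        intervals.append((chrom, s, e))
    return AnnotationTrack("CpG", "CpG_island", intervals)


def _stepwise_track(rng: np.random.Generator, genome: GenomeModel, name: str,
                    step_bp: int, mean: float, sd: float,
                    clip: tuple[float, float] | None,
                    depression: float,
                    zones: list[tuple[str, int, int]]) -> ScoreTrack:
    zone_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in zones:
        zone_by_chrom.setdefault(chrom, []).append((s, e))
    records = []
    for chrom, length in genome.chromosomes:
        edges = set(range(0, length, step_bp)) | {length}
        for zs, ze in zone_by_chrom.get(chrom, []):
            edges.add(zs)
            edges.add(ze)
        edges = sorted(e for e in edges if 0 <= e <= length)
        # baseline value per coarse step, then refine at zone boundaries
        n_steps = (length + step_bp - 1) // step_bp
        base = rng.normal(mean, sd, size=n_steps)
        if clip is not None:
            base = np.clip(base, clip[0], clip[1])
        zlist = sorted(zone_by_chrom.get(chrom, []))
        zstarts = np.array([z[0] for z in zlist], dtype=np.int64)
        zends = np.array([z[1] for z in zlist], dtype=np.int64)
        zends_cummax = np.maximum.accumulate(zends) if zlist else zends
        for s, e in zip(edges[:-1], edges[1:]):
            if s >= e:
                continue
            value = float(base[s // step_bp])
            if zlist:
                i = int(np.searchsorted(zstarts, e, side="left")) - 1
                if i >= 0 and zends_cummax[i] > s:
                    value -= depression
            records.append((chrom, s, e, value))
    return ScoreTrack(name, records)


def _make_intensities(cfg: SimulationConfig, rng: np.random.Generator,
                      probes: ProbeMap, genome: GenomeModel,
                      pedigree: PedigreeTable):
    first_chrom = genome.names[0]
    pos = probes.positions[first_chrom][: cfg.n_qc_probes]
    probe_ids = [f"{first_chrom}:{p}" for p in pos]
    base = np.exp(rng.normal(cfg.intensity_log_mean, cfg.intensity_log_sd,
                             size=len(probe_ids)))
    columns = {}
    noise_sd: dict[str, float] = {}
    array_to_sample: dict[str, str] = {}
    for sample in sorted(pedigree.replicate_groups):
        for array in pedigree.replicate_groups[sample]:
            aid = f"{sample}:{array}"
            sd = float(rng.uniform(cfg.noise_sd_min, cfg.noise_sd_max))
            noise_sd[aid] = sd
            array_to_sample[aid] = sample
            columns[aid] = base * np.exp2(rng.normal(0.0, sd, size=len(probe_ids)))
    df = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe"))
    reference = pd.Series(base, index=df.index, name="reference")
    return df, reference, noise_sd, array_to_sample


def generate_world(config: SimulationConfig) -> World:
    """Generate a fully consistent simulated bundle from one seed."""
    config.validate()
    (rng_probes, rng_regions, rng_carriers, rng_detect, rng_tracks,
     rng_cpg, rng_scores, rng_intens) = _child_rngs(config.seed, 8)

    genome = GenomeModel(tuple(
        (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chromosomes)
    ))
    probes = _make_probes(config, rng_probes, genome)
    probes.validate_against(genome)
    regions = _place_regions(config, rng_regions, probes)
    samples, pedigree = _cohort(config)
    carriers, inheritance = _draw_carriers(config, rng_carriers, regions,
                                           samples, pedigree)

    # per-array noise (also used by the intensity matrix) scales false calls
    intensities, reference, noise_sd, array_to_sample = _make_intensities(
        config, rng_intens, probes, genome, pedigree)
    sd_mid = 0.5 * (config.noise_sd_min + config.noise_sd_max)

    carried_by_sample: dict[str, list[TrueRegion]] = {s: [] for s in samples}
    for region in regions:
        for sample in carriers[region.region_id]:
            carried_by_sample[sample].append(region)

    true_spans: dict[str, list[tuple[int, int]]] = {}
    for region in regions:
        true_spans.setdefault(region.chrom, []).append(
            (region.start_idx, region.end_idx))

    call_origins: list[tuple[CNVSegment, str | None]] = []
    for program in sorted(config.programs):
        pm = config.programs[program]
        for sample in samples:
            for array in pedigree.replicate_groups[sample]:
                aid = f"{sample}:{array}"
                multiplier = (noise_sd[aid] / sd_mid) ** 2 if sd_mid > 0 else 1.0
                for region in carried_by_sample[sample]:
                    if rng_detect.random() < pm.detection_p:
                        seg = _jittered_segment(
                            region, probes.positions[region.chrom],
                            pm.jitter_sd_probes, rng_detect,
                            sample, program, array)
                        call_origins.append((seg, region.region_id))
                n_false = rng_detect.poisson(pm.false_rate * multiplier)
                for _ in range(n_false):
                    seg = _false_call(config, rng_detect, probes, true_spans,
                                      sample, program, array)
                    if seg is not None:
                        call_origins.append((seg, None))

    callset = CallSet([seg for seg, _ in call_origins], samples=samples)

    zones = _breakpoint_zones(config, regions, genome)
    tracks = _make_tracks(config, rng_tracks, genome, regions)
    cpg_track = _make_cpg_track(config, rng_cpg, genome, zones)
    scores = {
        "conservation": _stepwise_track(
            rng_scores, genome, "conservation", config.score_step_bp,
            config.score_baseline_mean, config.score_baseline_sd,
            (0.0, 100.0), config.score_depression, zones),
        "recombination": _stepwise_track(
            rng_scores, genome, "recombination", config.recomb_step_bp,
            config.recomb_mean, config.recomb_sd, (0.0, 1e9),
            0.0, []),
    }

    truth = GroundTruth(
        regions=regions,
        carriers=carriers,
        inheritance=inheritance,
        call_origins=call_origins,
        array_noise_sd=noise_sd,
        breakpoint_zones=zones,
    )
    return World(
        config=config,
        genome=genome,
        probes=probes,
        callset=callset,
        pedigree=pedigree,
        tracks=tracks,
        scores=scores,
        cpg_track=cpg_track,
        intensities=intensities,
        array_to_sample=array_to_sample,
        truth=truth,
    )


def truth_regions_as_reference(world: World,
                               program_id: str = "truth") -> CallSet:
    """The ground-truth regions as a pooled reference call set, standing in
    for an external gold-standard experiment."""
    segs = [CNVSegment(r.chrom, r.start, r.end, r.cnv_type, "pooled",
                       program_id, "0")
            for r in world.truth.regions]
    return CallSet(segs)


def truth_reference_per_sample(world: World,
                               program_id: str = "truth") -> CallSet:
    """Ground-truth carried segments per sample (individual-level reference)."""
    segs = []
    for region in world.truth.regions:
        for sample in sorted(world.truth.carriers[region.region_id]):
            segs.append(CNVSegment(region.chrom, region.start, region.end,
                                   region.cnv_type, sample, program_id, "0"))
    return CallSet(segs, samples=world.callset.samples)


# ---------------------------------------------------------------------------
# fixture emission / loading
# ---------------------------------------------------------------------------


def emit_fixture(world: World, directory) -> None:
    """Write the bundle in the package's external text formats.

    Everything written here parses back through the model readers; the
    ground truth goes to ``truth_*`` side files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_genome(world.genome, directory / "genome.tsv")
    write_probe_map(world.probes, directory / "probes.tsv")
    write_callset(world.callset, directory / "calls.tsv")
    write_pedigree(world.pedigree, directory / "trios.tsv",
                   directory / "replicates.tsv")
    (directory / "tracks").mkdir(exist_ok=True)
    for cls in sorted(world.tracks):
        write_annotation_track(world.tracks[cls], directory / "tracks" / f"{cls}.bed")
    write_annotation_track(world.cpg_track, directory / "tracks" / "CpG_island.bed")
    (directory / "scores").mkdir(exist_ok=True)
    for name in sorted(world.scores):
        write_score_track(world.scores[name], directory / "scores" / f"{name}.bedgraph")
    world.intensities.to_csv(directory / "intensities.tsv", sep="\t")
    with open(directory / "samples.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample\n")
        for sample in sorted(world.callset.samples):
            fh.write(sample + "\n")
    with open(directory / "truth_regions.tsv", "w", encoding="utf-8") as fh:
        fh.write("region_id\tchrom\tstart\tend\ttype\tfrequency\tcarriers\n")
        for r in world.truth.regions:
            carriers = ",".join(sorted(world.truth.carriers[r.region_id]))
            fh.write(f"{r.region_id}\t{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{r.cnv_type}\t{r.frequency!r}\t{carriers}\n")
    world.config.to_yaml(directory / "sim_config.yaml")


@dataclass
class FixtureBundle:
    genome: GenomeModel
    probes: ProbeMap
    callset: CallSet
    pedigree: PedigreeTable
    tracks: dict[str, AnnotationTrack]
    scores: dict[str, ScoreTrack]
    intensities: pd.DataFrame


def load_fixture(directory) -> FixtureBundle:
    """Read an emitted fixture back through the model readers."""
    directory = Path(directory)
    with open(directory / "samples.tsv", "r", encoding="utf-8") as fh:
        samples = [line.strip() for line in fh if line.strip() and line.strip() != "sample"]
    tracks = {}
    for bed in sorted((directory / "tracks").glob("*.bed")):
        cls = bed.stem
        tracks[cls] = read_annotation_track(bed, cls)
    scores = {}
    for bg in sorted((directory / "scores").glob("*.bedgraph")):
        scores[bg.stem] = read_score_track(bg, bg.stem)
    return FixtureBundle(
        genome=read_genome(directory / "genome.tsv"),
        probes=read_probe_map(directory / "probes.tsv"),
        callset=read_callset(directory / "calls.tsv", samples=samples),
        pedigree=read_pedigree(directory / "trios.tsv", directory / "replicates.tsv"),
        tracks=tracks,
        scores=scores,
        intensities=pd.read_csv(directory / "intensities.tsv", sep="\t",
                                index_col="probe"),
    )
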