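"""Shared fixtures: small simulated worlds and oracle helpers.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from cnveval.model import GenomeModel, ProbeMap
from cnveval.simulate import ProgramModel, SimulationConfig, generate_world


def small_config(seed: int, **overrides) -> SimulationConfig:
    """A desk-scale world that runs in well under a second."""
    base = dict(
        seed=seed,
        n_chromosomes=2,
        chrom_length=15_000_000,
        n_regions=50,
        n_unrelated=8,
        n_trios=5,
        n_replicate_samples=3,
        n_replicates=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(small_config(101))


@pytest.fixture(scope="session")
def degenerate_world():
    """Perfect detection: p=1, no jitter, no false calls, no de novo."""
    cfg = small_config(
        202,
        programs={"perfect": ProgramModel(1.0, 0.0, 0.0)},
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def uniform_probes():
    """chr1 with 2000 probes at exactly 1 kb spacing."""
    return ProbeMap({"chr1": np.arange(0, 2_000_000, 1_000, dtype=np.int64)})


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeModel((("chr1", 2_000_000), ("chr2", 1_000_000)))


# ---------------------------------------------------------------------------
# independent oracles (deliberately different code paths from the package)
# ---------------------------------------------------------------------------


def brute_force_match(query, target, threshold, mode="query",
                      type_policy="strict") -> np.ndarray:
    """All-pairs matcher using numpy broadcasting: the reference for the
    interval-tree implementation."""
    if not target:
        return np.zeros(len(query), dtype=bool)
    t_chrom = np.array([t.chrom for t in target])
    t_type = np.array([t.cnv_type for t in target])
    ts = np.array([t.start for t in target], dtype=float)
    te = np.array([t.end for t in target], dtype=float)
    flags = np.zeros(len(query), dtype=bool)
    for i, q in enumerate(query):
        ov = np.clip(np.minimum(te, q.end) - np.maximum(ts, q.start), 0, None)
        ov[t_chrom != q.chrom] = 0.0
        if mode == "query":
            frac = ov / q.length
        else:
            frac = np.minimum(ov / q.length, ov / (te - ts))
        ok = frac > threshold
        if type_policy == "strict":
            ok &= t_type == q.cnv_type
        flags[i] = bool(ok.any())
    return flags


def random_segments(rng, n, genome: GenomeModel, sample_pool=("s1", "s2", "s3"),
                    program="P", max_len=200_000):
    """Random valid segments for oracle comparisons."""
    from cnveval.model import CNVSegment

    names = genome.names
    lengths = dict(genome.chromosomes)
    segs = []
    for _ in range(n):
        chrom = names[int(rng.integers(0, len(names)))]
        length = int(rng.integers(1_000, max_len))
        start = int(rng.integers(0, lengths[chrom] - length))
        segs.append(CNVSegment(
            chrom, start, start + length,
            "gain" if rng.random() < 0.5 else "loss",
            sample_pool[int(rng.integers(0, len(sample_pool)))],
            program,
            "a1",
        ))
    return segs
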