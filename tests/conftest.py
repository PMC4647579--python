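"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from convergene.core import GenomicInterval, PipelineConfig, overlaps
from convergene.io import CnvSegment
from convergene.pipeline import run_pipeline
from convergene.simulate import SimulationParams, simulate_cohort

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study: 4 samples, 2000 genes, 20 planted
    multi-altered genes, 100 single-altered decoys, fixed seed."""
    return simulate_cohort(SimulationParams(seed=0))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    c = default_cohort
    return run_pipeline(c.genes, c.segments, c.expression, c.exome,
                        c.transcriptome, c.fusions)


# ---------------------------------------------------------------------------
# independent oracles (never call the code paths they check)


def brute_force_gene_cnv(segments, genes, config):
    """Quadratic every-gene-against-every-segment re-derivation of the
    gene-level CNV call set, with its own copy of the resolution rule.

    Returns {(gene_id, sample_id): (status, copy_number)}.
    """
    hits: dict[tuple, list] = {}
    for g in genes:
        for seg in segments:
            if seg.interval.length >= config.focal_max_length:
                continue
            if seg.copy_number >= config.amp_min_copies:
                status = "amplified"
            elif seg.copy_number <= config.del_max_copies:
                status = "deleted"
            else:
                continue
            if not overlaps(g.interval, seg.interval):
                continue
            if config.min_overlap_fraction > 0:
                shared = (min(g.interval.end, seg.interval.end)
                          - max(g.interval.start, seg.interval.start))
                if shared < config.min_overlap_fraction * g.interval.length:
                    continue
            hits.setdefault((g.gene_id, seg.sample_id), []).append(
                (seg, status))

    resolved = {}
    for key, pairs in hits.items():
        best = None
        best_rank = None
        for seg, status in pairs:
            rank = (abs(seg.copy_number - config.neutral_copies),
                    1 if status == "amplified" else 0,
                    -seg.interval.start, -seg.interval.end)
            if best_rank is None or rank > best_rank:
                best_rank, best = rank, (status, seg.copy_number)
        resolved[key] = best
    return resolved


def random_cnv_instance(rng: np.random.Generator, n_segments: int,
                        n_genes: int):
    """Random segments and gene intervals spanning focal and arm scales,
    neutral and extreme copies, on a handful of chromosomes."""
    from convergene.core import GeneModel

    chroms = ["1", "2", "3"]
    chrom_len = 60_000_000
    segments = []
    for i in range(n_segments):
        chrom = chroms[int(rng.integers(len(chroms)))]
        if rng.random() < 0.6:  # focal scale
            length = int(rng.integers(10_000, 5_000_000))
        else:  # around or above the arm-level boundary
            length = int(rng.integers(8_000_000, 30_000_000))
        start = int(rng.integers(0, chrom_len - length))
        segments.append(CnvSegment(
            sample_id=f"S{int(rng.integers(1, 4))}",
            interval=GenomicInterval(chrom, start, start + length),
            copy_number=float(rng.integers(0, 9)),
        ))
    genes = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1_000, 200_000))
        start = int(rng.integers(0, chrom_len - length))
        genes.append(GeneModel(
            gene_id=f"G{i:05d}", symbol=f"SYM{i:05d}",
            interval=GenomicInterval(chrom, start, start + length),
        ))
    return segments, genes


def expression_status_oracle(values, floor=0.1, high=60.0, low=40.0):
    """Brute-force percentile classification of one sample's log-expression
    values: count-based mean-rank percentiles, strict thresholds."""
    expressed = [v for v in values if v >= floor]
    n = len(expressed)
    out = []
    for v in values:
        if v < floor:
            out.append("not_expressed")
            continue
        below = sum(1 for w in expressed if w < v)
        tied = sum(1 for w in expressed if w == v)
        mean_rank = below + (tied + 1) / 2.0
        pct = 50.0 if n == 1 else 100.0 * (mean_rank - 1.0) / (n - 1.0)
        if pct > high:
            out.append("high")
        elif pct < low:
            out.append("low")
        else:
            out.append("intermediate")
    return out
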