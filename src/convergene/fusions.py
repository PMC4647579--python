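"""Fusion stage: read-pair support filter and event/track export.

Fusion candidates need at least ``min_fusion_read_pairs`` spanning read
pairs (10 by default). Kept fusions become two gene-level events, one per
partner (a read-through with identical partners yields a single event).
By default fusion events are exported as evidence and circos-style tracks
but do not count toward the multiple-alteration prioritization; the
``count_fusions_in_integration`` config switch enables them there.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .core import AlterationEvent, GeneModel, PipelineConfig
from .io import FusionCall

__all__ = ["filter_fusions", "fusions_to_events", "fusion_tracks"]


def filter_fusions(fusions: Iterable[FusionCall],
                   config: PipelineConfig) -> list[FusionCall]:
    """Keep candidates with read_pairs >= the minimum (inclusive)."""
    return [f for f in fusions if f.read_pairs >= config.min_fusion_read_pairs]


def fusions_to_events(fusions: Iterable[FusionCall]) -> list[AlterationEvent]:
    """Two undirected events per fusion (5' and 3' partner), one for a
    read-through."""
    events = []
    for f in fusions:
        partners = (f.gene5,) if f.read_through else (f.gene5, f.gene3)
        for gene in partners:
            events.append(AlterationEvent(
                gene_id=gene, sample_id=f.sample_id,
                alteration_type="fusion", direction="not_applicable",
                evidence=f"fusion:{f.key}",
            ))
    return events


def fusion_tracks(fusions: Iterable[FusionCall],
                  genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Tabular circos-style link track: one row per fusion with the genomic
    midpoint of each partner. Fusions whose partner lacks a gene model are
    dropped from the track (they remain in the fusion table)."""
    pos = {
        g.gene_id: (g.interval.chrom, (g.interval.start + g.interval.end) // 2)
        for g in genes
    }
    rows = []
    for f in fusions:
        if f.gene5 not in pos or f.gene3 not in pos:
            continue
        c5, p5 = pos[f.gene5]
        c3, p3 = pos[f.gene3]
        rows.append({
            "sample_id": f.sample_id,
            "gene5": f.gene5, "chrom5": c5, "pos5": p5,
            "gene3": f.gene3, "chrom3": c3, "pos3": p3,
            "read_pairs": f.read_pairs,
        })
    df = pd.DataFrame(rows, columns=["sample_id", "gene5", "chrom5", "pos5",
                                     "gene3", "chrom3", "pos3", "read_pairs"])
    return df.sort_values(list(df.columns)).reset_index(drop=True)
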