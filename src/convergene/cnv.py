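"""Copy-number stage: focal/arm-level classification and gene-level calls.

Segments at least ``focal_max_length`` long (10 Mb by default) are treated
as arm-scale events and excluded from gene-level analysis; only shorter
(focal) segments with a non-neutral copy number generate gene calls. A gene
is assigned to a segment by interval overlap (any shared base by default;
``min_overlap_fraction`` can demand more). When several focal segments hit
one gene in one sample, the call takes the segment with the most extreme
copy number relative to the neutral baseline, ties broken toward
amplification and then toward the leftmost segment, and the provenance key
is flagged so mixed calls stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from intervaltree import IntervalTree

from .core import GeneModel, PipelineConfig
from .io import CnvSegment

__all__ = ["GeneCnvCall", "classify_segment", "call_gene_cnv"]

FOCAL = "focal"
ARM_LEVEL = "arm_level"


@dataclass(frozen=True)
class GeneCnvCall:
    """Gene-level amplification/deletion verdict for one sample.

    ``status`` derives solely from the segment copy number and the config
    baselines; ``focal`` derives solely from segment length. ``segment_key``
    names the winning segment (suffixed ``;mixed`` when discordant focal
    segments overlapped the gene).
    """

    gene_id: str
    sample_id: str
    status: str  # "amplified" | "deleted"
    focal: bool
    copy_number: float
    segment_key: str

    def __post_init__(self) -> None:
        if self.status not in ("amplified", "deleted"):
            raise ValueError(f"bad CNV status {self.status!r}")


def classify_segment(seg: CnvSegment, config: PipelineConfig) -> str:
    """``focal`` iff the segment is shorter than ``focal_max_length``.

    A segment of exactly the threshold length is arm-level: the focal
    filter applied downstream is a strict "shorter than".
    """
    return FOCAL if seg.interval.length < config.focal_max_length else ARM_LEVEL


def _segment_status(seg: CnvSegment, config: PipelineConfig) -> str | None:
    if seg.copy_number >= config.amp_min_copies:
        return "amplified"
    if seg.copy_number <= config.del_max_copies:
        return "deleted"
    return None


def call_gene_cnv(segments: Iterable[CnvSegment],
                  genes: Iterable[GeneModel],
                  config: PipelineConfig) -> list[GeneCnvCall]:
    """Emit one call per (gene, sample) overlapping >= 1 focal non-neutral segment.

    Genes overlapping only neutral-copy or only arm-level segments yield no
    call; "neutral" is a non-event. Output is sorted by (gene, sample).
    """
    genes = list(genes)
    trees: dict[str, IntervalTree] = {}
    gene_by_id = {}
    for g in genes:
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g.gene_id
        )
        gene_by_id[g.gene_id] = g

    # (gene_id, sample_id) -> list of (segment, status)
    hits: dict[tuple[str, str], list[tuple[CnvSegment, str]]] = {}
    for seg in segments:
        if classify_segment(seg, config) != FOCAL:
            continue
        status = _segment_status(seg, config)
        if status is None:
            continue
        tree = trees.get(seg.interval.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(seg.interval.start, seg.interval.end):
            if config.min_overlap_fraction > 0:
                shared = min(iv.end, seg.interval.end) - max(iv.begin,
                                                             seg.interval.start)
                if shared < config.min_overlap_fraction * (iv.end - iv.begin):
                    continue
            hits.setdefault((iv.data, seg.sample_id), []).append((seg, status))

    calls = []
    for (gene_id, sample_id), seg_hits in hits.items():
        calls.append(_resolve(gene_id, sample_id, seg_hits, config))
    calls.sort(key=lambda c: (c.gene_id, c.sample_id))
    return calls


def _resolve(gene_id: str, sample_id: str,
             seg_hits: list[tuple[CnvSegment, str]],
             config: PipelineConfig) -> GeneCnvCall:
    """Pick the most extreme segment; ties favour amplification, then the
    leftmost segment. Discordant (amp + del) overlaps are flagged ``mixed``."""
    def sort_key(item):
        seg, status = item
        extremity = abs(seg.copy_number - config.neutral_copies)
        amp_first = 1 if status == "amplified" else 0
        # most extreme first, then amplified, then leftmost
        return (-extremity, -amp_first, seg.interval.start, seg.interval.end,
                seg.key)

    ordered = sorted(seg_hits, key=sort_key)
    seg, status = ordered[0]
    mixed = len({s for _, s in seg_hits}) > 1
    key = seg.key + (";mixed" if mixed else "")
    return GeneCnvCall(gene_id=gene_id, sample_id=sample_id, status=status,
                       focal=True, copy_number=seg.copy_number,
                       segment_key=key)
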