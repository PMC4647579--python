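"""Three-step gene prioritization: converging evidence across platforms.

Step 1 selects genes with a concordant focal copy-number and expression
change in the *same* sample (amplified + highly expressed, or deleted +
lowly expressed) — the per-sample dosage relationship. Step 2 selects genes
carrying a filtered point mutation whose transcript is detectable in the
mutated sample, or whose gene carries a focal copy-number call in any
sample. Step 3 takes the union of the two candidate lists, pools each
candidate's alteration events across *all* samples, and prioritizes genes
whose events span at least ``min_alteration_types`` distinct alteration
types (two by default) — "multiple alterations within or across samples".

"Detectable transcript" is evidence for a mutation, not an alteration type
of its own; only cnv / expression-change / mutation (and fusion, when
enabled) events count toward the type tally. Expression high/low events are
pooled into step-3 profiles even for genes that entered via step 2, so a
mutated and overexpressed but copy-neutral gene is prioritized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .core import AlterationEvent, PipelineConfig
from .cnv import GeneCnvCall
from .expression import ExpressionCall, detectable_index
from .io import VariantCall

__all__ = [
    "GeneAlterationProfile",
    "cnv_events",
    "expression_events",
    "mutation_events",
    "collect_events",
    "step1_cnv_expression",
    "step2_mutation_support",
    "step3_prioritize",
]


@dataclass(frozen=True)
class GeneAlterationProfile:
    """Pooled alteration evidence for one candidate gene.

    ``n_types`` counts distinct alteration types over all samples;
    ``prioritized`` is true when that count reaches the configured minimum.
    """

    gene_id: str
    events: tuple[AlterationEvent, ...]
    types_present: frozenset[str]
    samples_affected: frozenset[str]
    n_types: int
    prioritized: bool


# ---------------------------------------------------------------------------
# call -> event conversion


def cnv_events(calls: Iterable[GeneCnvCall]) -> list[AlterationEvent]:
    return [
        AlterationEvent(
            gene_id=c.gene_id, sample_id=c.sample_id, alteration_type="cnv",
            direction="gain" if c.status == "amplified" else "loss",
            evidence=f"cnv:{c.segment_key}",
        )
        for c in calls
    ]


def expression_events(calls: Iterable[ExpressionCall]) -> list[AlterationEvent]:
    """High/low calls become gain/loss events; intermediate and
    not-expressed states are non-events."""
    out = []
    for c in calls:
        if c.status in ("high", "low"):
            out.append(AlterationEvent(
                gene_id=c.gene_id, sample_id=c.sample_id,
                alteration_type="expression",
                direction="gain" if c.status == "high" else "loss",
                evidence=f"expr:{c.sample_id}:pct={c.percentile:.4g}",
            ))
    return out


def mutation_events(passed: Iterable[VariantCall]) -> list[AlterationEvent]:
    return [
        AlterationEvent(
            gene_id=v.gene_id, sample_id=v.sample_id,
            alteration_type="mutation", direction="not_applicable",
            evidence=f"var:{v.chrom}:{v.pos}:{v.ref}>{v.alt}",
        )
        for v in passed if v.gene_id
    ]


def collect_events(cnv_calls: Iterable[GeneCnvCall],
                   expr_calls: Iterable[ExpressionCall],
                   passed_variants: Iterable[VariantCall],
                   fusion_events: Iterable[AlterationEvent] = (),
                   ) -> list[AlterationEvent]:
    """The full event pool: every gene-level alteration from every stage."""
    events = (cnv_events(cnv_calls) + expression_events(expr_calls)
              + mutation_events(passed_variants) + list(fusion_events))
    return sorted(events)


# ---------------------------------------------------------------------------
# the three steps


def step1_cnv_expression(cnv_calls: Iterable[GeneCnvCall],
                         expr_calls: Iterable[ExpressionCall],
                         ) -> dict[str, list[AlterationEvent]]:
    """Genes with same-sample concordant dosage: amplified+high or
    deleted+low. Returns gene -> the qualifying cnv and expression events."""
    expr_by = {(c.gene_id, c.sample_id): c for c in expr_calls}
    selected: dict[str, list[AlterationEvent]] = {}
    for cc in cnv_calls:
        ec = expr_by.get((cc.gene_id, cc.sample_id))
        if ec is None:
            continue
        concordant = (
            (cc.status == "amplified" and ec.status == "high")
            or (cc.status == "deleted" and ec.status == "low")
        )
        if concordant:
            selected.setdefault(cc.gene_id, []).extend(
                cnv_events([cc]) + expression_events([ec])
            )
    return selected


def step2_mutation_support(passed_variants: Iterable[VariantCall],
                           expr_calls: Iterable[ExpressionCall],
                           cnv_calls: Iterable[GeneCnvCall],
                           ) -> dict[str, list[AlterationEvent]]:
    """Genes with a filtered mutation that is either transcribed in the
    mutated sample or accompanied by a focal copy-number call in any sample.
    """
    detect = detectable_index(expr_calls)
    cnv_by_gene: dict[str, list[GeneCnvCall]] = {}
    for cc in cnv_calls:
        cnv_by_gene.setdefault(cc.gene_id, []).append(cc)

    selected: dict[str, list[AlterationEvent]] = {}
    for v in passed_variants:
        if not v.gene_id:
            continue
        transcribed = (v.gene_id, v.sample_id) in detect
        cnv_backed = v.gene_id in cnv_by_gene
        if not (transcribed or cnv_backed):
            continue
        bucket = selected.setdefault(v.gene_id, [])
        bucket.extend(mutation_events([v]))
        if cnv_backed and not transcribed:
            # record the copy-number route that admitted the mutation
            bucket.extend(cnv_events(cnv_by_gene[v.gene_id]))
    return selected


def step3_prioritize(step1: dict[str, list[AlterationEvent]],
                     step2: dict[str, list[AlterationEvent]],
                     all_events: Iterable[AlterationEvent],
                     config: PipelineConfig) -> list[GeneAlterationProfile]:
    """Profile every step-1/step-2 candidate from the full event pool and
    flag genes whose pooled events span >= ``min_alteration_types`` types.

    Output sorted by (n_types desc, samples affected desc, gene_id).
    """
    candidates = set(step1) | set(step2)
    pool: dict[str, list[AlterationEvent]] = {g: [] for g in candidates}
    for ev in all_events:
        if ev.alteration_type == "fusion" and not config.count_fusions_in_integration:
            continue
        if ev.gene_id in pool:
            pool[ev.gene_id].append(ev)

    profiles = []
    for gene_id in candidates:
        events = sorted(set(pool[gene_id]))
        types = frozenset(e.alteration_type for e in events)
        samples = frozenset(e.sample_id for e in events)
        profiles.append(GeneAlterationProfile(
            gene_id=gene_id,
            events=tuple(events),
            types_present=types,
            samples_affected=samples,
            n_types=len(types),
            prioritized=len(types) >= config.min_alteration_types,
        ))
    profiles.sort(key=lambda p: (-p.n_types, -len(p.samples_affected),
                                 p.gene_id))
    return profiles
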