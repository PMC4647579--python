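"""Variant stage: coverage, germline subtraction, prediction voting and
exome/transcriptome cross-validation.

Filters, in the order the full stage applies them:

1. drop ``synonymous``/``other`` effects (no protein consequence);
2. coverage: keep calls with depth >= ``min_coverage`` ("below 5X" removed);
3. germline subtraction: drop calls present in dbSNP unless also catalogued
   in COSMIC (somatic-catalog membership rescues a polymorphism-database
   hit);
4. functional-prediction vote: keep missense/inframe calls judged
   deleterious by >= 2 of 3 tools; truncating calls (nonsense, frameshift,
   splice) bypass the vote, since missense predictors do not score them;
5. cross-validation: keep exome calls whose identical (sample, chrom, pos,
   ref, alt) key also appears among transcriptome calls (position-only
   matching available via config);
6. drop calls with no assigned gene (unusable for gene-level integration).

Each rejected call is labelled with the first failing filter in this order;
the passed set itself is order-invariant because the predicates are
independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import TRUNCATING_EFFECTS, PipelineConfig
from .io import VariantCall

__all__ = [
    "FilteredVariantSet",
    "REJECTION_REASONS",
    "filter_coverage",
    "subtract_germline",
    "vote_deleterious",
    "filter_deleterious",
    "cross_validate",
    "run_variant_stage",
]

REJECTION_REASONS = (
    "synonymous",
    "low_coverage",
    "dbsnp_only",
    "not_deleterious",
    "no_transcriptome_support",
    "unassigned_gene",
)


@dataclass
class FilteredVariantSet:
    """Partition of an input variant list into passed and (reason-labelled)
    rejected calls. Conservation holds at every stage:
    ``len(input) == len(passed) + len(rejected)``."""

    passed: list[VariantCall] = field(default_factory=list)
    rejected: list[tuple[VariantCall, str]] = field(default_factory=list)

    def extend_rejected(self, variants: Iterable[VariantCall],
                        reason: str) -> None:
        if reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {reason!r}")
        self.rejected.extend((v, reason) for v in variants)


def _partition(variants: Iterable[VariantCall], predicate,
               reason: str) -> FilteredVariantSet:
    out = FilteredVariantSet()
    for v in variants:
        if predicate(v):
            out.passed.append(v)
        else:
            out.rejected.append((v, reason))
    return out


def filter_coverage(variants: Iterable[VariantCall],
                    config: PipelineConfig) -> FilteredVariantSet:
    """Keep calls with read depth >= ``min_coverage`` (strict "below" fails)."""
    return _partition(variants, lambda v: v.coverage >= config.min_coverage,
                      "low_coverage")


def subtract_germline(variants: Iterable[VariantCall]) -> FilteredVariantSet:
    """Drop calls in dbSNP but not in COSMIC; COSMIC membership rescues."""
    return _partition(variants, lambda v: not (v.in_dbsnp and not v.in_cosmic),
                      "dbsnp_only")


def vote_deleterious(v: VariantCall, config: PipelineConfig) -> bool:
    """2-of-3 deleterious consensus; missing verdicts count as not
    deleterious; truncating effects bypass the vote entirely."""
    if v.effect in TRUNCATING_EFFECTS:
        return True
    votes = sum(1 for p in v.predictions if p == "D")
    return votes >= config.min_deleterious_votes


def filter_deleterious(variants: Iterable[VariantCall],
                       config: PipelineConfig) -> FilteredVariantSet:
    return _partition(variants, lambda v: vote_deleterious(v, config),
                      "not_deleterious")


def cross_validate(exome: Iterable[VariantCall],
                   transcriptome: Iterable[VariantCall],
                   config: Optional[PipelineConfig] = None,
                   ) -> FilteredVariantSet:
    """Keep exome calls matched by an identical transcriptome call.

    The output record is the exome call (exome coverage retained). Allele
    identity is required unless ``config.match_positions_only`` is set.
    """
    positions_only = bool(config and config.match_positions_only)
    seen = {t.key(positions_only) for t in transcriptome}
    return _partition(exome, lambda v: v.key(positions_only) in seen,
                      "no_transcriptome_support")


def run_variant_stage(exome: Iterable[VariantCall],
                      transcriptome: Iterable[VariantCall],
                      config: PipelineConfig) -> FilteredVariantSet:
    """Apply the full exome filter cascade against the transcriptome calls.

    Returns the partition of the *exome* input; transcriptome calls serve
    only as the cross-validation reference.
    """
    result = FilteredVariantSet()
    current = list(exome)

    step = _partition(current,
                      lambda v: v.effect not in ("synonymous", "other"),
                      "synonymous")
    result.rejected.extend(step.rejected)

    step2 = filter_coverage(step.passed, config)
    result.rejected.extend(step2.rejected)

    step3 = subtract_germline(step2.passed)
    result.rejected.extend(step3.rejected)

    step4 = filter_deleterious(step3.passed, config)
    result.rejected.extend(step4.rejected)

    step5 = cross_validate(step4.passed, transcriptome, config)
    result.rejected.extend(step5.rejected)

    step6 = _partition(step5.passed, lambda v: bool(v.gene_id),
                       "unassigned_gene")
    result.rejected.extend(step6.rejected)

    result.passed = step6.passed
    return result
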