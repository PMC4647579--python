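"""End-to-end orchestration: run every stage and write the output tables.

Given one cohort's gene models, segments, expression matrix, exome and
transcriptome variant calls and fusion candidates, :func:`run_pipeline`
produces gene-level calls per stage, the pooled event list, and the
prioritized gene profiles. :func:`write_results` serializes everything as
sorted TSV with provenance headers, so two runs on identical input and
config are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .core import AlterationEvent, GeneModel, PipelineConfig
from .cnv import GeneCnvCall, call_gene_cnv
from .cohort import cumulative_frequency, oncoprint_matrix
from .expression import ExpressionCall, classify_expression
from .fusions import filter_fusions, fusion_tracks, fusions_to_events
from .integrate import (
    GeneAlterationProfile,
    collect_events,
    step1_cnv_expression,
    step2_mutation_support,
    step3_prioritize,
)
from .io import (
    CnvSegment,
    ExpressionRecord,
    FusionCall,
    VariantCall,
    write_dataframe,
    write_table,
)
from .variants import FilteredVariantSet, run_variant_stage

__all__ = ["PipelineResult", "run_pipeline", "write_results"]


@dataclass
class PipelineResult:
    cnv_calls: list[GeneCnvCall]
    expr_calls: list[ExpressionCall]
    variants: FilteredVariantSet
    fusions_kept: list[FusionCall]
    events: list[AlterationEvent]
    step1_genes: set[str]
    step2_genes: set[str]
    profiles: list[GeneAlterationProfile]

    @property
    def prioritized(self) -> list[str]:
        return [p.gene_id for p in self.profiles if p.prioritized]


def run_pipeline(genes: Iterable[GeneModel],
                 segments: Iterable[CnvSegment],
                 expression: Iterable[ExpressionRecord],
                 exome: Iterable[VariantCall],
                 transcriptome: Iterable[VariantCall],
                 fusions: Iterable[FusionCall] = (),
                 config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run every stage and the three-step prioritization."""
    config = config or PipelineConfig()
    genes = list(genes)
    cnv_calls = call_gene_cnv(segments, genes, config)
    expr_calls = classify_expression(expression, config)
    vset = run_variant_stage(exome, transcriptome, config)
    kept_fusions = filter_fusions(fusions, config)
    events = collect_events(cnv_calls, expr_calls, vset.passed,
                            fusions_to_events(kept_fusions))
    s1 = step1_cnv_expression(cnv_calls, expr_calls)
    s2 = step2_mutation_support(vset.passed, expr_calls, cnv_calls)
    profiles = step3_prioritize(s1, s2, events, config)
    return PipelineResult(
        cnv_calls=cnv_calls, expr_calls=expr_calls, variants=vset,
        fusions_kept=kept_fusions, events=events,
        step1_genes=set(s1), step2_genes=set(s2), profiles=profiles,
    )


def _profiles_frame(profiles: list[GeneAlterationProfile]) -> pd.DataFrame:
    rows = [{
        "gene_id": p.gene_id,
        "n_types": p.n_types,
        "types_present": ",".join(sorted(p.types_present)),
        "n_samples": len(p.samples_affected),
        "samples_affected": ",".join(sorted(p.samples_affected)),
        "prioritized": int(p.prioritized),
        "evidence": ";".join(e.evidence for e in p.events),
    } for p in profiles]
    return pd.DataFrame(rows, columns=["gene_id", "n_types", "types_present",
                                       "n_samples", "samples_affected",
                                       "prioritized", "evidence"])


def write_results(result: PipelineResult, out_dir: str | Path,
                  config: Optional[PipelineConfig] = None,
                  genes: Optional[Iterable[GeneModel]] = None) -> None:
    """Write all stage outputs, the gene profiles, an oncoprint-style
    matrix, cohort frequencies and (when gene models are given) a
    circos-style fusion link track."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cnv_rows = [{
        "gene_id": c.gene_id, "sample_id": c.sample_id, "status": c.status,
        "focal": int(c.focal), "copy_number": c.copy_number,
        "segment_key": c.segment_key,
    } for c in result.cnv_calls]
    write_dataframe(
        pd.DataFrame(cnv_rows, columns=["gene_id", "sample_id", "status",
                                        "focal", "copy_number",
                                        "segment_key"]),
        out / "gene_cnv_calls.tsv", config)

    expr_rows = [{
        "gene_id": c.gene_id, "sample_id": c.sample_id, "status": c.status,
        "log_expr": round(c.log_expr, 10), "percentile": round(c.percentile, 10),
    } for c in result.expr_calls]
    write_dataframe(
        pd.DataFrame(expr_rows, columns=["gene_id", "sample_id", "status",
                                         "log_expr", "percentile"]),
        out / "expression_calls.tsv", config)

    write_table(result.variants.passed, out / "variants_passed.tsv",
                VariantCall, config)
    rej_rows = sorted(
        ({"sample_id": v.sample_id, "chrom": v.chrom, "pos": v.pos,
          "ref": v.ref, "alt": v.alt, "gene_id": v.gene_id, "reason": reason}
         for v, reason in result.variants.rejected),
        key=lambda r: (r["sample_id"], r["chrom"], r["pos"], r["ref"],
                       r["alt"], r["reason"]),
    )
    write_dataframe(
        pd.DataFrame(rej_rows, columns=["sample_id", "chrom", "pos", "ref",
                                        "alt", "gene_id", "reason"]),
        out / "variants_rejected.tsv", config)

    write_table(result.fusions_kept, out / "fusions_kept.tsv", FusionCall,
                config)
    write_table(result.events, out / "events.tsv", AlterationEvent, config)
    write_dataframe(_profiles_frame(result.profiles),
                    out / "gene_profiles.tsv", config)

    samples = sorted({e.sample_id for e in result.events}) or ["none"]
    profile_genes = [p.gene_id for p in result.profiles]
    if profile_genes:
        onc = oncoprint_matrix(
            [e for e in result.events if e.gene_id in set(profile_genes)],
            gene_ids=sorted(profile_genes), sample_ids=samples)
        write_dataframe(onc, out / "oncoprint.tsv", config, index=True)
        freq = cumulative_frequency(
            [e for e in result.events if e.gene_id in set(profile_genes)],
            samples, sorted(profile_genes), config)
        freq_rows = [dict(r.__dict__) for r in freq]
        write_dataframe(
            pd.DataFrame(freq_rows).sort_values(
                ["freq_cumulative", "gene_id"],
                ascending=[False, True]),
            out / "cohort_frequency.tsv", config)

    if genes is not None:
        write_dataframe(fusion_tracks(result.fusions_kept, genes),
                        out / "fusion_tracks.tsv", config)
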