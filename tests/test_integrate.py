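"""Three-step prioritization: concordance, mutation support, pooling."""

import pytest

from convergene.cnv import GeneCnvCall
from convergene.core import PipelineConfig
from convergene.expression import ExpressionCall
from convergene.integrate import (
    collect_events,
    step1_cnv_expression,
    step2_mutation_support,
    step3_prioritize,
)
from convergene.io import VariantCall


def cnv(gene, sample, status, cn=5.0):
    return GeneCnvCall(gene, sample, status, True, cn, f"seg:{gene}:{sample}")


def expr(gene, sample, status, log_expr=1.0, pct=80.0):
    return ExpressionCall(gene, sample, status, log_expr, pct)


def mut(gene, sample, pos=100):
    return VariantCall(sample, "1", pos, "A", "T", gene, "missense", 50,
                       False, False, ("D", "D", "T"), "exome")


class TestStep1:
    def test_amp_plus_high_same_sample_selected(self):
        sel = step1_cnv_expression([cnv("G1", "S1", "amplified")],
                                   [expr("G1", "S1", "high")])
        assert set(sel) == {"G1"}
        assert len(sel["G1"]) == 2  # one cnv + one expression event

    def test_discordant_not_selected(self):
        sel = step1_cnv_expression([cnv("G1", "S1", "deleted")],
                                   [expr("G1", "S1", "high")])
        assert sel == {}

    def test_cross_sample_combination_not_step1(self):
        sel = step1_cnv_expression([cnv("G1", "S1", "amplified")],
                                   [expr("G1", "S2", "high"),
                                    expr("G1", "S1", "intermediate")])
        assert sel == {}

    def test_deleted_plus_low_selected(self):
        sel = step1_cnv_expression([cnv("G1", "S1", "deleted", 1.0)],
                                   [expr("G1", "S1", "low", 0.2, 5.0)])
        assert set(sel) == {"G1"}


class TestStep2:
    def test_mutation_in_expressed_gene_selected(self):
        sel = step2_mutation_support([mut("G1", "S1")],
                                     [expr("G1", "S1", "intermediate")], [])
        assert set(sel) == {"G1"}

    def test_mutation_in_silent_gene_without_cnv_not_selected(self):
        sel = step2_mutation_support(
            [mut("G1", "S1")],
            [expr("G1", "S1", "not_expressed", 0.0, float("nan"))], [])
        assert sel == {}

    def test_silent_mutation_rescued_by_cnv_in_other_sample(self):
        sel = step2_mutation_support(
            [mut("G1", "S1")],
            [expr("G1", "S1", "not_expressed", 0.0, float("nan"))],
            [cnv("G1", "S2", "deleted", 0.0)])
        assert set(sel) == {"G1"}
        types = {e.alteration_type for e in sel["G1"]}
        assert types == {"mutation", "cnv"}


class TestStep3:
    def test_types_pooled_across_samples(self, config):
        cnv_calls = [cnv("G1", "S2", "amplified")]
        expr_calls = [expr("G1", "S2", "high"),
                      expr("G1", "S1", "intermediate")]
        variants = [mut("G1", "S1")]
        events = collect_events(cnv_calls, expr_calls, variants)
        s1 = step1_cnv_expression(cnv_calls, expr_calls)
        s2 = step2_mutation_support(variants, expr_calls, cnv_calls)
        (p,) = step3_prioritize(s1, s2, events, config)
        assert p.prioritized and p.n_types == 3
        assert p.samples_affected == {"S1", "S2"}

    def test_detectable_alone_is_not_an_alteration(self, config):
        expr_calls = [expr("G1", "S1", "intermediate")]
        variants = [mut("G1", "S1")]
        events = collect_events([], expr_calls, variants)
        s2 = step2_mutation_support(variants, expr_calls, [])
        (p,) = step3_prioritize({}, s2, events, config)
        assert p.n_types == 1 and not p.prioritized

    def test_mutation_plus_overexpression_copy_neutral_prioritized(self,
                                                                   config):
        expr_calls = [expr("G1", "S1", "high")]
        variants = [mut("G1", "S1")]
        events = collect_events([], expr_calls, variants)
        s2 = step2_mutation_support(variants, expr_calls, [])
        (p,) = step3_prioritize({}, s2, events, config)
        assert p.prioritized and p.types_present == {"mutation", "expression"}

    def test_fusion_events_excluded_by_default(self, config):
        from convergene.fusions import fusions_to_events
        from convergene.io import FusionCall
        expr_calls = [expr("G1", "S1", "intermediate")]
        variants = [mut("G1", "S1")]
        fev = fusions_to_events([FusionCall("S1", "G1", "G2", 20)])
        events = collect_events([], expr_calls, variants, fev)
        s2 = step2_mutation_support(variants, expr_calls, [])
        (p,) = step3_prioritize({}, s2, events, config)
        assert not p.prioritized
        enabled = PipelineConfig(count_fusions_in_integration=True)
        (q,) = step3_prioritize({}, s2, events, enabled)
        assert q.prioritized and "fusion" in q.types_present


class TestPipelineProperties:
    def test_prioritized_subset_of_candidates(self, default_result):
        r = default_result
        candidates = r.step1_genes | r.step2_genes
        assert set(r.prioritized) <= candidates

    def test_type_counts_match_bruteforce_rescan(self, default_result,
                                                 config):
        by_gene = {}
        for e in default_result.events:
            if e.alteration_type == "fusion":
                continue  # not counted by default
            by_gene.setdefault(e.gene_id, set()).add(e.alteration_type)
        for p in default_result.profiles:
            assert p.n_types == len(by_gene.get(p.gene_id, set()))
            if p.prioritized:
                assert p.n_types >= config.min_alteration_types

    def test_min_types_one_makes_all_candidates_prioritized(self,
                                                            default_result):
        cfg = PipelineConfig(min_alteration_types=1)
        s1 = {g: [] for g in default_result.step1_genes}
        s2 = {g: [] for g in default_result.step2_genes}
        profiles = step3_prioritize(s1, s2, default_result.events, cfg)
        assert {p.gene_id for p in profiles if p.prioritized} == \
            default_result.step1_genes | default_result.step2_genes

    def test_adding_a_sample_never_removes_a_gene(self, default_cohort,
                                                  config):
        """Prioritization is monotone: a sub-cohort's prioritized set is a
        subset of the full cohort's."""
        from convergene.pipeline import run_pipeline
        c = default_cohort
        keep = set(c.params.sample_ids[:-1])
        sub = run_pipeline(
            c.genes,
            [s for s in c.segments if s.sample_id in keep],
            [r for r in c.expression if r.sample_id in keep],
            [v for v in c.exome if v.sample_id in keep],
            [v for v in c.transcriptome if v.sample_id in keep],
            [f for f in c.fusions if f.sample_id in keep],
            config)
        full = run_pipeline(c.genes, c.segments, c.expression, c.exome,
                            c.transcriptome, c.fusions, config)
        assert set(sub.prioritized) <= set(full.prioritized)
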