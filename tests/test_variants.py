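"""Variant filter cascade: truth tables, ordering, conservation."""

import itertools

import numpy as np
import pytest

from convergene.core import PipelineConfig
from convergene.io import VariantCall
from convergene.variants import (
    cross_validate,
    filter_coverage,
    filter_deleterious,
    run_variant_stage,
    subtract_germline,
    vote_deleterious,
)


def var(sample="S1", chrom="1", pos=100, ref="A", alt="T", gene="G1",
        effect="missense", coverage=50, dbsnp=False, cosmic=False,
        preds=("D", "D", "T"), platform="exome"):
    return VariantCall(sample, chrom, pos, ref, alt, gene, effect, coverage,
                       dbsnp, cosmic, tuple(preds), platform)


class TestCoverage:
    @pytest.mark.parametrize("cov,passes", [(4, False), (5, True),
                                            (0, False), (6, True)])
    def test_boundary(self, cov, passes, config):
        out = filter_coverage([var(coverage=cov)], config)
        assert bool(out.passed) is passes
        if not passes:
            assert out.rejected[0][1] == "low_coverage"


class TestGermlineSubtraction:
    @pytest.mark.parametrize("dbsnp,cosmic,passes", [
        (True, False, False),   # polymorphism only: subtracted
        (True, True, True),     # somatic-catalog membership rescues
        (False, False, True),
        (False, True, True),
    ])
    def test_four_flag_combinations(self, dbsnp, cosmic, passes):
        out = subtract_germline([var(dbsnp=dbsnp, cosmic=cosmic)])
        assert bool(out.passed) is passes
        if not passes:
            assert out.rejected[0][1] == "dbsnp_only"


class TestPredictionVote:
    def test_two_of_three(self, config):
        assert vote_deleterious(var(preds=("D", "D", "T")), config)
        assert not vote_deleterious(var(preds=("D", ".", ".")), config)

    def test_exhaustive_27_triples(self, config):
        """All verdict triples; pass iff >= 2 'D' — 7 of 27 combinations."""
        passing = 0
        for triple in itertools.product("DT.", repeat=3):
            expected = sum(1 for p in triple if p == "D") >= 2
            got = vote_deleterious(var(preds=triple), config)
            assert got is expected, triple
            passing += got
        assert passing == 7

    @pytest.mark.parametrize("effect", ["nonsense", "frameshift", "splice"])
    def test_truncating_effects_bypass_vote(self, effect, config):
        assert vote_deleterious(var(effect=effect, preds=(".", ".", ".")),
                                config)

    def test_inframe_does_not_bypass(self, config):
        assert not vote_deleterious(var(effect="inframe", preds=(".", ".", ".")),
                                    config)


class TestCrossValidation:
    def test_identical_key_passes(self, config):
        t = var(platform="transcriptome", coverage=7)
        out = cross_validate([var()], [t], config)
        assert len(out.passed) == 1
        assert out.passed[0].coverage == 50   # exome record retained

    def test_allele_mismatch_rejected(self, config):
        t = var(platform="transcriptome", alt="G")
        out = cross_validate([var()], [t], config)
        assert out.rejected[0][1] == "no_transcriptome_support"

    def test_empty_transcriptome_rejects_all(self, config):
        out = cross_validate([var(), var(pos=200)], [], config)
        assert not out.passed and len(out.rejected) == 2

    def test_position_only_mode(self):
        cfg = PipelineConfig(match_positions_only=True)
        t = var(platform="transcriptome", alt="G")
        out = cross_validate([var()], [t], cfg)
        assert len(out.passed) == 1


class TestFullStage:
    def test_first_failing_reason_wins(self, config):
        v = var(coverage=2, dbsnp=True)  # fails coverage AND germline
        out = run_variant_stage([v], [], config)
        assert out.rejected[0][1] == "low_coverage"

    def test_synonymous_dropped_first(self, config):
        v = var(effect="synonymous", coverage=1)
        out = run_variant_stage([v], [], config)
        assert out.rejected[0][1] == "synonymous"

    def test_unassigned_gene_dropped_last(self, config):
        v = var(gene="")
        out = run_variant_stage([v], [var(platform="transcriptome")], config)
        assert out.rejected[0][1] == "unassigned_gene"

    def test_empty_input(self, config):
        out = run_variant_stage([], [], config)
        assert out.passed == [] and out.rejected == []

    def test_conservation_at_every_stage(self, default_cohort, config):
        exome = default_cohort.exome
        out = run_variant_stage(exome, default_cohort.transcriptome, config)
        assert len(out.passed) + len(out.rejected) == len(exome)

    def test_single_filters_idempotent(self, config):
        rng = np.random.default_rng(2)
        pool = [var(pos=i, coverage=int(rng.integers(0, 12)),
                    dbsnp=bool(rng.integers(2)), cosmic=bool(rng.integers(2)))
                for i in range(60)]
        once = filter_coverage(pool, config)
        twice = filter_coverage(once.passed, config)
        assert twice.passed == once.passed and not twice.rejected
        g_once = subtract_germline(pool)
        g_twice = subtract_germline(g_once.passed)
        assert g_twice.passed == g_once.passed and not g_twice.rejected

    def test_coverage_and_germline_commute(self, config):
        rng = np.random.default_rng(4)
        pool = [var(pos=i, coverage=int(rng.integers(0, 12)),
                    dbsnp=bool(rng.integers(2)), cosmic=bool(rng.integers(2)))
                for i in range(80)]
        ab = subtract_germline(filter_coverage(pool, config).passed).passed
        ba = filter_coverage(subtract_germline(pool).passed, config).passed
        assert ab == ba

    def test_synthetic_passed_set_equals_planted(self, default_cohort,
                                                 default_result):
        planted = set()
        truth = default_cohort.truth
        for events in list(truth.multi_altered.values()) + \
                list(truth.single_altered.values()):
            for e in events:
                if e.alteration_type == "mutation":
                    planted.add((e.gene_id, e.sample_id))
        got = {(v.gene_id, v.sample_id)
               for v in default_result.variants.passed}
        assert got == planted
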