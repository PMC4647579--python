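"""Synthetic cohort: determinism, planted truth, filter observability."""

import hashlib
from pathlib import Path

import pytest

from convergene.cnv import ARM_LEVEL, FOCAL, classify_segment
from convergene.core import PipelineConfig
from convergene.simulate import (
    SimulationError,
    SimulationParams,
    read_cohort,
    simulate_cohort,
    write_cohort,
)


def dir_digest(d: Path) -> dict:
    return {f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(Path(d).iterdir())}


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_cohort(SimulationParams(seed=5, n_genes=400,
                                            n_multi_altered=5,
                                            n_single_altered=30))


class TestDeterminism:
    def test_same_seed_identical_bytes(self, tmp_path):
        params = SimulationParams(seed=9, n_genes=300, n_multi_altered=4,
                                  n_single_altered=20)
        write_cohort(simulate_cohort(params), tmp_path / "a")
        write_cohort(simulate_cohort(params), tmp_path / "b")
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        base = dict(n_genes=300, n_multi_altered=4, n_single_altered=20)
        write_cohort(simulate_cohort(SimulationParams(seed=1, **base)),
                     tmp_path / "a")
        write_cohort(simulate_cohort(SimulationParams(seed=2, **base)),
                     tmp_path / "b")
        assert dir_digest(tmp_path / "a") != dir_digest(tmp_path / "b")


class TestTruthTable:
    def test_planted_counts_match_params(self, small_cohort):
        t = small_cohort.truth
        assert len(t.multi_altered) == 5
        assert len(t.single_altered) == 30
        assert len(t.clean) == 400 - 5 - 30

    def test_roles_partition_gene_universe(self, small_cohort):
        t = small_cohort.truth
        all_ids = {g.gene_id for g in small_cohort.genes}
        union = t.multi_genes | t.single_genes | set(t.clean)
        assert union == all_ids
        assert not (t.multi_genes & t.single_genes)
        assert not (t.multi_genes & set(t.clean))

    def test_multi_genes_have_two_plus_types(self, small_cohort):
        for gene, events in small_cohort.truth.multi_altered.items():
            assert len({e.alteration_type for e in events}) >= 2, gene

    def test_both_within_and_across_sample_patterns_present(self,
                                                            default_cohort):
        within = across = 0
        for events in default_cohort.truth.multi_altered.values():
            samples = {e.sample_id for e in events}
            if len(samples) == 1:
                within += 1
            else:
                across += 1
        assert within > 0 and across > 0

    def test_single_genes_have_exactly_one_event(self, small_cohort):
        for gene, events in small_cohort.truth.single_altered.items():
            assert len(events) == 1, gene

    def test_truth_json_roundtrip(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        back = read_cohort(tmp_path)["truth"]
        assert back.multi_altered == small_cohort.truth.multi_altered
        assert back.single_altered == small_cohort.truth.single_altered
        assert back.clean == small_cohort.truth.clean


class TestFilterObservability:
    """Every pipeline filter sees at least one passing and one failing
    record in the default cohort."""

    def test_segments_span_focal_and_arm_level(self, default_cohort, config):
        classes = {classify_segment(s, config)
                   for s in default_cohort.segments}
        assert classes == {FOCAL, ARM_LEVEL}

    def test_neutral_focal_segments_present(self, default_cohort, config):
        assert any(
            classify_segment(s, config) == FOCAL
            and s.copy_number == config.neutral_copies
            for s in default_cohort.segments)

    def test_every_rejection_reason_observed(self, default_result):
        reasons = {r for _, r in default_result.variants.rejected}
        assert reasons == {"synonymous", "low_coverage", "dbsnp_only",
                           "not_deleterious", "no_transcriptome_support",
                           "unassigned_gene"}
        assert default_result.variants.passed

    def test_cosmic_rescue_present_among_passed(self, default_result):
        assert any(v.in_dbsnp and v.in_cosmic
                   for v in default_result.variants.passed)

    def test_truncating_bypass_present_among_passed(self, default_result):
        assert any(v.effect == "nonsense"
                   for v in default_result.variants.passed)

    def test_fusions_span_threshold(self, default_cohort, config):
        rp = [f.read_pairs for f in default_cohort.fusions]
        assert any(r >= config.min_fusion_read_pairs for r in rp)
        assert any(r < config.min_fusion_read_pairs for r in rp)
        assert config.min_fusion_read_pairs in rp  # exact boundary present

    def test_expression_statuses_all_present(self, default_result):
        statuses = {c.status for c in default_result.expr_calls}
        assert statuses == {"not_expressed", "low", "intermediate", "high"}


class TestExpressionBackground:
    def test_not_expressed_fraction_near_parameter(self, default_cohort,
                                                   config):
        p = default_cohort.params
        by_gene: dict = {}
        for r in default_cohort.expression:
            by_gene.setdefault(r.gene_id, []).append(r.log_expr)
        silent = sum(1 for vals in by_gene.values()
                     if all(v < config.expr_noise_floor for v in vals))
        n = len(by_gene)
        expect = p.frac_not_expressed
        sd = (expect * (1 - expect) / n) ** 0.5
        # planted genes are forced expressed, shifting the fraction down a
        # little; allow 3 binomial SD around the adjusted expectation
        adjusted = expect * (n - p.n_multi_altered - p.n_single_altered) / n
        assert abs(silent / n - adjusted) <= 3 * sd + 0.01


class TestConstraints:
    def test_gene_intervals_do_not_overlap_within_chrom(self, small_cohort):
        by_chrom: dict = {}
        for g in small_cohort.genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_infeasible_params_rejected(self):
        with pytest.raises(SimulationError):
            SimulationParams(n_genes=10, n_multi_altered=8,
                             n_single_altered=8)
        with pytest.raises(SimulationError):
            simulate_cohort(SimulationParams(n_genes=100_000))
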