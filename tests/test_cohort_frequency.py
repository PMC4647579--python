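"""Cumulative alteration frequency and the three-class typology."""

import numpy as np
import pytest

from convergene.cohort import (
    CohortFrequencyRecord,
    classify_gene,
    cumulative_frequency,
    oncoprint_matrix,
    select_frequent_genes,
)
from convergene.core import AlterationEvent, PipelineConfig


def ev(gene, sample, etype="mutation", direction=None):
    if direction is None:
        direction = ("not_applicable" if etype in ("mutation", "fusion")
                     else "gain")
    return AlterationEvent(gene, sample, etype, direction)


def rec(fm=0.0, fce=0.0, **kw):
    base = dict(gene_id="G", n_samples=10, freq_mutation=fm, freq_cnv=0.0,
                freq_expression=0.0, freq_fusion=0.0, freq_cnv_expr=fce,
                freq_cumulative=max(fm, fce), gene_class="mixed")
    base.update(kw)
    return CohortFrequencyRecord(**base)


class TestCumulativeFrequency:
    def test_union_not_sum(self):
        samples = [f"s{i}" for i in range(1, 11)]
        events = ([ev("G1", s) for s in ("s1", "s2")]
                  + [ev("G1", s, "cnv") for s in ("s2", "s3", "s4")])
        (r,) = cumulative_frequency(events, samples, ["G1"])
        assert r.freq_mutation == pytest.approx(0.2)
        assert r.freq_cnv == pytest.approx(0.3)
        assert r.freq_cumulative == pytest.approx(0.4)  # s2 counted once

    def test_gene_without_events_all_zero(self):
        (r,) = cumulative_frequency([], ["s1", "s2"], ["G1"])
        assert r.freq_cumulative == 0.0 and r.gene_class == "mixed"

    def test_no_samples_errors(self):
        with pytest.raises(ValueError):
            cumulative_frequency([], [], ["G1"])

    def test_random_matrices_match_union_oracle(self):
        rng = np.random.default_rng(17)
        types = ["mutation", "cnv", "expression", "fusion"]
        for _ in range(30):
            n_s, n_g = int(rng.integers(2, 10)), int(rng.integers(1, 12))
            samples = [f"s{i}" for i in range(n_s)]
            genes = [f"g{i}" for i in range(n_g)]
            events = []
            for g in genes:
                for s in samples:
                    for t in types:
                        if rng.random() < 0.2:
                            events.append(ev(g, s, t))
            records = cumulative_frequency(events, samples, genes)
            for r in records:
                hit = {e.sample_id for e in events if e.gene_id == r.gene_id}
                assert r.freq_cumulative == pytest.approx(len(hit) / n_s)
                per_type = [r.freq_mutation, r.freq_cnv, r.freq_expression,
                            r.freq_fusion]
                assert max(per_type) <= r.freq_cumulative + 1e-12
                assert r.freq_cumulative <= min(1.0, sum(per_type)) + 1e-12

    def test_permutation_invariant_in_sample_order(self):
        samples = ["a", "b", "c"]
        events = [ev("G1", "a"), ev("G1", "c", "cnv")]
        r1 = cumulative_frequency(events, samples, ["G1"])
        r2 = cumulative_frequency(events, samples[::-1], ["G1"])
        assert r1 == r2


class TestSelectFrequentGenes:
    def test_mutation_frequency_floor(self, config):
        records = [rec(fm=0.03, gene_id="KEEP"),
                   rec(fm=0.029, gene_id="DROP"),
                   rec(fm=0.5, fce=0.5, gene_id="TOP",
                       freq_cumulative=0.8)]
        assert select_frequent_genes(records, config) == ["TOP", "KEEP"]

    def test_empty(self, config):
        assert select_frequent_genes([], config) == []


class TestClassifyGene:
    @pytest.mark.parametrize("fm,fce,expected", [
        (0.30, 0.02, "mutation_dominant"),
        (0.05, 0.30, "cnv_expression_dominant"),
        (0.10, 0.12, "mixed"),
        (0.0, 0.0, "mixed"),
        (0.30, 0.0, "mutation_dominant"),
    ])
    def test_dominance_rule(self, fm, fce, expected, config):
        assert classify_gene(rec(fm=fm, fce=fce), config).gene_class == expected

    def test_stable_under_common_scaling(self, config):
        a = classify_gene(rec(fm=0.3, fce=0.05), config).gene_class
        b = classify_gene(rec(fm=0.06, fce=0.01), config).gene_class
        assert a == b == "mutation_dominant"

    def test_exactly_one_class(self, config):
        rng = np.random.default_rng(8)
        from convergene.cohort import GENE_CLASSES
        for _ in range(100):
            r = rec(fm=float(rng.random()), fce=float(rng.random()))
            assert classify_gene(r, config).gene_class in GENE_CLASSES


class TestOncoprint:
    def test_cell_codes_ordered(self):
        events = [ev("G1", "s1", "cnv", "gain"),
                  ev("G1", "s1", "mutation"),
                  ev("G1", "s2", "expression", "loss"),
                  ev("G2", "s2", "cnv", "loss")]
        m = oncoprint_matrix(events)
        assert m.loc["G1", "s1"] == "AM"
        assert m.loc["G1", "s2"] == "L"
        assert m.loc["G2", "s1"] == ""
        assert m.loc["G2", "s2"] == "D"
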