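"""Synthetic multi-platform cohort with a planted, machine-checkable truth.

The default parameters emulate a four-sample hyperploid cancer cell-line
cohort profiled on three platforms: copy-number segments, an FPKM
expression matrix (bimodal: a log-normal expressed component over a
noise-floor component), and exome plus transcriptome variant tables with
coverage, catalog flags and three functional-prediction verdicts, plus a
fusion candidate table.

Ground truth is planted by construction:

* ``multi_altered`` genes each receive at least two distinct alteration
  types, arranged either within one sample or split across samples (both
  patterns are represented), every planted event built to pass its stage
  filter;
* ``single_altered`` genes receive exactly one passing event (a focal CNV,
  an expression change, a filtered mutation, or a supported fusion) and are
  constructed collision-free so they can never reach two alteration types;
* ``clean`` genes receive only events designed to *fail* a specific filter
  (dbSNP-only variants, 1-4X coverage, non-deleterious verdicts, missing
  transcriptome support, synonymous changes, neutral-copy focal segments,
  under-supported fusions, sub-floor expression), so every filter's
  behaviour is observable in the default cohort.

Generation is deterministic given the seed; each data type draws from its
own random stream spawned from the master seed, so adding one data type
never perturbs another's draws. After construction the generator re-checks
every planted event against the actual stage implementations and refuses to
return a cohort that violates its own truth table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import AlterationEvent, GeneModel, GenomicInterval, PipelineConfig
from .cnv import call_gene_cnv
from .expression import classify_expression
from .io import (
    CnvSegment,
    ExpressionRecord,
    FusionCall,
    VariantCall,
    write_expression_matrix,
    write_gene_models_bed,
    write_table,
)
from .variants import run_variant_stage

__all__ = ["SimulationParams", "TruthTable", "Cohort", "simulate_cohort",
           "write_cohort", "read_cohort", "SimulationError"]

_DEFAULT_GENOME = tuple((str(i), 50_000_000) for i in range(1, 6))

# base-pair margin kept free on each side of a gene within its slot; planted
# segments may extend at most _SEG_PAD_MAX into it, so a segment never
# reaches a neighbouring gene
_GENE_PAD = 12_000
_SEG_PAD_MAX = 10_000


class SimulationError(RuntimeError):
    """Raised when parameters are infeasible or a planted event fails its
    own stage filter on re-check."""


@dataclass
class SimulationParams:
    """Cohort-generator knobs; defaults are the study conditions.

    ``fpkm_lognormal_mu``/``sigma`` parameterize the expressed component in
    natural-log FPKM space (median ~7 FPKM, a realistic bulk RNA-seq
    spread); ``frac_not_expressed`` puts a quarter of genes at noise level;
    ``coverage_mean`` matches ~80X exome depth. ``germline_rate`` and
    ``somatic_rate`` are expected decoy variants per clean gene.
    """

    n_samples: int = 4
    n_genes: int = 2_000
    genome: tuple = _DEFAULT_GENOME
    seed: int = 0
    n_multi_altered: int = 20
    n_single_altered: int = 100
    fpkm_lognormal_mu: float = 2.0
    fpkm_lognormal_sigma: float = 1.2
    frac_not_expressed: float = 0.25
    germline_rate: float = 0.2
    somatic_rate: float = 0.15
    coverage_mean: float = 80.0

    def __post_init__(self) -> None:
        if self.n_multi_altered + self.n_single_altered > self.n_genes:
            raise SimulationError(
                "n_multi_altered + n_single_altered exceeds n_genes"
            )
        for name in ("germline_rate", "somatic_rate", "coverage_mean"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not 0 <= self.frac_not_expressed < 1:
            raise SimulationError("frac_not_expressed must be in [0, 1)")
        if self.n_samples < 1 or self.n_genes < 1:
            raise SimulationError("need at least one sample and one gene")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass
class TruthTable:
    """Planted ground truth: the acceptance oracle for the whole pipeline.

    The three gene sets partition the gene universe. Event lists hold the
    planted *passing* events per gene (evidence prefixed ``planted:``).
    """

    multi_altered: dict[str, list[AlterationEvent]]
    single_altered: dict[str, list[AlterationEvent]]
    clean: list[str]

    @property
    def multi_genes(self) -> set[str]:
        return set(self.multi_altered)

    @property
    def single_genes(self) -> set[str]:
        return set(self.single_altered)

    def to_json(self) -> str:
        def dump(events):
            return [e.__dict__ for e in events]
        return json.dumps(
            {
                "multi_altered": {g: dump(v) for g, v in
                                  sorted(self.multi_altered.items())},
                "single_altered": {g: dump(v) for g, v in
                                   sorted(self.single_altered.items())},
                "clean": sorted(self.clean),
            },
            indent=1, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        raw = json.loads(text)
        def load(d):
            return {g: [AlterationEvent(**e) for e in evs]
                    for g, evs in d.items()}
        return cls(multi_altered=load(raw["multi_altered"]),
                   single_altered=load(raw["single_altered"]),
                   clean=list(raw["clean"]))


@dataclass
class Cohort:
    """Everything one simulated study produces, in memory."""

    params: SimulationParams
    genes: list[GeneModel]
    segments: list[CnvSegment]
    expression: list[ExpressionRecord]
    exome: list[VariantCall]
    transcriptome: list[VariantCall]
    fusions: list[FusionCall]
    truth: TruthTable


# ---------------------------------------------------------------------------
# internal builder


class _Builder:
    def __init__(self, params: SimulationParams, config: PipelineConfig):
        self.p = params
        self.c = config
        streams = np.random.SeedSequence(params.seed).spawn(6)
        (self.rng_genes, self.rng_roles, self.rng_expr,
         self.rng_cnv, self.rng_var, self.rng_fus) = (
            np.random.default_rng(s) for s in streams)

        self.samples = params.sample_ids
        self.genes: list[GeneModel] = []
        self.segments: list[CnvSegment] = []
        self.exome: list[VariantCall] = []
        self.transcriptome: list[VariantCall] = []
        self.fusions: list[FusionCall] = []
        # (gene_id, sample_id) -> desired expression status
        self.expr_overrides: dict[tuple[str, str], str] = {}
        self.truth_multi: dict[str, list[AlterationEvent]] = {}
        self.truth_single: dict[str, list[AlterationEvent]] = {}
        self.planted_cnv: dict[tuple[str, str], str] = {}  # -> status
        self.used_variant_keys: set[tuple] = set()
        self._floor_fpkm = 10.0 ** config.expr_noise_floor - 1.0

    # -- gene universe ----------------------------------------------------

    def build_genes(self) -> None:
        p = self.p
        total_len = sum(l for _, l in p.genome)
        counts = [int(p.n_genes * l / total_len) for _, l in p.genome]
        i = 0
        while sum(counts) < p.n_genes:
            counts[i % len(counts)] += 1
            i += 1
        gi = 0
        self._slot: dict[str, tuple[int, int]] = {}
        for (chrom, length), n_chrom in zip(p.genome, counts):
            if n_chrom == 0:
                continue
            slot = length // n_chrom
            if slot < 60_000 + 2 * _GENE_PAD + 2:
                raise SimulationError(
                    f"too many genes for chromosome {chrom}: slot {slot} bp"
                )
            for k in range(n_chrom):
                gene_len = int(self.rng_genes.integers(5_000, 60_001))
                lo = k * slot + _GENE_PAD
                hi = (k + 1) * slot - _GENE_PAD - gene_len
                start = int(self.rng_genes.integers(lo, hi + 1))
                gid = f"G{gi:05d}"
                self.genes.append(GeneModel(
                    gene_id=gid, symbol=f"SYM{gi:05d}",
                    interval=GenomicInterval(chrom, start, start + gene_len),
                    strand="+" if self.rng_genes.random() < 0.5 else "-",
                ))
                self._slot[gid] = (k * slot, (k + 1) * slot)
                gi += 1
        self.gene_by_id = {g.gene_id: g for g in self.genes}

    def assign_roles(self) -> None:
        ids = [g.gene_id for g in self.genes]
        perm = self.rng_roles.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        p = self.p
        self.multi_ids = shuffled[:p.n_multi_altered]
        self.single_ids = shuffled[p.n_multi_altered:
                                   p.n_multi_altered + p.n_single_altered]
        self.clean_ids = shuffled[p.n_multi_altered + p.n_single_altered:]

    # -- planted event helpers -------------------------------------------

    def _pick_sample(self, rng) -> str:
        return self.samples[int(rng.integers(0, len(self.samples)))]

    def _other_sample(self, sample: str, rng) -> str:
        if len(self.samples) == 1:
            return sample
        while True:
            s = self._pick_sample(rng)
            if s != sample:
                return s

    def plant_cnv(self, gene_id: str, sample: str, status: str) -> AlterationEvent:
        g = self.gene_by_id[gene_id]
        slot_lo, slot_hi = self._slot[gene_id]
        pad5 = int(self.rng_cnv.integers(2_000, _SEG_PAD_MAX + 1))
        pad3 = int(self.rng_cnv.integers(2_000, _SEG_PAD_MAX + 1))
        start = max(slot_lo, g.interval.start - pad5)
        end = min(slot_hi, g.interval.end + pad3)
        if status == "amplified":
            cn = float(self.rng_cnv.integers(int(self.c.amp_min_copies) + 1,
                                             int(self.c.amp_min_copies) + 6))
        else:
            cn = float(self.rng_cnv.integers(0, int(self.c.del_max_copies) + 1))
        seg = CnvSegment(
            sample_id=sample,
            interval=GenomicInterval(g.interval.chrom, start, end),
            copy_number=cn,
            n_probes=max(3, (end - start) // 6_000),
        )
        self.segments.append(seg)
        self.planted_cnv[(gene_id, sample)] = status
        return AlterationEvent(
            gene_id=gene_id, sample_id=sample, alteration_type="cnv",
            direction="gain" if status == "amplified" else "loss",
            evidence=f"planted:cnv:{seg.key}",
        )

    def plant_expression(self, gene_id: str, sample: str,
                         status: str) -> AlterationEvent:
        self.expr_overrides[(gene_id, sample)] = status
        return AlterationEvent(
            gene_id=gene_id, sample_id=sample, alteration_type="expression",
            direction="gain" if status == "high" else "loss",
            evidence=f"planted:expr:{sample}:{status}",
        )

    def force_intermediate(self, gene_id: str, samples) -> None:
        for s in samples:
            self.expr_overrides.setdefault((gene_id, s), "intermediate")

    def _variant_pos(self, gene_id: str, sample: str, rng) -> tuple[int, str, str]:
        g = self.gene_by_id[gene_id]
        bases = "ACGT"
        for _ in range(100):
            pos = int(g.interval.start
                      + rng.integers(0, g.interval.length))
            ref, alt = rng.choice(list(bases), size=2, replace=False)
            key = (sample, g.interval.chrom, pos, str(ref), str(alt))
            if key not in self.used_variant_keys:
                self.used_variant_keys.add(key)
                return pos, str(ref), str(alt)
        raise SimulationError(f"cannot place a unique variant in {gene_id}")

    def plant_mutation(self, gene_id: str, sample: str, index: int,
                       ) -> AlterationEvent:
        """A variant built to pass every filter: adequate coverage, not a
        bare dbSNP hit, a 2-of-3 deleterious vote (or truncating), and an
        identical transcriptome record."""
        g = self.gene_by_id[gene_id]
        pos, ref, alt = self._variant_pos(gene_id, sample, self.rng_var)
        truncating = index % 5 == 4  # exercise the truncating-effect bypass
        effect = "nonsense" if truncating else "missense"
        preds = (".", ".", ".") if truncating else [
            ("D", "D", "T"), ("D", "T", "D"), ("T", "D", "D"), ("D", "D", "D"),
        ][index % 4]
        rescued = index % 7 == 6  # dbSNP hit rescued by COSMIC membership
        cov = max(self.c.min_coverage,
                  int(self.rng_var.poisson(self.p.coverage_mean)))
        common = dict(sample_id=sample, chrom=g.interval.chrom, pos=pos,
                      ref=ref, alt=alt, gene_id=gene_id, effect=effect,
                      in_dbsnp=rescued, in_cosmic=rescued,
                      predictions=tuple(preds))
        self.exome.append(VariantCall(platform="exome", coverage=cov, **common))
        tcov = max(1, int(self.rng_var.poisson(self.p.coverage_mean / 2)))
        self.transcriptome.append(VariantCall(platform="transcriptome",
                                              coverage=tcov, **common))
        return AlterationEvent(
            gene_id=gene_id, sample_id=sample, alteration_type="mutation",
            direction="not_applicable",
            evidence=f"planted:var:{g.interval.chrom}:{pos}:{ref}>{alt}",
        )

    # -- roles ------------------------------------------------------------

    def plant_multi(self) -> None:
        """Five recurring patterns, cycled over the multi-altered genes;
        patterns 2 and 3 split their alteration types across samples."""
        for i, gid in enumerate(self.multi_ids):
            pattern = i % 5
            sa = self._pick_sample(self.rng_roles)
            events: list[AlterationEvent] = []
            if pattern == 0:  # amplified + over-expressed, one sample
                events.append(self.plant_cnv(gid, sa, "amplified"))
                events.append(self.plant_expression(gid, sa, "high"))
            elif pattern == 1:  # deleted + under-expressed, one sample
                events.append(self.plant_cnv(gid, sa, "deleted"))
                events.append(self.plant_expression(gid, sa, "low"))
            elif pattern == 2:  # mutation in A; amp + high in B
                sb = self._other_sample(sa, self.rng_roles)
                events.append(self.plant_mutation(gid, sa, i))
                self.force_intermediate(gid, [sa])
                events.append(self.plant_cnv(gid, sb, "amplified"))
                events.append(self.plant_expression(gid, sb, "high"))
            elif pattern == 3:  # mutation in A; amp (dosage-silent) in B
                sb = self._other_sample(sa, self.rng_roles)
                events.append(self.plant_mutation(gid, sa, i))
                self.force_intermediate(gid, [sa, sb])
                events.append(self.plant_cnv(gid, sb, "amplified"))
            else:  # mutation + over-expression, one sample, copy-neutral
                events.append(self.plant_mutation(gid, sa, i))
                events.append(self.plant_expression(gid, sa, "high"))
            self.truth_multi[gid] = events

    def plant_single(self) -> None:
        """Exactly one passing event per gene, collision-free: a mutated
        decoy is pinned to intermediate expression in every sample so the
        pooled profile can never reach a second alteration type."""
        kinds = ["cnv", "expr_high", "expr_low", "mutation", "fusion"]
        i, ci = 0, 0
        n = len(self.single_ids)
        while i < n:
            kind = kinds[ci % len(kinds)]
            ci += 1
            gid = self.single_ids[i]
            sa = self._pick_sample(self.rng_roles)
            if kind == "fusion":
                if i + 1 >= n:
                    kind = "expr_high"
                else:
                    g5, g3 = gid, self.single_ids[i + 1]
                    # first supported fusion sits exactly at the read-pair
                    # threshold so the boundary is observable
                    rp = (self.c.min_fusion_read_pairs if not self.fusions
                          else self.c.min_fusion_read_pairs
                          + int(self.rng_fus.integers(0, 30)))
                    fus = FusionCall(sample_id=sa, gene5=g5, gene3=g3,
                                     read_pairs=rp)
                    self.fusions.append(fus)
                    for g in (g5, g3):
                        self.truth_single[g] = [AlterationEvent(
                            gene_id=g, sample_id=sa,
                            alteration_type="fusion",
                            direction="not_applicable",
                            evidence=f"planted:fusion:{fus.key}",
                        )]
                    i += 2
                    continue
            if kind == "cnv":
                status = "amplified" if i % 2 == 0 else "deleted"
                ev = self.plant_cnv(gid, sa, status)
                self.force_intermediate(gid, [sa])
            elif kind == "expr_high":
                ev = self.plant_expression(gid, sa, "high")
            elif kind == "expr_low":
                ev = self.plant_expression(gid, sa, "low")
            else:  # mutation
                ev = self.plant_mutation(gid, sa, i)
                self.force_intermediate(gid, self.samples)
            self.truth_single[gid] = [ev]
            i += 1

    def plant_clean_decoys(self) -> None:
        """Events built to fail exactly one filter each, guaranteeing every
        filter has both a passing and a failing record in the cohort."""
        modes = ["dbsnp_only", "low_coverage", "not_deleterious",
                 "no_twin", "synonymous"]
        # guaranteed one of each failure mode on the first clean genes
        forced = list(modes)
        mode_idx = 0
        for gid in self.clean_ids:
            if forced:
                n_fail = 1
            else:
                n_fail = int(self.rng_var.poisson(self.p.somatic_rate))
            n_germ = int(self.rng_var.poisson(self.p.germline_rate))
            for _ in range(n_germ):
                self._failing_variant(gid, "dbsnp_only")
            for _ in range(n_fail):
                mode = forced.pop(0) if forced else modes[mode_idx % len(modes)]
                mode_idx += 1
                self._failing_variant(gid, mode)

        # one variant with no assignable gene (intergenic)
        chrom = self.p.genome[0][0]
        key = ("S1", chrom, 100, "A", "T")
        self.used_variant_keys.add(key)
        v = dict(sample_id="S1", chrom=chrom, pos=100, ref="A", alt="T",
                 gene_id="", effect="missense",
                 in_dbsnp=False, in_cosmic=False,
                 predictions=("D", "D", "T"))
        self.exome.append(VariantCall(platform="exome", coverage=60, **v))
        self.transcriptome.append(VariantCall(platform="transcriptome",
                                              coverage=25, **v))

        # neutral-copy focal segments: overlap a gene but call nothing
        for k in range(4):
            gid = self.clean_ids[-(k + 1)]
            g = self.gene_by_id[gid]
            slot_lo, slot_hi = self._slot[gid]
            start = max(slot_lo, g.interval.start - 3_000)
            end = min(slot_hi, g.interval.end + 3_000)
            self.segments.append(CnvSegment(
                sample_id=self._pick_sample(self.rng_cnv),
                interval=GenomicInterval(g.interval.chrom, start, end),
                copy_number=float(self.c.neutral_copies),
                n_probes=max(3, (end - start) // 6_000),
            ))

        # arm-scale amplified segments: excluded by the focal filter no
        # matter how many genes they cover
        for sample in self.samples:
            for _ in range(2):
                self._arm_level_segment(sample)

        # under-supported fusions between clean genes
        for k in range(5):
            g5 = self.clean_ids[2 * k + 10]
            g3 = self.clean_ids[2 * k + 11]
            self.fusions.append(FusionCall(
                sample_id=self._pick_sample(self.rng_fus),
                gene5=g5, gene3=g3,
                read_pairs=int(self.rng_fus.integers(
                    1, self.c.min_fusion_read_pairs)),
            ))

    def _arm_level_segment(self, sample: str) -> None:
        existing = [s.interval for s in self.segments
                    if s.sample_id == sample]
        for _ in range(50):
            chrom, chrom_len = self.p.genome[
                int(self.rng_cnv.integers(0, len(self.p.genome)))]
            length = int(self.rng_cnv.integers(self.c.focal_max_length
                                               + 2_000_000,
                                               self.c.focal_max_length
                                               + 10_000_000))
            if length >= chrom_len:
                continue
            start = int(self.rng_cnv.integers(0, chrom_len - length))
            iv = GenomicInterval(chrom, start, start + length)
            if any(iv.chrom == e.chrom and iv.start < e.end and
                   e.start < iv.end for e in existing):
                continue
            self.segments.append(CnvSegment(
                sample_id=sample, interval=iv,
                copy_number=float(self.rng_cnv.integers(
                    int(self.c.amp_min_copies) + 1,
                    int(self.c.amp_min_copies) + 4)),
                n_probes=length // 6_000,
            ))
            return
        raise SimulationError("could not place an arm-level segment")

    def _failing_variant(self, gid: str, mode: str) -> None:
        g = self.gene_by_id[gid]
        sample = self._pick_sample(self.rng_var)
        pos, ref, alt = self._variant_pos(gid, sample, self.rng_var)
        cov = max(self.c.min_coverage,
                  int(self.rng_var.poisson(self.p.coverage_mean)))
        effect, preds = "missense", ("D", "D", "T")
        in_dbsnp = in_cosmic = False
        twin = True
        if mode == "dbsnp_only":
            in_dbsnp = True
        elif mode == "low_coverage":
            cov = int(self.rng_var.integers(1, self.c.min_coverage))
        elif mode == "not_deleterious":
            preds = [("D", "T", "T"), ("T", "T", "T"), ("D", "T", "."),
                     ("T", ".", ".")][int(self.rng_var.integers(0, 4))]
        elif mode == "no_twin":
            twin = False
        elif mode == "synonymous":
            effect, preds = "synonymous", (".", ".", ".")
        common = dict(sample_id=sample, chrom=g.interval.chrom, pos=pos,
                      ref=ref, alt=alt, gene_id=gid, effect=effect,
                      in_dbsnp=in_dbsnp, in_cosmic=in_cosmic,
                      predictions=tuple(preds))
        self.exome.append(VariantCall(platform="exome", coverage=cov, **common))
        if twin:
            self.transcriptome.append(VariantCall(
                platform="transcriptome",
                coverage=max(1, int(self.rng_var.poisson(
                    self.p.coverage_mean / 2))),
                **common))

    # -- expression matrix ------------------------------------------------

    def build_expression(self) -> list[ExpressionRecord]:
        p, rng = self.p, self.rng_expr
        n_g, n_s = len(self.genes), len(self.samples)
        expressed = rng.random(n_g) >= p.frac_not_expressed
        # genes carrying planted evidence must have an expressed background
        special = set(self.multi_ids) | set(self.single_ids)
        for i, g in enumerate(self.genes):
            if g.gene_id in special:
                expressed[i] = True
        fpkm = np.where(
            expressed[:, None],
            rng.lognormal(p.fpkm_lognormal_mu, p.fpkm_lognormal_sigma,
                          size=(n_g, n_s)),
            rng.uniform(0.0, self._floor_fpkm * 0.95, size=(n_g, n_s)),
        )
        gene_index = {g.gene_id: i for i, g in enumerate(self.genes)}
        sample_index = {s: j for j, s in enumerate(self.samples)}
        # per-sample background statistics (pre-override; the overridden
        # cells are few, so the shift is negligible and re-checked anyway)
        bg = fpkm[expressed, :]
        col_max = bg.max(axis=0)
        col_med = np.median(bg, axis=0)
        for (gid, sid), status in sorted(self.expr_overrides.items()):
            i, j = gene_index[gid], sample_index[sid]
            if status == "high":
                fpkm[i, j] = col_max[j] * (1.5 + rng.random())
            elif status == "low":
                # just above the noise floor: bottom of the expressed range
                fpkm[i, j] = 10.0 ** (self.c.expr_noise_floor + 0.002
                                      + 0.016 * rng.random()) - 1.0
            else:  # intermediate
                fpkm[i, j] = col_med[j] * (0.98 + 0.04 * rng.random())
        return [
            ExpressionRecord(gene_id=g.gene_id, sample_id=s,
                             fpkm=float(fpkm[i, j]))
            for i, g in enumerate(self.genes)
            for j, s in enumerate(self.samples)
        ]

    # -- verification -----------------------------------------------------

    def verify(self, cohort: Cohort) -> None:
        """Re-check every planted event against the real stage filters."""
        expr_calls = classify_expression(cohort.expression, self.c)
        status_by = {(c.gene_id, c.sample_id): c.status for c in expr_calls}
        for (gid, sid), want in self.expr_overrides.items():
            got = status_by.get((gid, sid))
            if got != want:
                raise SimulationError(
                    f"planted expression {want} for {gid}/{sid} classified "
                    f"as {got}"
                )
        cnv_calls = call_gene_cnv(cohort.segments, cohort.genes, self.c)
        cnv_by = {(c.gene_id, c.sample_id): c.status for c in cnv_calls}
        for (gid, sid), want in self.planted_cnv.items():
            if cnv_by.get((gid, sid)) != want:
                raise SimulationError(
                    f"planted {want} segment for {gid}/{sid} produced call "
                    f"{cnv_by.get((gid, sid))}"
                )
        vset = run_variant_stage(cohort.exome, cohort.transcriptome, self.c)
        passed = {v.key() for v in vset.passed}
        planted = {
            (e.sample_id,) + self._evidence_site(e)
            for evs in list(self.truth_multi.values())
            + list(self.truth_single.values())
            for e in evs if e.alteration_type == "mutation"
        }
        if passed != planted:
            raise SimulationError(
                f"variant stage passed {len(passed)} calls but "
                f"{len(planted)} were planted"
            )

    @staticmethod
    def _evidence_site(e: AlterationEvent) -> tuple:
        # planted:var:chrom:pos:REF>ALT
        _, _, chrom, pos, change = e.evidence.split(":")
        ref, alt = change.split(">")
        return (chrom, int(pos), ref, alt)


def simulate_cohort(params: Optional[SimulationParams] = None,
                    config: Optional[PipelineConfig] = None,
                    verify: bool = True) -> Cohort:
    """Generate a deterministic synthetic cohort with planted ground truth.

    ``config`` supplies the filter thresholds the plants must satisfy;
    with ``verify`` (default) every planted event is re-checked against the
    actual stage implementations before the cohort is returned.
    """
    params = params or SimulationParams()
    config = config or PipelineConfig()
    b = _Builder(params, config)
    b.build_genes()
    b.assign_roles()
    b.plant_multi()
    b.plant_single()
    b.plant_clean_decoys()
    expression = b.build_expression()
    truth = TruthTable(
        multi_altered={g: sorted(v) for g, v in b.truth_multi.items()},
        single_altered={g: sorted(v) for g, v in b.truth_single.items()},
        clean=sorted(b.clean_ids),
    )
    cohort = Cohort(
        params=params,
        genes=b.genes,
        segments=sorted(b.segments,
                        key=lambda s: (s.sample_id, s.interval)),
        expression=expression,
        exome=sorted(b.exome, key=lambda v: v.key()),
        transcriptome=sorted(b.transcriptome, key=lambda v: v.key()),
        fusions=sorted(b.fusions,
                       key=lambda f: (f.sample_id, f.gene5, f.gene3)),
        truth=truth,
    )
    if verify:
        b.verify(cohort)
    return cohort


# ---------------------------------------------------------------------------
# disk round-trip


_FILES = {
    "genes": "genes.bed",
    "segments": "segments.tsv",
    "expression": "expression.tsv",
    "exome": "exome_variants.tsv",
    "transcriptome": "transcriptome_variants.tsv",
    "fusions": "fusions.tsv",
    "truth": "truth.json",
}


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the cohort in exactly the dialects the readers accept.

    Re-running with the same seed overwrites with identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_models_bed(cohort.genes, out / _FILES["genes"])
    write_table(cohort.segments, out / _FILES["segments"], CnvSegment)
    write_expression_matrix(cohort.expression, out / _FILES["expression"])
    write_table(cohort.exome, out / _FILES["exome"], VariantCall)
    write_table(cohort.transcriptome, out / _FILES["transcriptome"],
                VariantCall)
    write_table(cohort.fusions, out / _FILES["fusions"], FusionCall)
    (out / _FILES["truth"]).write_text(cohort.truth.to_json() + "\n")


def read_cohort(in_dir: str | Path) -> dict:
    """Load a written cohort back through the standard readers."""
    from .io import (read_expression_matrix, read_fusions, read_gene_models,
                     read_segments, read_variants)
    d = Path(in_dir)
    return {
        "genes": read_gene_models(d / _FILES["genes"], "bed"),
        "segments": read_segments(d / _FILES["segments"]),
        "expression": read_expression_matrix(d / _FILES["expression"]),
        "exome": read_variants(d / _FILES["exome"], "exome"),
        "transcriptome": read_variants(d / _FILES["transcriptome"],
                                       "transcriptome"),
        "fusions": read_fusions(d / _FILES["fusions"]),
        "truth": TruthTable.from_json((d / _FILES["truth"]).read_text()),
    }
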