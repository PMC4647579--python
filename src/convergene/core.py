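"""Shared domain types, coordinate conventions and pipeline configuration.

Coordinate convention
---------------------
All genomic coordinates are **0-based half-open** internally (`[start, end)`,
the BED convention). Formats that print 1-based inclusive coordinates (GTF,
VCF, MAF-like tables) are converted once, at ingest, and never again.
Chromosome names are normalized once at ingest by stripping a leading
``chr``/``Chr`` prefix, so ``chr3`` and ``3`` refer to the same sequence.

Every numeric threshold the pipeline applies lives in :class:`PipelineConfig`;
downstream stages receive the config object and never hard-code a literal.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ConfigError",
    "GenomicInterval",
    "GeneModel",
    "PipelineConfig",
    "AlterationEvent",
    "normalize_chrom",
    "overlaps",
    "load_config",
    "ALTERATION_TYPES",
    "DIRECTIONS",
    "EFFECTS",
    "TRUNCATING_EFFECTS",
    "PREDICTION_CODES",
]

#: Alteration categories a gene-level event may carry.
ALTERATION_TYPES = ("cnv", "expression", "mutation", "fusion")

#: Direction of a dosage-type event; mutations and fusions are undirected.
DIRECTIONS = ("gain", "loss", "neutral", "not_applicable")

#: Variant effect classes recognised by the variant stage.
EFFECTS = ("missense", "nonsense", "frameshift", "inframe", "splice",
           "synonymous", "other")

#: Effects that truncate the protein and bypass the missense-predictor vote.
TRUNCATING_EFFECTS = frozenset({"nonsense", "frameshift", "splice"})

#: Per-tool functional-prediction verdict codes:
#: ``D`` deleterious, ``T`` tolerated, ``.`` missing / not scored.
PREDICTION_CODES = ("D", "T", ".")


class ConfigError(ValueError):
    """Raised for malformed or inconsistent pipeline configuration."""


def normalize_chrom(chrom: str) -> str:
    """Return the chromosome name without a leading ``chr`` prefix.

    >>> normalize_chrom("chr3"), normalize_chrom("3"), normalize_chrom("chrX")
    ('3', '3', 'X')
    """
    c = str(chrom).strip()
    if c[:3].lower() == "chr":
        c = c[3:]
    if not c:
        raise ValueError(f"empty chromosome name: {chrom!r}")
    return c


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative interval start: {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base.

    Intervals on different chromosomes never overlap (returns ``False``,
    never raises). Abutting intervals (``a.end == b.start``) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class GeneModel:
    """A named gene with a genomic footprint; the unit everything aggregates to.

    ``gene_id`` is the authoritative identity and must be unique within a
    gene set; ``symbol`` is a display name and may collide (collisions are
    logged at ingest, never merged).
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")


# Fields whose value may legitimately be zero (everything else numeric in the
# config must be strictly positive).
_NON_NEGATIVE_FIELDS = {"del_max_copies", "min_overlap_fraction"}


@dataclass
class PipelineConfig:
    """Every numeric threshold applied anywhere in the pipeline.

    Parameters
    ----------
    focal_max_length:
        Segment-length cutoff (bases) separating focal from arm-level
        copy-number segments. Segments of this length or longer are
        arm-level and excluded from gene-level analysis.
    expr_noise_floor:
        Noise floor in log10(FPKM+1) units; transcripts below it are
        treated as not expressed.
    high_percentile, low_percentile:
        Strict per-sample percentile cutoffs for calling a gene highly
        (> high) or lowly (< low) expressed among expressed genes.
    min_coverage:
        Minimum read depth for a variant call; calls below it are removed.
    min_deleterious_votes, n_predictors:
        A missense variant needs ``min_deleterious_votes`` "deleterious"
        verdicts out of ``n_predictors`` functional-prediction tools.
    min_fusion_read_pairs:
        Minimum spanning read pairs supporting a fusion candidate.
    min_alteration_types:
        Distinct alteration types (cnv / expression / mutation, optionally
        fusion) a gene must accumulate, within or across samples, to be
        prioritized.
    amp_min_copies, del_max_copies, neutral_copies:
        Integer-copy baselines for calling amplification / deletion on
        focal segments. Hyperploid genomes may need a per-sample baseline;
        all three are configurable for that reason.
    cohort_min_mutation_freq:
        Cohort-mode gene filter: minimum fraction of samples mutated.
    class_dominance_ratio:
        Ratio at which one alteration route (mutation vs dosage) dominates
        the other when assigning the three-class gene typology.
    min_overlap_fraction:
        Minimum fraction of a gene covered by a segment for the gene to be
        assigned to it (0 = any overlap of at least one base).
    count_fusions_in_integration:
        Whether fusion events count toward ``min_alteration_types``.
        Off by default: fusions are exported as evidence and tracks only.
    match_positions_only:
        Cross-validate exome vs transcriptome variants on position only,
        instead of requiring identical ref/alt alleles.
    """

    focal_max_length: int = 10_000_000
    expr_noise_floor: float = 0.1
    high_percentile: float = 60.0
    low_percentile: float = 40.0
    min_coverage: int = 5
    min_deleterious_votes: int = 2
    n_predictors: int = 3
    min_fusion_read_pairs: int = 10
    min_alteration_types: int = 2
    amp_min_copies: float = 3.0
    del_max_copies: float = 1.0
    neutral_copies: float = 2.0
    cohort_min_mutation_freq: float = 0.03
    class_dominance_ratio: float = 3.0
    min_overlap_fraction: float = 0.0
    count_fusions_in_integration: bool = False
    match_positions_only: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                continue
            if not isinstance(v, (int, float)):
                raise ConfigError(f"{f.name} must be numeric, got {v!r}")
            if f.name in _NON_NEGATIVE_FIELDS:
                if v < 0:
                    raise ConfigError(f"{f.name} must be >= 0, got {v}")
            elif v <= 0:
                raise ConfigError(f"{f.name} must be > 0, got {v}")
        if not self.low_percentile < self.high_percentile:
            raise ConfigError(
                f"low_percentile ({self.low_percentile}) must be below "
                f"high_percentile ({self.high_percentile})"
            )
        if not (self.del_max_copies < self.neutral_copies < self.amp_min_copies):
            raise ConfigError(
                "copy-number baselines must satisfy "
                "del_max_copies < neutral_copies < amp_min_copies"
            )
        if self.min_deleterious_votes > self.n_predictors:
            raise ConfigError(
                "min_deleterious_votes cannot exceed n_predictors"
            )
        if self.min_overlap_fraction > 1:
            raise ConfigError("min_overlap_fraction must be <= 1")

    # -- serialization ----------------------------------------------------

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat ``key: value`` YAML document; unset keys take defaults.

        Unknown keys raise :class:`ConfigError` (typo protection).
        """
        raw = Path(path).read_text()
        try:
            data = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config file {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must be a key: value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def hash(self) -> str:
        """Short stable digest of every threshold, stamped into output headers."""
        blob = ";".join(
            f"{f.name}={getattr(self, f.name)!r}"
            for f in dataclasses.fields(self)
        )
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Module-level alias for :meth:`PipelineConfig.load`."""
    return PipelineConfig.load(path)


@dataclass(frozen=True, order=True)
class AlterationEvent:
    """One gene-level alteration observed in one sample.

    Dosage events (``cnv``, ``expression``) carry a ``gain``/``loss``
    direction; ``mutation`` and ``fusion`` events are undirected
    (``not_applicable``). ``evidence`` is a free-text provenance key naming
    the source stage and record.
    """

    gene_id: str
    sample_id: str
    alteration_type: str
    direction: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.alteration_type not in ALTERATION_TYPES:
            raise ValueError(f"bad alteration_type {self.alteration_type!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"bad direction {self.direction!r}")
        if self.alteration_type in ("cnv", "expression"):
            if self.direction not in ("gain", "loss"):
                raise ValueError(
                    f"{self.alteration_type} event needs direction gain/loss, "
                    f"got {self.direction!r}"
                )
        elif self.direction != "not_applicable":
            raise ValueError(
                f"{self.alteration_type} event must be undirected, "
                f"got {self.direction!r}"
            )
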