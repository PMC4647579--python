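"""Readers and writers for every external table the pipeline touches.

Input dialects
--------------
* gene models: BED (0-based half-open, name in column 4, optional strand in
  column 6 and gene_id override in column 7) or GTF (1-based inclusive,
  ``gene`` features with ``gene_id``/``gene_name`` attributes).
* copy-number segments: SEG-style TSV with header
  ``sample_id  chrom  start  end  copy_number  [n_probes]``.
* expression: TSV matrix, first column ``gene_id``, one column per sample,
  cells are FPKM.
* variants: MAF-like TSV (columns below) or a VCF v4.x with the annotation
  carried in INFO keys. VCF/1-based positions are shifted to the internal
  0-based convention at ingest; multi-allelic rows are split into one call
  per alternate allele so the identity key (sample, chrom, pos, ref, alt)
  is always well defined.
* fusions: TSV ``sample_id  gene5  gene3  read_pairs``.

All outputs are TSV with a one-line ``#``-prefixed header naming the package
version and the config hash, deterministic column order, and rows sorted for
reproducible diffs. Readers skip ``#`` comment lines, validate every row and
raise :class:`FormatError` naming the offending line — rows are never
silently dropped.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    EFFECTS,
    PREDICTION_CODES,
    AlterationEvent,
    GeneModel,
    GenomicInterval,
    PipelineConfig,
    normalize_chrom,
)

__all__ = [
    "FormatError",
    "CnvSegment",
    "ExpressionRecord",
    "VariantCall",
    "FusionCall",
    "read_gene_models",
    "read_segments",
    "read_expression_matrix",
    "read_variants",
    "read_fusions",
    "read_events",
    "read_table",
    "write_table",
    "write_gene_models_bed",
    "write_expression_matrix",
    "write_dataframe",
    "load_catalog",
    "apply_catalog",
]

log = logging.getLogger("convergene")


class FormatError(ValueError):
    """Raised for malformed input tables, naming the offending row."""


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class CnvSegment:
    """One copy-number segment from one sample.

    ``copy_number`` is an integer copy count or a copy ratio depending on
    the upstream caller; the classification baselines in
    :class:`~convergene.core.PipelineConfig` are interpreted on the same
    scale.
    """

    sample_id: str
    interval: GenomicInterval
    copy_number: float
    n_probes: Optional[int] = None

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError(
                f"negative copy number {self.copy_number} "
                f"({self.sample_id} {self.interval})"
            )

    @property
    def key(self) -> str:
        i = self.interval
        return f"{self.sample_id}:{i.chrom}:{i.start}-{i.end}"


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene x sample expression measurement in FPKM.

    ``log_expr`` = log10(FPKM + 1) is derived at construction and is the
    scale every downstream threshold uses.
    """

    gene_id: str
    sample_id: str
    fpkm: float
    log_expr: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError(f"negative FPKM for {self.gene_id}/{self.sample_id}")
        expected = float(np.log10(self.fpkm + 1.0))
        if self.log_expr is None:
            object.__setattr__(self, "log_expr", expected)
        elif abs(self.log_expr - expected) > 1e-9:
            raise ValueError(
                f"log_expr {self.log_expr} inconsistent with fpkm {self.fpkm}"
            )


@dataclass(frozen=True)
class VariantCall:
    """A single-nucleotide or indel call with its annotation columns.

    ``predictions`` is the ordered verdict triple from the three
    functional-prediction tools, coded ``D`` (deleterious), ``T``
    (tolerated) or ``.`` (not scored). ``pos`` is internal 0-based.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str = ""
    effect: str = "missense"
    coverage: int = 0
    in_dbsnp: bool = False
    in_cosmic: bool = False
    predictions: tuple = (".", ".", ".")
    platform: str = "exome"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.coverage < 0:
            raise ValueError(f"negative coverage at {self.chrom}:{self.pos}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if len(self.predictions) != 3 or any(
            p not in PREDICTION_CODES for p in self.predictions
        ):
            raise ValueError(f"bad prediction triple {self.predictions!r}")
        if self.platform not in ("exome", "transcriptome"):
            raise ValueError(f"unknown platform {self.platform!r}")

    def key(self, positions_only: bool = False) -> tuple:
        """Cross-platform identity key (sample, chrom, pos[, ref, alt])."""
        if positions_only:
            return (self.sample_id, self.chrom, self.pos)
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FusionCall:
    """A fusion-transcript candidate: 5' and 3' partner plus read support."""

    sample_id: str
    gene5: str
    gene3: str
    read_pairs: int

    def __post_init__(self) -> None:
        if self.read_pairs < 0:
            raise ValueError("read_pairs must be >= 0")

    @property
    def read_through(self) -> bool:
        return self.gene5 == self.gene3

    @property
    def key(self) -> str:
        return f"{self.sample_id}:{self.gene5}--{self.gene3}"


# ---------------------------------------------------------------------------
# generic TSV dialect: one column set per record type

_BOOL_TRUE = {"1", "true", "t", "yes"}
_BOOL_FALSE = {"0", "false", "f", "no", ""}


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "1" if v else "0"
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)  # shortest representation that round-trips exactly
    return str(v)


def _parse_bool(s: str) -> bool:
    t = str(s).strip().lower()
    if t in _BOOL_TRUE:
        return True
    if t in _BOOL_FALSE:
        return False
    raise FormatError(f"cannot parse boolean value {s!r}")


_COLUMNS = {
    CnvSegment: ["sample_id", "chrom", "start", "end", "copy_number", "n_probes"],
    ExpressionRecord: ["gene_id", "sample_id", "fpkm", "log_expr"],
    VariantCall: [
        "sample_id", "chrom", "pos", "ref", "alt", "gene_id", "effect",
        "coverage", "in_dbsnp", "in_cosmic", "pred1", "pred2", "pred3",
        "platform",
    ],
    FusionCall: ["sample_id", "gene5", "gene3", "read_pairs"],
    AlterationEvent: ["gene_id", "sample_id", "alteration_type", "direction",
                      "evidence"],
}


def _sort_key(rec) -> tuple:
    if isinstance(rec, CnvSegment):
        i = rec.interval
        return (rec.sample_id, i.chrom, i.start, i.end, rec.copy_number,
                rec.n_probes if rec.n_probes is not None else -1)
    if isinstance(rec, VariantCall):
        return (rec.sample_id, rec.chrom, rec.pos, rec.ref, rec.alt,
                rec.platform)
    if isinstance(rec, ExpressionRecord):
        return (rec.gene_id, rec.sample_id)
    if isinstance(rec, FusionCall):
        return (rec.sample_id, rec.gene5, rec.gene3, rec.read_pairs)
    if isinstance(rec, AlterationEvent):
        return (rec.gene_id, rec.sample_id, rec.alteration_type,
                rec.direction, rec.evidence)
    raise TypeError(f"no TSV dialect registered for {type(rec).__name__}")


def _to_row(rec) -> list[str]:
    if isinstance(rec, CnvSegment):
        i = rec.interval
        return [_fmt(v) for v in (rec.sample_id, i.chrom, i.start, i.end,
                                  rec.copy_number, rec.n_probes)]
    if isinstance(rec, ExpressionRecord):
        return [_fmt(v) for v in (rec.gene_id, rec.sample_id, rec.fpkm,
                                  rec.log_expr)]
    if isinstance(rec, VariantCall):
        return [_fmt(v) for v in (rec.sample_id, rec.chrom, rec.pos, rec.ref,
                                  rec.alt, rec.gene_id, rec.effect,
                                  rec.coverage, rec.in_dbsnp, rec.in_cosmic,
                                  *rec.predictions, rec.platform)]
    if isinstance(rec, FusionCall):
        return [_fmt(v) for v in (rec.sample_id, rec.gene5, rec.gene3,
                                  rec.read_pairs)]
    if isinstance(rec, AlterationEvent):
        return [_fmt(v) for v in (rec.gene_id, rec.sample_id,
                                  rec.alteration_type, rec.direction,
                                  rec.evidence)]
    raise TypeError(f"no TSV dialect registered for {type(rec).__name__}")


def _from_row(record_type, row: dict):
    try:
        if record_type is CnvSegment:
            n_probes = row.get("n_probes", "")
            return CnvSegment(
                sample_id=row["sample_id"],
                interval=GenomicInterval(
                    normalize_chrom(row["chrom"]),
                    int(row["start"]), int(row["end"]),
                ),
                copy_number=float(row["copy_number"]),
                n_probes=int(n_probes) if str(n_probes).strip() not in ("", "nan")
                else None,
            )
        if record_type is ExpressionRecord:
            return ExpressionRecord(
                gene_id=row["gene_id"], sample_id=row["sample_id"],
                fpkm=float(row["fpkm"]),
            )
        if record_type is VariantCall:
            return VariantCall(
                sample_id=row["sample_id"],
                chrom=normalize_chrom(row["chrom"]),
                pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                gene_id=row.get("gene_id", "") or "",
                effect=row["effect"],
                coverage=int(row["coverage"]),
                in_dbsnp=_parse_bool(row["in_dbsnp"]),
                in_cosmic=_parse_bool(row["in_cosmic"]),
                predictions=(row["pred1"], row["pred2"], row["pred3"]),
                platform=row["platform"],
            )
        if record_type is FusionCall:
            return FusionCall(
                sample_id=row["sample_id"], gene5=row["gene5"],
                gene3=row["gene3"], read_pairs=int(row["read_pairs"]),
            )
        if record_type is AlterationEvent:
            return AlterationEvent(
                gene_id=row["gene_id"], sample_id=row["sample_id"],
                alteration_type=row["alteration_type"],
                direction=row["direction"],
                evidence=row.get("evidence", "") or "",
            )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"bad row {row!r}: {exc}") from exc
    raise TypeError(f"no TSV dialect registered for {record_type.__name__}")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return df


def read_table(path: str | Path, record_type) -> list:
    """Read a TSV written by :func:`write_table` back into records."""
    required = [c for c in _COLUMNS[record_type] if c != "n_probes"]
    df = _read_tsv(path, required)
    out = []
    for idx, row in enumerate(df.to_dict("records"), start=2):
        try:
            out.append(_from_row(record_type, row))
        except FormatError as exc:
            raise FormatError(f"{path} line {idx}: {exc}") from exc
    return out


def write_table(records: Iterable, path: str | Path, record_type=None,
                config: Optional[PipelineConfig] = None) -> None:
    """Write records of one type to TSV, sorted, with a provenance header.

    ``record_type`` is only needed for an empty record list (to emit the
    header). Output is byte-deterministic for equal input.
    """
    records = list(records)
    if records:
        record_type = type(records[0])
        if any(type(r) is not record_type for r in records):
            raise TypeError("write_table requires records of a single type")
    elif record_type is None:
        raise TypeError("record_type required for an empty record list")
    columns = _COLUMNS[record_type]
    # sort on raw values (numeric-aware), then format
    rows = [_to_row(r) for r in sorted(records, key=_sort_key)]
    _write_rows(path, columns, rows, config)


def _header_line(config: Optional[PipelineConfig]) -> str:
    h = config.hash() if config is not None else "none"
    return f"# convergene={__version__} config_hash={h}"


def _write_rows(path, columns, rows, config) -> None:
    lines = [_header_line(config), "\t".join(columns)]
    lines += ["\t".join(r) for r in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataframe(df: pd.DataFrame, path: str | Path,
                    config: Optional[PipelineConfig] = None,
                    index: bool = False) -> None:
    """Write a DataFrame as TSV with the standard provenance header."""
    body = df.to_csv(sep="\t", index=index, float_format="%.10g",
                     lineterminator="\n")
    Path(path).write_text(_header_line(config) + "\n" + body)


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, format: str = "bed") -> list[GeneModel]:
    """Read gene models from BED or GTF into the internal convention.

    BED columns: chrom, start, end, name[, score, strand[, gene_id]].
    When no explicit gene_id column is present the name doubles as the id.
    GTF ``gene`` features use the ``gene_id`` attribute (``gene_name`` as
    symbol when present); 1-based inclusive coordinates become
    ``[start-1, end)``.
    """
    if format not in ("bed", "gtf"):
        raise ValueError(f"unknown gene model format {format!r}")
    models: list[GeneModel] = []
    seen_ids: set[str] = set()
    seen_symbols: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if format == "bed":
            model = _parse_bed_gene(line, lineno, path)
        else:
            model = _parse_gtf_gene(line, lineno, path)
        if model is None:
            continue
        if model.gene_id in seen_ids:
            raise FormatError(
                f"{path} line {lineno}: duplicate gene_id {model.gene_id!r}"
            )
        if model.symbol in seen_symbols:
            log.warning("duplicate gene symbol %r (gene_id %s, %s line %d); "
                        "kept as a distinct gene", model.symbol, model.gene_id,
                        path, lineno)
        seen_ids.add(model.gene_id)
        seen_symbols.add(model.symbol)
        models.append(model)
    if not models:
        raise FormatError(f"{path}: no gene models found")
    return models


def _parse_bed_gene(line: str, lineno: int, path) -> GeneModel:
    parts = line.split()
    if len(parts) < 4:
        raise FormatError(f"{path} line {lineno}: BED needs >= 4 columns")
    try:
        chrom = normalize_chrom(parts[0])
        start, end = int(parts[1]), int(parts[2])
        interval = GenomicInterval(chrom, start, end)
    except ValueError as exc:
        raise FormatError(f"{path} line {lineno}: {exc}") from exc
    symbol = parts[3]
    strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "unknown"
    gene_id = parts[6] if len(parts) > 6 else symbol
    return GeneModel(gene_id=gene_id, symbol=symbol, interval=interval,
                     strand=strand)


def _parse_gtf_gene(line: str, lineno: int, path) -> Optional[GeneModel]:
    parts = line.split("\t")
    if len(parts) < 9:
        raise FormatError(f"{path} line {lineno}: GTF needs 9 columns")
    if parts[2] != "gene":
        return None
    attrs = {}
    for chunk in parts[8].strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    if "gene_id" not in attrs:
        raise FormatError(f"{path} line {lineno}: gene feature lacks gene_id")
    try:
        interval = GenomicInterval(
            normalize_chrom(parts[0]), int(parts[3]) - 1, int(parts[4])
        )
    except ValueError as exc:
        raise FormatError(f"{path} line {lineno}: {exc}") from exc
    strand = parts[6] if parts[6] in ("+", "-") else "unknown"
    return GeneModel(
        gene_id=attrs["gene_id"],
        symbol=attrs.get("gene_name", attrs["gene_id"]),
        interval=interval,
        strand=strand,
    )


def write_gene_models_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as 7-column BED (name, score 0, strand, gene_id)."""
    rows = sorted(
        (m.interval.chrom, m.interval.start, m.interval.end, m.symbol, 0,
         m.strand if m.strand != "unknown" else ".", m.gene_id)
        for m in models
    )
    Path(path).write_text(
        "\n".join("\t".join(_fmt(v) for v in r) for r in rows) + "\n"
    )


# ---------------------------------------------------------------------------
# segments


def read_segments(path: str | Path) -> list[CnvSegment]:
    """Read a SEG-style TSV of per-sample copy-number segments.

    Overlapping segments within one sample are kept but logged as warnings
    (the cnv stage resolves multi-segment genes deterministically).
    """
    df = _read_tsv(path, ["sample_id", "chrom", "start", "end", "copy_number"])
    segments = []
    for idx, row in enumerate(df.to_dict("records"), start=2):
        try:
            segments.append(_from_row(CnvSegment, row))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path} line {idx}: {exc}") from exc
    _warn_self_overlaps(segments, path)
    return segments


def _warn_self_overlaps(segments: list[CnvSegment], path) -> None:
    by_key: dict[tuple, list[CnvSegment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.interval.chrom), []).append(s)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: (s.interval.start, s.interval.end))
        for a, b in zip(segs, segs[1:]):
            if b.interval.start < a.interval.end:
                log.warning(
                    "%s: overlapping segments for sample %s on chrom %s: "
                    "%s and %s (both kept)", path, sample, chrom, a.key, b.key,
                )


# ---------------------------------------------------------------------------
# expression


def read_expression_matrix(path: str | Path) -> list[ExpressionRecord]:
    """Read a gene x sample FPKM matrix into long-form expression records."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     float_precision="round_trip")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicated gene row(s): {dupes[:5]}")
    if df.shape[1] == 0:
        raise FormatError(f"{path}: expression matrix has no sample columns")
    records = []
    for gene_id, row in df.iterrows():
        for sample_id, fpkm in row.items():
            fv = pd.to_numeric(fpkm, errors="coerce")
            if pd.isna(fv):
                raise FormatError(
                    f"{path}: non-numeric FPKM {fpkm!r} for gene {gene_id} "
                    f"sample {sample_id}"
                )
            records.append(ExpressionRecord(gene_id=str(gene_id),
                                            sample_id=str(sample_id),
                                            fpkm=float(fv)))
    return records


def write_expression_matrix(records: Iterable[ExpressionRecord],
                            path: str | Path) -> None:
    """Write long-form expression records back to the gene x sample dialect."""
    records = list(records)
    genes = sorted({r.gene_id for r in records})
    samples = sorted({r.sample_id for r in records})
    table = {(r.gene_id, r.sample_id): r.fpkm for r in records}
    lines = ["gene_id\t" + "\t".join(samples)]
    for g in genes:
        lines.append(
            g + "\t" + "\t".join(_fmt(table[(g, s)]) for s in samples)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# variants


_VARIANT_REQUIRED = ["sample_id", "chrom", "pos", "ref", "alt", "effect",
                     "coverage", "in_dbsnp", "in_cosmic",
                     "pred1", "pred2", "pred3"]


def read_variants(path: str | Path, platform: str) -> list[VariantCall]:
    """Read variant calls from a MAF-like TSV or a VCF, stamping ``platform``.

    The TSV dialect carries internal 0-based positions (it round-trips with
    :func:`write_table`); VCF positions are 1-based and shifted at ingest.
    """
    if platform not in ("exome", "transcriptome"):
        raise ValueError(f"unknown platform {platform!r}")
    p = Path(path)
    if p.suffix.lower() in (".vcf", ".gz") or p.name.lower().endswith(".vcf.gz"):
        return _read_variants_vcf(p, platform)
    df = _read_tsv(p, _VARIANT_REQUIRED)
    calls = []
    for idx, row in enumerate(df.to_dict("records"), start=2):
        row = dict(row)
        row["platform"] = platform
        try:
            calls.append(_from_row(VariantCall, row))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path} line {idx}: {exc}") from exc
    return calls


def _read_variants_vcf(path: Path, platform: str) -> list[VariantCall]:
    """VCF ingest: annotation in INFO keys GENE, EFFECT, DP, DBSNP, COSMIC,
    PRED (pipe-joined D/T/. triple); sample id from the single sample column
    or INFO key SAMPLE. Multi-allelic records split per alternate allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    default_sample = vcf.samples[0] if vcf.samples else None
    calls = []
    for v in vcf:
        sample_id = v.INFO.get("SAMPLE") or default_sample
        if sample_id is None:
            raise FormatError(
                f"{path}: no sample column and no INFO/SAMPLE at "
                f"{v.CHROM}:{v.POS}"
            )
        pred = str(v.INFO.get("PRED", ".|.|.")).split("|")
        if len(pred) != 3:
            raise FormatError(f"{path}: bad PRED triple at {v.CHROM}:{v.POS}")
        for alt in v.ALT:
            calls.append(VariantCall(
                sample_id=str(sample_id),
                chrom=normalize_chrom(v.CHROM),
                pos=v.POS - 1,
                ref=v.REF,
                alt=alt,
                gene_id=str(v.INFO.get("GENE", "") or ""),
                effect=str(v.INFO.get("EFFECT", "other")),
                coverage=int(v.INFO.get("DP", 0)),
                in_dbsnp=bool(int(v.INFO.get("DBSNP", 0))),
                in_cosmic=bool(int(v.INFO.get("COSMIC", 0))),
                predictions=tuple(pred),
                platform=platform,
            ))
    return calls


# ---------------------------------------------------------------------------
# fusions / events


def read_fusions(path: str | Path) -> list[FusionCall]:
    return read_table(path, FusionCall)


def read_events(path: str | Path) -> list[AlterationEvent]:
    """Read a generic alteration-event table (gene, sample, type, direction).

    This is the cohort-mode entry point: pre-made MAF/CNV/expression events
    from any cohort can be summarised without the upstream stages.
    """
    return read_table(path, AlterationEvent)


# ---------------------------------------------------------------------------
# catalog helper


def load_catalog(path: str | Path) -> set[tuple]:
    """Load a positions+alleles catalog (TSV: chrom, pos, ref, alt).

    Used to set dbSNP / COSMIC membership flags on synthetic or un-annotated
    variant tables; live database lookups are out of scope.
    """
    df = _read_tsv(path, ["chrom", "pos", "ref", "alt"])
    return {
        (normalize_chrom(r["chrom"]), int(r["pos"]), r["ref"], r["alt"])
        for r in df.to_dict("records")
    }


def apply_catalog(variants: Iterable[VariantCall],
                  dbsnp: Optional[set] = None,
                  cosmic: Optional[set] = None) -> list[VariantCall]:
    """Return variants with catalog membership flags set from position sets."""
    out = []
    for v in variants:
        site = (v.chrom, v.pos, v.ref, v.alt)
        out.append(dataclasses.replace(
            v,
            in_dbsnp=site in dbsnp if dbsnp is not None else v.in_dbsnp,
            in_cosmic=site in cosmic if cosmic is not None else v.in_cosmic,
        ))
    return out
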