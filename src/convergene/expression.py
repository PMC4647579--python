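"""Expression stage: noise-floor filtering and percentile classification.

Transcripts below the noise floor (log10(FPKM+1) < 0.1 by default) are
called ``not_expressed``. Among the remaining expressed genes of each
sample, an empirical percentile rank is assigned as

    percentile = 100 * (rank - 1) / (n - 1)

with ties taking the mean percentile of their rank span and a single
expressed gene sitting at 50. Status is ``high`` strictly above the high
cutoff (60 by default), ``low`` strictly below the low cutoff (40), and
``intermediate`` otherwise. The classification uses ranks only, so it is
invariant under any strictly monotone transform of the expression values,
and it is computed per sample — each transcriptome is binned against
itself, as appropriate for cell lines without paired normals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from scipy.stats import rankdata

from .core import PipelineConfig
from .io import ExpressionRecord

__all__ = ["ExpressionCall", "classify_expression", "detectable"]

STATUSES = ("not_expressed", "low", "intermediate", "high")


@dataclass(frozen=True)
class ExpressionCall:
    """Expression status of one gene in one sample.

    ``percentile`` is the rank percentile among the sample's expressed
    genes; it is NaN for ``not_expressed`` records, which never enter the
    ranking.
    """

    gene_id: str
    sample_id: str
    status: str
    log_expr: float
    percentile: float

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"bad expression status {self.status!r}")


def classify_expression(records: Iterable[ExpressionRecord],
                        config: PipelineConfig) -> list[ExpressionCall]:
    """Classify every (gene, sample) cell; errors on a sample with no
    expressed gene (its percentiles would be undefined)."""
    by_sample: dict[str, list[ExpressionRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)

    calls: list[ExpressionCall] = []
    for sample_id in sorted(by_sample):
        recs = by_sample[sample_id]
        expressed = [r for r in recs if r.log_expr >= config.expr_noise_floor]
        if not expressed:
            raise ValueError(
                f"sample {sample_id!r} has no expressed genes above the "
                f"noise floor {config.expr_noise_floor}"
            )
        for r in recs:
            if r.log_expr < config.expr_noise_floor:
                calls.append(ExpressionCall(r.gene_id, sample_id,
                                            "not_expressed", r.log_expr,
                                            math.nan))
        n = len(expressed)
        if n == 1:
            pct = [50.0]
        else:
            ranks = rankdata([r.log_expr for r in expressed], method="average")
            pct = [100.0 * (rk - 1.0) / (n - 1.0) for rk in ranks]
        for r, p in zip(expressed, pct):
            if p > config.high_percentile:
                status = "high"
            elif p < config.low_percentile:
                status = "low"
            else:
                status = "intermediate"
            calls.append(ExpressionCall(r.gene_id, sample_id, status,
                                        r.log_expr, p))
    calls.sort(key=lambda c: (c.gene_id, c.sample_id))
    return calls


def detectable(gene_id: str, sample_id: str,
               calls: Iterable[ExpressionCall]) -> bool:
    """True iff the gene's transcript is above the noise floor in the sample.

    A gene/sample pair absent from the call set is undetectable.
    """
    for c in calls:
        if c.gene_id == gene_id and c.sample_id == sample_id:
            return c.status != "not_expressed"
    return False


def detectable_index(calls: Iterable[ExpressionCall]) -> set[tuple[str, str]]:
    """Set of (gene, sample) pairs with a detectable transcript (fast path)."""
    return {(c.gene_id, c.sample_id) for c in calls
            if c.status != "not_expressed"}
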