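"""Expression cutoffs defining the "expressed gene" set.

A large excess of zero / sub-1-FPKM genes — enriched on the X chromosome
— drags the median X expression down and produces the artifactual
X:A ~ 0.5.  The cutoff removes those no-/low-expression genes before the
ratio is estimated.  Default thresholds: 1.0 FPKM for bulk samples,
0.1 FPKM for single cells, both with an "at least" comparator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenePartition

__all__ = [
    "FilterConfig",
    "FilterReportRow",
    "BULK_DEFAULT",
    "SINGLE_CELL_DEFAULT",
    "apply_cutoff",
    "filter_report",
    "zero_fraction_by_group",
]


@dataclass(frozen=True)
class FilterConfig:
    """Expression filter: keep genes whose FPKM passes ``cutoff``.

    comparator
        ``at_least`` keeps FPKM >= cutoff; ``greater_than`` keeps
        FPKM > cutoff (so cutoff 0 / greater_than keeps exactly the
        genes with any expression).
    scope
        ``per_sample``: each sample defines its own expressed-gene set
        (the per-cell analysis).  ``pooled``: the gene's mean FPKM
        across all samples is compared to the cutoff instead.
    """

    cutoff: float = 1.0
    comparator: str = "at_least"
    scope: str = "per_sample"

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.comparator not in ("at_least", "greater_than"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.scope not in ("per_sample", "pooled"):
            raise ValueError(f"unknown scope {self.scope!r}")

    def passes(self, values: pd.Series) -> pd.Series:
        if self.comparator == "at_least":
            return values >= self.cutoff
        return values > self.cutoff


BULK_DEFAULT = FilterConfig(cutoff=1.0)
SINGLE_CELL_DEFAULT = FilterConfig(cutoff=0.1)


@dataclass(frozen=True)
class FilterReportRow:
    sample_id: str
    cutoff: float
    comparator: str
    n_input: int
    n_retained: int
    retained_fraction_of_expressed: float  # retained / genes with FPKM > 0


def apply_cutoff(
    matrix: ExpressionMatrix, sample: str, cfg: FilterConfig
) -> tuple[set[str], FilterReportRow]:
    """Retained gene set for one sample plus its report row.

    An empty retained set is legal; downstream estimators guard on group
    size.
    """
    values = matrix.sample(sample)
    basis = matrix.values.mean(axis=1) if cfg.scope == "pooled" else values
    mask = cfg.passes(basis)
    retained = set(basis.index[mask])
    n_expressed = int((values > 0).sum())
    frac = len(retained & set(values.index[values > 0])) / n_expressed if n_expressed else 0.0
    row = FilterReportRow(
        sample_id=sample,
        cutoff=cfg.cutoff,
        comparator=cfg.comparator,
        n_input=matrix.n_genes,
        n_retained=len(retained),
        retained_fraction_of_expressed=frac,
    )
    return retained, row


def filter_report(matrix: ExpressionMatrix, cfg: FilterConfig) -> pd.DataFrame:
    """Report rows for every sample, as a DataFrame."""
    rows = [apply_cutoff(matrix, s, cfg)[1] for s in matrix.sample_ids]
    return pd.DataFrame([r.__dict__ for r in rows])


def zero_fraction_by_group(
    matrix: ExpressionMatrix, partition: GenePartition, sample: str
) -> tuple[float, float]:
    """(fraction of X genes with FPKM = 0, same for autosomal genes)."""
    values = matrix.sample(sample)
    x = values.loc[values.index.isin(partition.x_genes)]
    a = values.loc[values.index.isin(partition.a_genes)]
    if len(x) == 0 or len(a) == 0:
        raise ValueError("partition empty on one side for this matrix")
    return float(np.mean(x == 0)), float(np.mean(a == 0))
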