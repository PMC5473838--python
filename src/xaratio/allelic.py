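"""Allele-specific expression: maternal/paternal split and X:AA ratios.

The assignment follows three steps: total gene expression (FPKM) is
taken as given; the maternal fraction of each gene in each cell is
estimated from strain-informative SNP read counts as
``f = maternal_reads / (maternal_reads + paternal_reads)``; the total
FPKM is then apportioned to the two alleles by that fraction, so
maternal + paternal equals the total exactly.

Allele-resolved dosage is summarized as Xm:AA and Xp:AA — one allele's
X-gene median over the *total* (both-allele) autosomal median.  With
both X alleles active and balanced each allele contributes ~0.5; as the
paternal X silences, Xp:AA falls and, under compensation, Xm:AA rises
toward the male configuration (Xm:AA ~ 1, Xp:AA = 0).

Expression filtering here is applied to the total gene FPKM, never the
allele-specific FPKM: a silenced allele of an expressed gene is a
genuine zero in the numerator, not noise to be gated out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import (
    BootstrapConfig,
    GroupSizeError,
    XARatioEstimate,
    bootstrap_xa_ratio,
    child_seed,
)
from .filtering import FilterConfig, apply_cutoff
from .io import AlleleCountTable, ExpressionMatrix, GeneAnnotation, GenePartition

__all__ = [
    "AllelicFractionTable",
    "AllelicExpressionMatrix",
    "StageSummary",
    "estimate_allelic_fractions",
    "split_expression",
    "allelic_xaa_ratio",
    "stage_timecourse",
    "snp_coverage_by_chromosome",
    "timecourse_frame",
]

RATIO_TYPES = ("XA_total", "Xm_AA", "Xp_AA", "X_fpkm_sum")


@dataclass
class AllelicFractionTable:
    """Per (gene, sample) maternal fraction where read support suffices.

    ``fractions`` holds ``maternal_fraction`` (NaN when informative
    reads fall below the threshold) and ``informative_reads`` (m + p).
    """

    fractions: pd.DataFrame
    min_informative_reads: int

    def fraction(self, gene: str, sample: str) -> float:
        try:
            return float(self.fractions.loc[(gene, sample), "maternal_fraction"])
        except KeyError:
            return float("nan")


@dataclass
class AllelicExpressionMatrix:
    """Maternal / paternal FPKM per gene per cell; NaN where undefined.

    Wherever both are defined, maternal + paternal equals the total
    FPKM exactly (paternal is computed as total - maternal).
    """

    maternal: pd.DataFrame
    paternal: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.maternal.index.equals(self.paternal.index) or not self.maternal.columns.equals(
            self.paternal.columns
        ):
            raise ValueError("maternal and paternal matrices must be aligned")


@dataclass
class StageSummary:
    """Per-stage, per-sex aggregate of the per-cell ratio estimates."""

    stage: str
    sex: str
    n_cells: int
    per_cell: pd.DataFrame  # cell_id x ratio columns
    means: dict[str, float]  # ratio_type -> arithmetic mean of defined cells


def estimate_allelic_fractions(
    counts: AlleleCountTable, min_informative_reads: int = 3
) -> AllelicFractionTable:
    """Maternal fraction f = m / (m + p) per (gene, cell).

    f is defined only where m + p >= ``min_informative_reads``; below
    that the allelic call is too noisy and the gene-cell is left
    undefined (NaN).
    """
    if min_informative_reads < 1:
        raise ValueError("min_informative_reads must be >= 1")
    c = counts.counts
    total = c["maternal_reads"] + c["paternal_reads"]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = c["maternal_reads"] / total
    f = f.where(total >= min_informative_reads)
    out = pd.DataFrame({"maternal_fraction": f, "informative_reads": total})
    return AllelicFractionTable(out, min_informative_reads)


def split_expression(
    matrix: ExpressionMatrix, fractions: AllelicFractionTable
) -> AllelicExpressionMatrix:
    """Apportion total FPKM to the alleles by the maternal fraction.

    Genes (or gene-cell pairs) without a defined fraction are NaN in
    both allele matrices; a zero total splits to (0, 0) whenever the
    fraction is defined.
    """
    f_long = fractions.fractions["maternal_fraction"].dropna()
    f = f_long.unstack(level="sample_id") if len(f_long) else pd.DataFrame()
    f = f.reindex(index=matrix.values.index, columns=matrix.values.columns)
    total = matrix.values
    t = total.to_numpy()
    maternal = np.clip((total * f).to_numpy(), 0.0, t)
    paternal = t - maternal
    # enforce bitwise maternal + paternal == total: a single rounding of
    # t - m can leave the sum off by an ulp, so re-derive each part from
    # the other until the identity holds (converges in 1-2 passes)
    for _ in range(5):
        bad = ~np.isnan(maternal) & (maternal + paternal != t)
        if not bad.any():
            break
        maternal[bad] = t[bad] - paternal[bad]
        still = ~np.isnan(maternal) & (maternal + paternal != t)
        paternal[still] = t[still] - maternal[still]
    else:  # pragma: no cover - never observed
        raise FloatingPointError("allelic split failed to conserve totals exactly")
    return AllelicExpressionMatrix(
        pd.DataFrame(maternal, index=total.index, columns=total.columns),
        pd.DataFrame(paternal, index=total.index, columns=total.columns),
    )


def allelic_xaa_ratio(
    allelic: AllelicExpressionMatrix,
    matrix: ExpressionMatrix,
    partition: GenePartition,
    sample: str,
    allele: str,
    filter_cfg: FilterConfig,
    boot_cfg: BootstrapConfig | None = None,
) -> XARatioEstimate:
    """Bootstrap Xm:AA or Xp:AA for one cell.

    Numerator: the chosen allele's FPKM over the SNP-informative X
    genes that pass the (total-FPKM) expression filter.  Denominator:
    total both-allele FPKM of the filtered autosomal genes.
    """
    if allele not in ("maternal", "paternal"):
        raise ValueError("allele must be 'maternal' or 'paternal'")
    boot_cfg = boot_cfg or BootstrapConfig()
    retained, _ = apply_cutoff(matrix, sample, filter_cfg)
    allele_values = (allelic.maternal if allele == "maternal" else allelic.paternal)[sample]
    x_defined = allele_values.dropna()
    x = x_defined.loc[x_defined.index.isin(partition.x_genes & retained)]
    totals = matrix.sample(sample)
    a = totals.loc[totals.index.isin(partition.a_genes & retained)]
    if len(x) < boot_cfg.min_group_size:
        raise GroupSizeError(
            f"sample {sample!r}: only {len(x)} SNP-informative X genes after filtering "
            f"(need {boot_cfg.min_group_size})"
        )
    est = bootstrap_xa_ratio(x, a, boot_cfg, allow_zeros=True)
    est.cutoff = filter_cfg.cutoff
    est.sample_id = sample
    return est


def _xa_total_for_sample(matrix, partition, sample, filter_cfg, boot_cfg):
    from .bootstrap import xa_ratio_for_sample

    return xa_ratio_for_sample(matrix, partition, sample, filter_cfg, boot_cfg)


def stage_timecourse(
    matrix: ExpressionMatrix,
    allelic: AllelicExpressionMatrix,
    partition: GenePartition,
    filter_cfg: FilterConfig,
    boot_cfg: BootstrapConfig | None = None,
) -> list[StageSummary]:
    """Per-cell X:A, Xm:AA, Xp:AA and X FPKM sums grouped by stage and sex.

    Cells must carry ``stage`` and ``sex`` labels in
    ``matrix.sample_meta``.  Each cell is estimated on its own
    (per-cell expressed-gene set, per-cell bootstrap with a
    deterministic child seed); the stage value is the arithmetic mean
    of the defined per-cell points.  A cell whose gene groups collapse
    is recorded with NaN, a stage with zero usable cells yields NaN
    means rather than an error.
    """
    if matrix.sample_meta is None or not {"stage", "sex"} <= set(matrix.sample_meta.columns):
        raise ValueError("matrix.sample_meta must provide 'stage' and 'sex' per cell")
    boot_cfg = boot_cfg or BootstrapConfig()
    meta = matrix.sample_meta
    summaries: list[StageSummary] = []
    stage_order = meta["stage"].drop_duplicates().tolist()
    for stage in stage_order:
        for sex in meta.loc[meta["stage"] == stage, "sex"].drop_duplicates():
            cells = meta.index[(meta["stage"] == stage) & (meta["sex"] == sex)]
            rows = {}
            for cell in cells:
                seed = child_seed(boot_cfg.seed, matrix.sample_ids.index(cell))
                cfg = BootstrapConfig(
                    n_sample=boot_cfg.n_sample,
                    n_boot=boot_cfg.n_boot,
                    seed=seed,
                    min_group_size=boot_cfg.min_group_size,
                    ci_level=boot_cfg.ci_level,
                )
                row: dict[str, float] = {}
                try:
                    est = _xa_total_for_sample(matrix, partition, cell, filter_cfg, cfg)
                    row["XA_total"] = est.point
                    row["XA_total_ci_low"] = est.ci_low
                    row["XA_total_ci_high"] = est.ci_high
                except (GroupSizeError, ValueError):
                    row["XA_total"] = np.nan
                for allele, name in (("maternal", "Xm_AA"), ("paternal", "Xp_AA")):
                    try:
                        est = allelic_xaa_ratio(
                            allelic, matrix, partition, cell, allele, filter_cfg, cfg
                        )
                        row[name] = est.point
                        row[f"{name}_ci_low"] = est.ci_low
                        row[f"{name}_ci_high"] = est.ci_high
                    except (GroupSizeError, ValueError):
                        row[name] = np.nan
                values = matrix.sample(cell)
                row["X_fpkm_sum"] = float(
                    values.loc[values.index.isin(partition.x_genes)].sum()
                )
                rows[cell] = row
            per_cell = pd.DataFrame.from_dict(rows, orient="index")
            means = {
                rt: float(per_cell[rt].mean()) if rt in per_cell and per_cell[rt].notna().any() else float("nan")
                for rt in RATIO_TYPES
            }
            summaries.append(
                StageSummary(stage=stage, sex=sex, n_cells=len(cells), per_cell=per_cell, means=means)
            )
    return summaries


def timecourse_frame(summaries: list[StageSummary]) -> pd.DataFrame:
    """Long-format table of a time-course: one row per (cell, ratio_type),
    plus one ``stage_mean`` row per (stage, sex, ratio_type)."""
    rows = []
    for s in summaries:
        for cell, row in s.per_cell.iterrows():
            for rt in RATIO_TYPES:
                if rt not in row:
                    continue
                rows.append(
                    {
                        "stage": s.stage,
                        "sex": s.sex,
                        "cell_id": cell,
                        "ratio_type": rt,
                        "point": row.get(rt, np.nan),
                        "ci_low": row.get(f"{rt}_ci_low", np.nan),
                        "ci_high": row.get(f"{rt}_ci_high", np.nan),
                    }
                )
        for rt, mean in s.means.items():
            rows.append(
                {
                    "stage": s.stage,
                    "sex": s.sex,
                    "cell_id": "stage_mean",
                    "ratio_type": rt,
                    "point": mean,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
    return pd.DataFrame(rows)


def snp_coverage_by_chromosome(
    counts: AlleleCountTable,
    matrix: ExpressionMatrix,
    ann: GeneAnnotation,
    cutoffs: list[float] | None = None,
    comparator: str = "at_least",
) -> pd.DataFrame:
    """Fraction of expressed genes with >= 1 informative SNP read.

    Reported per chromosome and overall, for each expression cutoff in
    ``cutoffs`` (a gene counts as expressed at a level if it passes the
    cutoff in at least one sample).  A uniform fraction across
    chromosomes and cutoff levels is the QC expectation: informative
    SNPs should not be depleted on the X or among lowly expressed
    genes.
    """
    cutoffs = cutoffs if cutoffs is not None else [0.0]
    gene_reads = counts.counts.sum(axis=1).groupby(level="gene_id").sum()
    informative = set(gene_reads.index[gene_reads >= 1])
    rows = []
    for cutoff in cutoffs:
        cfg = FilterConfig(cutoff=cutoff, comparator=comparator)
        passing = cfg.passes(matrix.values).any(axis=1)
        expressed = [g for g in matrix.gene_ids if passing[g]]
        by_chrom: dict[str, list[str]] = {}
        for g in expressed:
            chrom = ann.get(g)
            if chrom is None:
                continue
            by_chrom.setdefault(chrom, []).append(g)
        for chrom, genes in sorted(by_chrom.items()):
            n_inf = sum(g in informative for g in genes)
            rows.append(
                {
                    "cutoff": cutoff,
                    "chromosome": chrom,
                    "n_expressed": len(genes),
                    "n_informative": n_inf,
                    "fraction_informative": n_inf / len(genes) if genes else np.nan,
                }
            )
        all_genes = [g for genes in by_chrom.values() for g in genes]
        n_inf = sum(g in informative for g in all_genes)
        rows.append(
            {
                "cutoff": cutoff,
                "chromosome": "overall",
                "n_expressed": len(all_genes),
                "n_informative": n_inf,
                "fraction_informative": n_inf / len(all_genes) if all_genes else np.nan,
            }
        )
    return pd.DataFrame(rows)
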