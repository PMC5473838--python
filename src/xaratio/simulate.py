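"""Synthetic expression and allelic-count data with known ground truth.

The generator emulates the statistical structure the X:A analysis
assumes:

* per-gene expression levels are log-normal on the FPKM scale;
* each expressed autosomal gene transcribes two alleles that share one
  gene-level draw (alleles of a gene share their regulatory state), so
  the total is twice the per-allele output;
* the X chromosome emits a buffered total of ``u`` autosomal-allele
  units per cell, shared across its active alleles (``u = 2`` encodes
  full Ohno upregulation: one upregulated X matches two autosomal
  copies);
* a fraction of genes — larger on the X — are silent and emit only
  zero / sub-1-FPKM noise (uniform below ``noise_max_fpkm``, with a
  point mass at exactly zero);
* imprinted X inactivation is a stage schedule: the paternal X output
  falls with the silencing fraction ``s`` while, under full
  compensation, the maternal X rises to keep the per-gene total
  constant;
* SNP-overlapping reads are Poisson in the total FPKM and split
  binomially between the alleles.

Every dataset carries its generative truth, and :func:`expected_ratios`
returns the analytic medians the pipeline should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import (
    AlleleCountTable,
    ExpressionMatrix,
    GeneAnnotation,
)

__all__ = [
    "SimulationParams",
    "StageSpec",
    "StageSchedule",
    "SimulatedDataset",
    "ExpectedRatios",
    "simulate_expression",
    "simulate_timecourse",
    "expected_ratios",
    "expected_all_genes_xa",
    "preimplantation_schedule",
]

N_AUTOSOMES = 19  # mouse karyotype; autosomal genes are spread round-robin


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters of the synthetic transcriptome.

    expr_meanlog, expr_sdlog
        natural-log parameters of the per-allele autosomal FPKM
        distribution (log-normal).
    upregulation_factor
        total X output per cell in autosomal-allele units, shared
        across active X alleles; 2.0 is full Ohno upregulation.
    active_x_count
        active X alleles in a (non-time-course) female cell.
    x_noise_fraction, a_noise_fraction
        fraction of X / autosomal genes that are silent and emit only
        low-FPKM noise; the X excess reproduces the observed pile-up of
        no-/low-expression genes on the X.
    noise_max_fpkm, noise_zero_prob
        a noise gene's value is exactly 0 with probability
        ``noise_zero_prob``, else uniform on (0, noise_max_fpkm).
    snp_informative_prob
        probability that a gene carries >= 1 strain-informative SNP
        (0.82 mirrors a CAST x C57 F1 cross).
    snp_read_depth_scale
        informative reads per gene per cell ~ Poisson(scale x FPKM).
    """

    n_a_genes: int = 4000
    n_x_genes: int = 400
    expr_meanlog: float = 1.5
    expr_sdlog: float = 1.0
    upregulation_factor: float = 2.0
    active_x_count: int = 1
    x_noise_fraction: float = 0.45
    a_noise_fraction: float = 0.20
    noise_max_fpkm: float = 1.0
    noise_zero_prob: float = 0.5
    snp_informative_prob: float = 0.82
    snp_read_depth_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a_genes < 1 or self.n_x_genes < 1:
            raise ValueError("gene counts must be positive")
        for name in ("x_noise_fraction", "a_noise_fraction", "noise_zero_prob",
                     "snp_informative_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.upregulation_factor < 0:
            raise ValueError("upregulation_factor must be >= 0")
        if self.active_x_count not in (1, 2):
            raise ValueError("active_x_count must be 1 or 2")
        if self.expr_sdlog <= 0 or self.noise_max_fpkm <= 0:
            raise ValueError("expr_sdlog and noise_max_fpkm must be positive")
        if self.snp_read_depth_scale <= 0:
            raise ValueError("snp_read_depth_scale must be positive")


@dataclass(frozen=True)
class StageSpec:
    """One developmental stage of the paternal-X silencing schedule."""

    name: str
    paternal_silenced_fraction: float  # s in [0, 1]
    n_female_cells: int
    n_male_cells: int

    def __post_init__(self) -> None:
        if not 0 <= self.paternal_silenced_fraction <= 1:
            raise ValueError("paternal_silenced_fraction must be in [0, 1]")


@dataclass(frozen=True)
class StageSchedule:
    """Ordered silencing schedule across preimplantation stages.

    compensation
        ``full``: the maternal X output of each female cell rises so
        the per-gene X total stays constant as the paternal allele is
        silenced; ``none``: the maternal allele is unchanged.
    silencing_mode
        ``graded`` (default): every X gene's paternal output is scaled
        by ``1 - s`` — the medians then change smoothly and maternal +
        paternal recovery is exactly complementary.  ``binary``: a
        fraction ``s`` of X genes has the paternal allele fully off;
        once s >= 0.5 the median paternal expression is exactly zero.
    """

    stages: tuple[StageSpec, ...]
    compensation: str = "full"
    silencing_mode: str = "graded"

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("schedule needs at least one stage")
        if self.compensation not in ("full", "none"):
            raise ValueError("compensation must be 'full' or 'none'")
        if self.silencing_mode not in ("graded", "binary"):
            raise ValueError("silencing_mode must be 'graded' or 'binary'")
        s = [st.paternal_silenced_fraction for st in self.stages]
        if s != sorted(s):
            raise ValueError("silencing fractions must be non-decreasing across stages")


def preimplantation_schedule(
    n_cells_scale: float = 1.0, compensation: str = "full"
) -> StageSchedule:
    """Default preset: 4-cell -> 16-cell -> early blastocyst.

    Cell counts mirror a typical allele-resolved preimplantation
    single-cell study (female 11/21/15, male 3/27/28); ``n_cells_scale``
    shrinks them proportionally for quick runs (minimum 1 per group).
    """

    def n(k: int) -> int:
        return max(1, round(k * n_cells_scale))

    return StageSchedule(
        stages=(
            StageSpec("4cell", 0.0, n(11), n(3)),
            StageSpec("16cell", 0.55, n(21), n(27)),
            StageSpec("early_blast", 0.85, n(15), n(28)),
        ),
        compensation=compensation,
    )


@dataclass
class ExpectedRatios:
    """Analytic median-based expectations under the generative model."""

    x_a: float
    xm_aa: float
    xp_aa: float


@dataclass
class SimulationTruth:
    params: SimulationParams
    gene_flags: pd.Series  # gene id -> "active" | "noise"
    schedule: StageSchedule | None = None
    maternal_share: pd.DataFrame | None = None  # genes x cells, generative share
    expected: dict = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix
    annotation: GeneAnnotation
    allele_counts: AlleleCountTable | None
    truth: SimulationTruth
    maternal_fpkm: pd.DataFrame | None = None  # generative allelic FPKM
    paternal_fpkm: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# internals


def _gene_ids(params: SimulationParams) -> tuple[list[str], list[str]]:
    a = [f"geneA{i:05d}" for i in range(params.n_a_genes)]
    x = [f"geneX{i:05d}" for i in range(params.n_x_genes)]
    return a, x


def _annotation(params: SimulationParams) -> GeneAnnotation:
    a_ids, x_ids = _gene_ids(params)
    chrom = {g: f"chr{(i % N_AUTOSOMES) + 1}" for i, g in enumerate(a_ids)}
    chrom.update({g: "chrX" for g in x_ids})
    return GeneAnnotation(chrom)


def _noise_flags(params: SimulationParams, rng: np.random.Generator) -> pd.Series:
    """Per-gene active/noise flags with deterministic group counts."""
    a_ids, x_ids = _gene_ids(params)
    flags = pd.Series("active", index=a_ids + x_ids, dtype=object)
    n_a_noise = round(params.a_noise_fraction * params.n_a_genes)
    n_x_noise = round(params.x_noise_fraction * params.n_x_genes)
    flags[rng.choice(a_ids, size=n_a_noise, replace=False)] = "noise"
    flags[rng.choice(x_ids, size=n_x_noise, replace=False)] = "noise"
    return flags


def _noise_values(
    params: SimulationParams, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    vals = rng.uniform(0, params.noise_max_fpkm, size=shape)
    vals[rng.random(shape) < params.noise_zero_prob] = 0.0
    return vals


# ---------------------------------------------------------------------------
# generators


def simulate_expression(params: SimulationParams, n_samples: int) -> SimulatedDataset:
    """Expression-only dataset: ``n_samples`` cells of one condition.

    Female-like cells with ``active_x_count`` active X alleles and the
    buffered X output ``u``; no allelic counts.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(params.seed)
    a_ids, x_ids = _gene_ids(params)
    flags = _noise_flags(params, rng)
    genes = a_ids + x_ids
    g = rng.lognormal(params.expr_meanlog, params.expr_sdlog, size=(len(genes), n_samples))
    values = np.empty_like(g)
    is_x = np.array([gid.startswith("geneX") for gid in genes])
    values[~is_x] = 2.0 * g[~is_x]
    values[is_x] = params.upregulation_factor * g[is_x]
    noise_mask = (flags == "noise").to_numpy()
    values[noise_mask] = _noise_values(params, (noise_mask.sum(), n_samples), rng)
    samples = [f"cell{j:03d}" for j in range(n_samples)]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    u = params.upregulation_factor
    if params.active_x_count == 2:
        allelic = ExpectedRatios(x_a=u / 2, xm_aa=u / 4, xp_aa=u / 4)
    else:  # single active X: all X output on one (maternal, by convention) allele
        allelic = ExpectedRatios(x_a=u / 2, xm_aa=u / 2, xp_aa=0.0)
    truth = SimulationTruth(
        params=params,
        gene_flags=flags,
        expected={"filtered": allelic, "all_genes_x_a": expected_all_genes_xa(params)},
    )
    return SimulatedDataset(matrix, _annotation(params), None, truth)


def simulate_timecourse(
    params: SimulationParams, schedule: StageSchedule
) -> SimulatedDataset:
    """Multi-stage dataset with expression, allelic FPKM truth and SNP counts.

    Cells are generated stage by stage; female cells follow the
    schedule's paternal silencing, male cells have a single maternal X
    (paternal X share identically zero).  Observed FPKM is the exact
    sum of the generative maternal and paternal FPKMs.
    """
    rng = np.random.default_rng(params.seed)
    a_ids, x_ids = _gene_ids(params)
    genes = a_ids + x_ids
    flags = _noise_flags(params, rng)
    noise_mask = (flags == "noise").to_numpy()
    is_x = np.array([gid.startswith("geneX") for gid in genes])
    informative = rng.random(len(genes)) < params.snp_informative_prob
    u = params.upregulation_factor
    comp = 1.0 if schedule.compensation == "full" else 0.0

    cell_ids: list[str] = []
    meta_rows: list[dict] = []
    m_cols: list[np.ndarray] = []
    p_cols: list[np.ndarray] = []
    for stage in schedule.stages:
        s = stage.paternal_silenced_fraction
        for sex, n_cells in (("female", stage.n_female_cells), ("male", stage.n_male_cells)):
            for i in range(n_cells):
                cid = f"{stage.name}_{'F' if sex == 'female' else 'M'}{i:02d}"
                cell_ids.append(cid)
                meta_rows.append({"sample_id": cid, "stage": stage.name, "sex": sex})
                g = rng.lognormal(params.expr_meanlog, params.expr_sdlog, size=len(genes))
                m = np.empty(len(genes))
                p = np.empty(len(genes))
                m[~is_x] = g[~is_x]
                p[~is_x] = g[~is_x]
                gx = g[is_x]
                if sex == "male":
                    m[is_x] = u * gx
                    p[is_x] = 0.0
                elif schedule.silencing_mode == "graded":
                    m[is_x] = (u / 2.0) * (1.0 + comp * s) * gx
                    p[is_x] = (u / 2.0) * (1.0 - s) * gx
                else:  # binary per-gene silencing
                    silenced = rng.random(is_x.sum()) < s
                    m[is_x] = (u / 2.0) * np.where(silenced, 1.0 + comp, 1.0) * gx
                    p[is_x] = (u / 2.0) * np.where(silenced, 0.0, 1.0) * gx
                noise_vals = _noise_values(params, (int(noise_mask.sum()),), rng)
                m[noise_mask] = noise_vals / 2.0
                p[noise_mask] = noise_vals / 2.0
                if sex == "male":
                    xn = noise_mask & is_x
                    m[xn] = m[xn] + p[xn]  # male X noise is maternal too
                    p[xn] = 0.0
                m_cols.append(m)
                p_cols.append(p)

    maternal = pd.DataFrame(np.column_stack(m_cols), index=genes, columns=cell_ids)
    paternal = pd.DataFrame(np.column_stack(p_cols), index=genes, columns=cell_ids)
    total = maternal + paternal
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = ExpressionMatrix(total, sample_meta=meta)

    # SNP-overlapping reads: Poisson in total FPKM, binomial allele split
    info_genes = np.array(genes)[informative]
    tot_info = total.loc[info_genes].to_numpy()
    m_info = maternal.loc[info_genes].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(tot_info > 0, m_info / np.where(tot_info > 0, tot_info, 1.0), 0.0)
    n_reads = rng.poisson(params.snp_read_depth_scale * tot_info)
    m_reads = rng.binomial(n_reads, share)
    idx = pd.MultiIndex.from_product([info_genes, cell_ids], names=["gene_id", "sample_id"])
    counts = AlleleCountTable(
        pd.DataFrame(
            {
                "maternal_reads": m_reads.ravel(),
                "paternal_reads": (n_reads - m_reads).ravel(),
            },
            index=idx,
        )
    )

    share_all = pd.DataFrame(
        np.where(total.to_numpy() > 0, maternal.to_numpy() / np.where(total.to_numpy() > 0, total.to_numpy(), 1.0), np.nan),
        index=genes,
        columns=cell_ids,
    )
    expected = {
        (stage.name, sex): expected_ratios(
            params,
            s=stage.paternal_silenced_fraction,
            compensation=schedule.compensation,
            sex=sex,
            silencing_mode=schedule.silencing_mode,
        )
        for stage in schedule.stages
        for sex in ("female", "male")
    }
    truth = SimulationTruth(
        params=params,
        gene_flags=flags,
        schedule=schedule,
        maternal_share=share_all,
        expected=expected,
    )
    return SimulatedDataset(matrix, _annotation(params), counts, truth, maternal, paternal)


# ---------------------------------------------------------------------------
# analytic oracles


def expected_ratios(
    params: SimulationParams,
    s: float = 0.0,
    compensation: str = "full",
    sex: str = "female",
    silencing_mode: str = "graded",
) -> ExpectedRatios:
    """Expected (X:A, Xm:AA, Xp:AA) medians after noise filtering.

    Valid when noise fractions are below 0.5 and the expression cutoff
    removes the noise genes, so group medians track active genes.  With
    the shared-allele draw the autosomal median is exactly ``2 m`` and
    every X median is an exact (graded) or numeric-mixture (binary)
    transform of the same log-normal, so the ratios are free of the
    log-normal scale ``m``.
    """
    if params.x_noise_fraction >= 0.5 or params.a_noise_fraction >= 0.5:
        raise ValueError("noise fraction >= 0.5: medians are noise-dominated, oracle invalid")
    if not 0 <= s <= 1:
        raise ValueError("s must be in [0, 1]")
    u = params.upregulation_factor
    if sex == "male":
        return ExpectedRatios(x_a=u / 2, xm_aa=u / 2, xp_aa=0.0)
    if sex != "female":
        raise ValueError("sex must be 'female' or 'male'")
    comp = 1.0 if compensation == "full" else 0.0
    if silencing_mode == "graded":
        xm = u * (1.0 + comp * s) / 4.0
        xp = u * (1.0 - s) / 4.0
        xa = u * (2.0 - (1.0 - comp) * s) / 4.0
        return ExpectedRatios(x_a=xa, xm_aa=xm, xp_aa=xp)
    # binary: numeric median of the per-gene mixture, in units of m = e^meanlog
    dist = stats.lognorm(s=params.expr_sdlog)  # scale 1 <=> median 1 in m-units
    half_u = u / 2.0

    def mixture_median(weights_scales: list[tuple[float, float]]) -> float:
        def cdf(t: float) -> float:
            return sum(w * dist.cdf(t / sc) for w, sc in weights_scales if sc > 0) + sum(
                w for w, sc in weights_scales if sc == 0
            )

        hi = 10.0 * max(sc for _, sc in weights_scales)
        return float(optimize.brentq(lambda t: cdf(t) - 0.5, 1e-12, hi))

    xm_med = mixture_median([(1 - s, half_u), (s, half_u * (1 + comp))])
    if s >= 0.5:
        xp_med = 0.0
    else:
        xp_med = float(half_u * dist.ppf((0.5 - s) / (1 - s)))
    if compensation == "full":
        xa_med = u  # per-gene total preserved at u * g
    else:
        xa_med = mixture_median([(1 - s, u), (s, half_u)])
    a_med = 2.0
    return ExpectedRatios(x_a=xa_med / a_med, xm_aa=xm_med / a_med, xp_aa=xp_med / a_med)


def expected_all_genes_xa(params: SimulationParams) -> float:
    """Expected all-genes (cutoff 0, at_least) X:A median ratio.

    Numeric median of the active/noise mixture per chromosome group:
    noise genes contribute a point mass at zero plus a uniform tail
    below ``noise_max_fpkm``; active genes are log-normal.
    """
    dist = stats.lognorm(s=params.expr_sdlog, scale=np.exp(params.expr_meanlog))

    def group_median(noise_frac: float, scale: float) -> float:
        def cdf(t: float) -> float:
            noise_cdf = params.noise_zero_prob + (1 - params.noise_zero_prob) * min(
                t / params.noise_max_fpkm, 1.0
            )
            return noise_frac * noise_cdf + (1 - noise_frac) * dist.cdf(t / scale)

        if cdf(0.0) >= 0.5:
            return 0.0
        hi = 100.0 * scale * float(dist.ppf(0.999))
        return float(optimize.brentq(lambda t: cdf(t) - 0.5, 1e-12, hi))

    x_med = group_median(params.x_noise_fraction, params.upregulation_factor)
    a_med = group_median(params.a_noise_fraction, 2.0)
    if a_med == 0:
        raise ValueError("autosomal median is zero under these noise settings")
    return x_med / a_med
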