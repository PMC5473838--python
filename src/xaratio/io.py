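"""Reading, validation and gene partitioning for FPKM expression tables.

The pipeline consumes three plain-text inputs:

* an expression table (genes x samples, FPKM),
* a gene-to-chromosome annotation (GTF or two-column TSV),
* an allelic SNP read-count table (gene, sample, maternal reads,
  paternal reads).

All tables are validated on read: FPKM values must be finite and
non-negative, identifiers unique, and allele counts non-negative
integers.  Genes are then partitioned into X-linked and autosomal sets;
Y, mitochondrial and unplaced-scaffold genes are excluded from the
autosomal denominator by default because the X:A contrast is X versus
(diploid) autosomes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "GenePartition",
    "AlleleCountTable",
    "PartitionPolicy",
    "read_expression_table",
    "write_expression_table",
    "read_gene_annotation",
    "read_allele_counts",
    "write_allele_counts",
    "partition_genes",
]


class InputError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples table of FPKM values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
        Every cell must hold a finite value >= 0; missing entries are an
        input error, not implicit zeros.
    sample_meta
        Optional per-sample annotation (e.g. ``sex`` in
        {female, male, unknown}, ``stage``, ``group``), indexed by
        sample id.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(v)
            raise InputError(f"non-numeric expression value at {bad}")
        if np.isnan(arr).any():
            g, s = _first_where(v, np.isnan(arr))
            raise InputError(f"missing expression value for gene {g!r}, sample {s!r}")
        if np.isinf(arr).any():
            g, s = _first_where(v, np.isinf(arr))
            raise InputError(f"non-finite expression value for gene {g!r}, sample {s!r}")
        if (arr < 0).any():
            g, s = _first_where(v, arr < 0)
            raise InputError(
                f"negative FPKM {v.loc[g, s]} for gene {g!r}, sample {s!r}"
            )
        if self.sample_meta is not None:
            missing = [s for s in v.columns if s not in self.sample_meta.index]
            if missing:
                raise InputError(f"samples missing from sample_meta: {missing[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """FPKM vector of one sample, indexed by gene id."""
        if sample_id not in self.values.columns:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.values[sample_id]

    def scaled(self, sample_id: str, factor: float) -> "ExpressionMatrix":
        """Copy with one sample's FPKMs multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        v = self.values.copy()
        v[sample_id] = v[sample_id] * factor
        return ExpressionMatrix(v, self.sample_meta)


def _first_where(df: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return df.index[i], df.columns[j]


def _first_non_numeric(df: pd.DataFrame) -> str:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            return f"gene {gene!r}, sample {col!r} (value {df.loc[gene, col]!r})"
    return "unknown position"


@dataclass
class GeneAnnotation:
    """Mapping from gene id to chromosome name.

    Genes annotated on more than one chromosome are recorded in
    ``ambiguous`` and removed from the mapping (they cannot be placed in
    the X/autosome partition).
    """

    chromosomes: dict[str, str]
    ambiguous: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def get(self, gene_id: str) -> str | None:
        return self.chromosomes.get(gene_id)


@dataclass(frozen=True)
class GenePartition:
    """Disjoint split of a matrix's genes into X-linked / autosomal / excluded."""

    x_genes: frozenset[str]
    a_genes: frozenset[str]
    excluded: dict[str, str]  # gene id -> reason

    def __post_init__(self) -> None:
        if self.x_genes & self.a_genes:
            raise ValueError("x_genes and a_genes overlap")

    @property
    def n_total(self) -> int:
        return len(self.x_genes) + len(self.a_genes) + len(self.excluded)


@dataclass
class AlleleCountTable:
    """Per (gene, sample) maternal / paternal SNP-overlapping read counts.

    Genes absent from the table carry no informative SNP and are dropped
    from allelic analyses (they are *not* zero-count genes).
    """

    counts: pd.DataFrame  # MultiIndex (gene_id, sample_id); columns maternal_reads, paternal_reads

    def __post_init__(self) -> None:
        c = self.counts
        expected = ["maternal_reads", "paternal_reads"]
        if list(c.columns) != expected:
            raise InputError(f"allele count columns must be {expected}, got {list(c.columns)}")
        for col in expected:
            vals = c[col]
            if vals.isna().any():
                raise InputError(f"missing value in column {col!r}")
            frac = vals.astype(float) % 1 != 0
            if frac.any():
                gene, sample = c.index[frac.to_numpy().argmax()]
                raise InputError(
                    f"non-integer {col} for gene {gene!r}, sample {sample!r}"
                )
            if (vals < 0).any():
                gene, sample = c.index[(vals < 0).to_numpy().argmax()]
                raise InputError(
                    f"negative {col} for gene {gene!r}, sample {sample!r}"
                )
        self.counts = c.astype(np.int64)
        if c.index.has_duplicates:
            raise InputError("duplicate (gene, sample) rows in allele count table")

    def __len__(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_table(path, dialect: str = "generic_tsv") -> ExpressionMatrix:
    """Read an FPKM table.

    ``generic_tsv``: header row names samples, first column names genes.
    ``fpkm_tracking``: Cufflinks isoform/gene tracking layout; gene ids
    come from ``tracking_id`` and samples from the ``<sample>_FPKM``
    columns.

    Duplicate gene rows are collapsed by summation (transcript-to-gene
    aggregation keeps FPKM additive); a warning is emitted.
    """
    if dialect == "generic_tsv":
        # pandas mangles duplicate header names, so check the raw header
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    header = line.rstrip("\n").split("\t")[1:]
                    break
            else:
                raise InputError(f"{path}: empty file")
        seen = [h for h in set(header) if header.count(h) > 1]
        if seen:
            raise InputError(f"{path}: duplicate sample columns {sorted(seen)}")
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    elif dialect == "fpkm_tracking":
        raw = pd.read_csv(path, sep="\t", comment="#")
        if "tracking_id" not in raw.columns:
            raise InputError(f"{path}: fpkm_tracking dialect requires a tracking_id column")
        fpkm_cols = [c for c in raw.columns if c.endswith("_FPKM")]
        if not fpkm_cols:
            raise InputError(f"{path}: no *_FPKM columns found")
        df = raw.set_index("tracking_id")[fpkm_cols]
        df.columns = [c[: -len("_FPKM")] for c in df.columns]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate sample columns {dups}")
    # validate numerics before any collapsing so the error names the raw row
    probe = ExpressionMatrix(df[~df.index.duplicated(keep="first")])
    del probe
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        warnings.warn(
            f"{path}: {len(dups)} duplicate gene rows collapsed by sum", stacklevel=2
        )
        df = df.groupby(level=0, sort=False).sum()
    return ExpressionMatrix(df.astype(float))


def write_expression_table(
    matrix: ExpressionMatrix, path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_annotation(path, fmt: str = "two_column_tsv") -> GeneAnnotation:
    """Read a gene -> chromosome mapping from a GTF or a two-column TSV.

    A gene listed on more than one chromosome is recorded as ambiguous
    and excluded from the mapping.
    """
    pairs: list[tuple[str, str]] = []
    if fmt == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise InputError(
                        f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                    )
                m = _GTF_GENE_ID.search(fields[8])
                if m is None:
                    raise InputError(
                        f"{path}: line {lineno}: no gene_id attribute"
                    )
                pairs.append((m.group(1), fields[0]))
    elif fmt == "two_column_tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if "gene_id" in df.columns and "chromosome" in df.columns:
            df = df[["gene_id", "chromosome"]]
        else:  # headerless two-column file
            df = pd.read_csv(
                path, sep="\t", comment="#", header=None,
                names=["gene_id", "chromosome"], dtype=str,
            )
        if df.isna().any().any():
            lineno = int(df.isna().any(axis=1).to_numpy().argmax()) + 1
            raise InputError(f"{path}: line {lineno}: missing field")
        pairs = list(df.itertuples(index=False, name=None))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    chrom: dict[str, str] = {}
    ambiguous: set[str] = set()
    for gene, c in pairs:
        if gene in ambiguous:
            continue
        prev = chrom.get(gene)
        if prev is None:
            chrom[gene] = c
        elif prev != c:
            del chrom[gene]
            ambiguous.add(gene)
    return GeneAnnotation(chrom, ambiguous)


def read_allele_counts(path) -> AlleleCountTable:
    """Read a four-column TSV: gene_id, sample_id, maternal_reads, paternal_reads."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "sample_id": str})
    required = ["gene_id", "sample_id", "maternal_reads", "paternal_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    df = df.set_index(["gene_id", "sample_id"])[["maternal_reads", "paternal_reads"]]
    return AlleleCountTable(df)


def write_allele_counts(
    table: AlleleCountTable, path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.counts.reset_index().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# partitioning


@dataclass(frozen=True)
class PartitionPolicy:
    """How chromosome names map to the X / autosome / excluded split.

    Names are normalized by stripping an optional ``chr`` prefix and
    upper-casing, so ``chrX`` and ``X`` are equivalent.  Anything that is
    neither X, an excluded name, nor a plain number is treated as an
    unplaced scaffold.
    """

    normalize: bool = True
    x_names: tuple[str, ...] = ("X",)
    exclude_names: tuple[str, ...] = ("Y", "MT", "M")

    def normalize_name(self, name: str) -> str:
        name = str(name).strip()
        if self.normalize:
            if name.lower().startswith("chr"):
                name = name[3:]
            name = name.upper()
        return name


def partition_genes(
    matrix: ExpressionMatrix,
    ann: GeneAnnotation,
    policy: PartitionPolicy | None = None,
) -> GenePartition:
    """Assign every matrix gene to exactly one of x / autosome / excluded.

    Raises if either the X or the autosomal group comes out empty, since
    a median ratio is then undefined.
    """
    policy = policy or PartitionPolicy()
    x: set[str] = set()
    a: set[str] = set()
    excluded: dict[str, str] = {}
    x_set = {policy.normalize_name(n) for n in policy.x_names}
    excl_set = {policy.normalize_name(n) for n in policy.exclude_names}
    for gene in matrix.gene_ids:
        if gene in ann.ambiguous:
            excluded[gene] = "ambiguous chromosome"
            continue
        chrom = ann.get(gene)
        if chrom is None:
            excluded[gene] = "unannotated"
            continue
        name = policy.normalize_name(chrom)
        if name in x_set:
            x.add(gene)
        elif name in excl_set:
            excluded[gene] = name
        elif name.isdigit():
            a.add(gene)
        else:
            excluded[gene] = "unplaced scaffold"
    if not x:
        raise InputError("partition produced zero X-linked genes; X:A ratio undefined")
    if not a:
        raise InputError("partition produced zero autosomal genes; X:A ratio undefined")
    return GenePartition(frozenset(x), frozenset(a), excluded)
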