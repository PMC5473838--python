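# xaratio

Bootstrap estimation of X-chromosome dosage compensation from FPKM
expression tables, with allele-specific (maternal/paternal) resolution
for hybrid single-cell data.

## The problem

Ohno's hypothesis holds that mammalian dosage compensation is a
two-step mechanism: one female X is inactivated, and the remaining
active X is transcriptionally upregulated about two-fold in both sexes,
so that X-linked output matches the two autosomal copies
(X:AA &asymp; 1). Naively computed X:A expression ratios from RNA-seq
often come out near 0.5 instead — but that estimate is dominated by the
excess of genes with zero or very low expression on the X chromosome.
Once no-/low-expression genes are removed by an FPKM cutoff, the ratio
of median expressions rises to and stabilizes near 1.

In hybrid (e.g. CAST &times; C57 F1) single-cell data, strain-specific
SNPs let the same analysis resolve each X allele separately. During
imprinted X inactivation in female preimplantation embryos, the
paternal Xp:AA ratio falls stage by stage while the maternal Xm:AA
rises to compensate, keeping total X:AA near 1; male cells (single
maternal X) show Xm:AA &asymp; 1 and Xp:AA = 0 throughout.

`xaratio` implements this analysis as a tested, reusable pipeline, plus
a synthetic-data generator with analytic ground truth so every stage
can be validated end to end without any external download.

## The statistic

For one sample, genes are split into X-linked and autosomal groups and
filtered by an FPKM cutoff (`Exp`; genes with expression &ge; `Exp` are
retained). Each bootstrap replicate draws 100 genes with replacement
from each group and records

&nbsp;&nbsp;&nbsp;&nbsp;r&#7495; = median(X draw) / median(A draw)

Over 1000 replicates the point estimate is the median of the r&#7495;
and the confidence interval is the 2.5–97.5 percentile band. For
allele-resolved data the numerator is the maternal (or paternal) FPKM
of SNP-informative X genes — total FPKM apportioned by the SNP read
fraction f = m/(m+p) — over the total both-allele autosomal median
(Xm:AA, Xp:AA).

## Worked example

```python
from xaratio import (SimulationParams, simulate_expression, partition_genes,
                     FilterConfig, BootstrapConfig, xa_ratio_for_sample,
                     proximity_assessment)

params = SimulationParams(seed=7)                 # u = 2, one active X, X-enriched noise
ds = simulate_expression(params, n_samples=1)
partition = partition_genes(ds.matrix, ds.annotation)
cell = ds.matrix.sample_ids[0]

for label, cutoff in [("all genes", 0.0), ("FPKM >= 1", 1.0)]:
    est = xa_ratio_for_sample(ds.matrix, partition, cell, FilterConfig(cutoff=cutoff),
                              BootstrapConfig(seed=1))
    prox = proximity_assessment(est)
    print(f"{label:10s}  X:A = {est.point:.3f}  95% CI [{est.ci_low:.3f}, {est.ci_high:.3f}]"
          f"  (n_x={est.n_x}, n_a={est.n_a})  closer to {prox['closer_to']}")
```

prints

```
all genes   X:A = 0.375  95% CI [0.111, 0.844]  (n_x=400, n_a=4000)  closer to 0.5
FPKM >= 1   X:A = 1.079  95% CI [0.761, 1.442]  (n_x=216, n_a=3157)  closer to 1.0
```

The cell was simulated with a fully upregulated single active X
(upregulation factor u = 2), so its true filtered X:A is 1. With all
genes included, the X-enriched low-expression noise drags the estimate
down to 0.375 — the classic artifact; the FPKM &ge; 1 filter recovers
the generative ratio, and the bootstrap distribution sits closer to 1
than to 0.5.

## Command line

The same pipeline is exposed as a CLI (`simulate`, `xa-ratio`, `sweep`,
`allelic`, `timecourse`, `qc`):

```sh
xaratio simulate --seed 7 --timecourse --out-dir run/
xaratio timecourse --expression run/expression.tsv --annotation run/annotation.tsv \
    --allele-counts run/allele_counts.tsv --sample-meta run/sample_meta.tsv \
    --seed 1 --out run/timecourse.tsv
```

Outputs are TSVs with a `# config_sha256=...` header line; every run is
reproducible from its config and seed, and logs to stderr and
`run.log`.

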