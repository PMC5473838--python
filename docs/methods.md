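# Methods

## Estimation procedure

The X:A ratio of one sample is estimated by a gene-group bootstrap.
After partitioning genes into X-linked and autosomal sets (Y,
mitochondrial, unplaced-scaffold, unannotated and
ambiguously-annotated genes are excluded; chromosome names are
normalized by stripping an optional `chr` prefix, case-insensitively,
so mixed annotation dialects coexist), an expression filter retains
genes whose FPKM passes the cutoff. Each of `n_boot` (default 1000)
replicates draws `n_sample` (default 100) genes with replacement from
each group and records median(X)/median(A); the point estimate is the
median of the replicate ratios, the interval the 2.5–97.5 percentile
band (level configurable). Medians use the conventional even-length
definition (mean of the two central order statistics), so small cases
can be verified bit-for-bit against direct computation. Sampling is
with replacement — the standard bootstrap — which keeps `n_sample`
well-defined when a filtered single cell retains fewer than 100 X
genes (a warning is emitted in that case); an exhaustive
without-replacement mode exists for oracle checks, where drawing the
whole group reduces every replicate to the plain median ratio.

Randomness is controlled by one root seed per run; per-sample analyses
derive a child seed from the root via a `SeedSequence` spawn key on the
sample index, so adding or removing a sample never perturbs the other
samples' estimates, and identical (inputs, seed) give bit-identical
bootstrap distributions.

Closeness of an estimate to the reference ratios 1 (compensation) and
0.5 (no compensation) is summarized by `proximity_assessment`: the
fraction of bootstrap replicates strictly closer to each reference,
ties split evenly and broken toward 1. This transparent bootstrap
support criterion is used instead of an opaque parametric test because
the relevant question — which regime the estimate supports — is about
the bootstrap distribution itself. Distribution shape between the X
and autosomal groups is compared with the two-sample
Kolmogorov–Smirnov test (scipy) on log-scale values.

## Filtering

The cutoff comparator defaults to *at least* (FPKM &ge; cutoff);
*greater than* is available, and cutoff 0 with *greater than* selects
exactly the genes with any expression. Defaults are 1.0 FPKM for bulk
samples and 0.1 for single cells. Filtering scope is per-sample by
default — each cell defines its own expressed-gene set, matching the
per-cell estimation — with a pooled-mean scope available for cohorts
that should share one gene set. For allele-specific ratios the filter
is always applied to the **total** (both-allele) gene FPKM: a silenced
allele of an expressed gene must enter the numerator as a genuine
zero; gating on allele-specific FPKM would delete the very signal the
time-course measures.

## Allelic assignment

Maternal fraction per gene per cell is f = m/(m+p) from
strain-informative SNP read counts, with no mapping-bias correction,
defined only where m + p &ge; `min_informative_reads` (default 3 —
enough to suppress single-read noise while retaining most expressed
genes; configurable). Genes absent from the count table are
SNP-uninformative and are dropped from allelic analyses, not treated
as zero. Total FPKM is apportioned as maternal = f·total,
paternal = total − maternal; a short re-derivation loop enforces the
conservation identity maternal + paternal == total *bitwise* (a single
floating-point rounding of total − maternal can otherwise leave the
sum off by one ulp).

Xm:AA and Xp:AA take the chosen allele's FPKM over SNP-informative,
filter-passing X genes as the numerator group and the total FPKM of
filter-passing autosomal genes as the denominator group. The
both-allele denominator is what makes the scale interpretable: a
balanced biallelic female gives ~0.5 per allele, a male (or fully
compensated female) gives Xm:AA ~ 1.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with every
parameter exposed:

- **Expression.** Per (gene, cell), one log-normal gene-level draw `g`
  (`expr_meanlog` = 1.5, `expr_sdlog` = 1.0 natural-log units,
  i.e. a median of ~4.5 FPKM per allele — a typical expressed-gene
  scale). Both alleles of an autosomal gene share the draw (alleles
  share their cell's regulatory state), so the total is exactly `2g`
  and the autosomal median is exactly `2·exp(meanlog)`. This shared
  draw is deliberate: with independent per-allele draws the median of
  the two-allele sum exceeds twice the per-allele median for any
  skewed distribution, which would bias the filtered X:A below the
  generative ratio and make the analytic oracle intractable.
- **X output.** The X chromosome emits a buffered total of
  `upregulation_factor` (u, default 2 = full Ohno upregulation)
  autosomal-allele units per cell, shared across its active alleles.
  The buffered-total convention reflects the observation the pipeline
  is built to test: X:A is the same whether one or two X alleles are
  active.
- **Noise.** A fraction of genes per chromosome group
  (`x_noise_fraction` = 0.45 &gt; `a_noise_fraction` = 0.20) is silent
  and emits exact zeros with probability 0.5, else uniform FPKM below
  `noise_max_fpkm` = 1.0. Uniform-below-cutoff is the least-structured
  model of sub-threshold noise; the X excess reproduces the observed
  pile-up of no-/low-expression genes on the X. Group sizes default to
  4000 autosomal / 400 X genes — large enough that per-cell medians are
  stable, small enough for seconds-scale runs.
- **Silencing schedule.** Female cells follow an ordered schedule of
  paternal silencing fractions `s` (preset: 4-cell 0.0, 16-cell 0.55,
  early blastocyst 0.85; per-stage cell counts 11/21/15 female and
  3/27/28 male). Under `graded` silencing (default) every X gene's
  paternal output is scaled by (1−s) and, with full compensation, the
  maternal output by (1+s), preserving each gene's total. A `binary`
  mode (a fraction s of genes with the paternal allele fully off,
  maternal doubled under compensation) is also implemented; it is not
  the default because the median paternal expression collapses to
  exactly zero once s &ge; 0.5, so median-based Xp:AA cannot resolve
  the late stages and maternal + paternal medians are no longer
  complementary. Male cells have all X output on the maternal allele
  at every stage.
- **SNP counts.** Each gene is SNP-informative with probability 0.82
  (an F1 hybrid of divergent strains); informative reads per gene per
  cell are Poisson(`snp_read_depth_scale` &times; FPKM) with
  `snp_read_depth_scale` = 2, split binomially by the generative
  maternal share.

`expected_ratios` returns the analytic medians: with graded silencing
and full compensation, X:A = u/2, Xm:AA = u(1+s)/4, Xp:AA = u(1−s)/4
(exact, scale-free); binary-mode medians are computed numerically from
the mixture CDF (scipy lognorm + Brent root-finding), and the
all-genes ratio from the noise/active mixture CDF the same way. These
oracles are valid while noise fractions stay below 0.5 and the
expression cutoff removes the noise band; synthetic analyses therefore
use the 1.0-FPKM cutoff (the generator's noise ceiling), the analogue
of placing the real-data cutoff just above the noise floor.

### What the generator does not emulate

Gene-length and library-size effects inside FPKM, transcript-level
structure, escape genes, cell-cycle and batch variation, allelic
mapping bias, and bursty transcription kinetics. Passing tests
demonstrate that the estimator recovers known truth under the stated
generative assumptions — not that those assumptions exhaust real
single-cell data. One realistic artifact is present and worth knowing:
because allelic calls require &ge; 3 informative reads, lowly expressed
genes drop out of the allelic numerator more often, which biases
per-cell Xm:AA/Xp:AA upward by a few percent relative to truth (well
inside the bootstrap intervals, as the coverage tests measure).

## Numerical choices and degenerate inputs

- A bootstrap replicate with a zero autosomal median is an error;
  zero values themselves are admitted only for the all-genes analysis
  and for allele-specific numerators, where a silenced allele is
  signal. An allele-specific estimate may therefore be exactly 0.
- Group sizes below `min_group_size` (default 20) raise an error
  naming the sample; inside a cutoff sweep or time-course such cells
  are recorded as missing instead of aborting the run.
- Duplicate gene rows in an expression file collapse by sum (FPKM is
  additive over transcripts) with a warning; duplicate sample columns
  are an error. Genes annotated on several chromosomes are excluded as
  ambiguous. Pseudoautosomal genes follow their annotation (X-linked
  if annotated on X).
- Proximity ties (a replicate exactly equidistant from both
  references) are split evenly and reported toward the reference 1
  with support 0.5.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data: 8 cells of 4400 genes for the bulk-style contrast and cutoff
sweep; the full 105-cell preset time-course for the stage trajectory;
20 replicate simulations at reduced per-stage cell counts (scale 0.15)
for the interval-coverage check; 100 000 bootstrap replicates for the
oracle-agreement check. These sizes keep per-cell median noise small
relative to the effects under test while the whole suite completes in
well under a minute.
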