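import numpy as np
import pandas as pd
import pytest

from xaratio import (
    AlleleCountTable,
    BootstrapConfig,
    ExpressionMatrix,
    FilterConfig,
    GroupSizeError,
    allelic_xaa_ratio,
    estimate_allelic_fractions,
    partition_genes,
    preimplantation_schedule,
    simulate_timecourse,
    snp_coverage_by_chromosome,
    split_expression,
    stage_timecourse,
    timecourse_frame,
    SimulationParams,
    StageSchedule,
    StageSpec,
)


def counts_table(rows):
    idx = pd.MultiIndex.from_tuples(
        [(g, s) for g, s, _, _ in rows], names=["gene_id", "sample_id"]
    )
    return AlleleCountTable(
        pd.DataFrame(
            {
                "maternal_reads": [m for _, _, m, _ in rows],
                "paternal_reads": [p for _, _, _, p in rows],
            },
            index=idx,
        )
    )


class TestFractions:
    @pytest.mark.parametrize(
        "m,p,thr,expected",
        [(5, 5, 1, 0.5), (10, 0, 1, 1.0), (1, 0, 3, np.nan)],
    )
    def test_fraction_rule(self, m, p, thr, expected):
        table = estimate_allelic_fractions(counts_table([("g1", "c1", m, p)]), thr)
        got = table.fraction("g1", "c1")
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_absent_gene_is_undefined_not_zero(self):
        table = estimate_allelic_fractions(counts_table([("g1", "c1", 5, 5)]), 1)
        assert np.isnan(table.fraction("g2", "c1"))


class TestSplit:
    def test_proportional_split(self):
        m = ExpressionMatrix(pd.DataFrame({"c1": [10.0]}, index=["g1"]))
        fr = estimate_allelic_fractions(counts_table([("g1", "c1", 7, 3)]), 1)
        split = split_expression(m, fr)
        assert split.maternal.loc["g1", "c1"] == 7.0
        assert split.paternal.loc["g1", "c1"] == 3.0

    def test_zero_total_splits_to_zero(self):
        m = ExpressionMatrix(pd.DataFrame({"c1": [0.0]}, index=["g1"]))
        fr = estimate_allelic_fractions(counts_table([("g1", "c1", 3, 1)]), 1)
        split = split_expression(m, fr)
        assert split.maternal.loc["g1", "c1"] == 0.0
        assert split.paternal.loc["g1", "c1"] == 0.0

    def test_conservation_is_bitwise_exact(self, sim_timecourse):
        ds, _ = sim_timecourse
        fr = estimate_allelic_fractions(ds.allele_counts, 3)
        split = split_expression(ds.matrix, fr)
        m = split.maternal.to_numpy()
        p = split.paternal.to_numpy()
        t = ds.matrix.values.to_numpy()
        defined = ~np.isnan(m)
        assert (m[defined] + p[defined] == t[defined]).all()
        assert (m[defined] >= 0).all() and (p[defined] >= 0).all()

    def test_undefined_fraction_propagates(self):
        m = ExpressionMatrix(pd.DataFrame({"c1": [10.0, 4.0]}, index=["g1", "g2"]))
        fr = estimate_allelic_fractions(counts_table([("g1", "c1", 7, 3)]), 1)
        split = split_expression(m, fr)
        assert np.isnan(split.maternal.loc["g2", "c1"])


class TestAllelicRatios:
    def test_balanced_biallelic_female_gives_half_per_allele(self, sim_timecourse):
        """4-cell-like cells (both X active, f ~ 0.5) put each allele near
        half the total X:AA."""
        ds, part = sim_timecourse
        fr = estimate_allelic_fractions(ds.allele_counts, 3)
        split = split_expression(ds.matrix, fr)
        meta = ds.matrix.sample_meta
        cells = meta.index[(meta["stage"] == "4cell") & (meta["sex"] == "female")]
        fcfg, bcfg = FilterConfig(cutoff=1.0), BootstrapConfig(seed=2)
        for cell in cells:
            em = allelic_xaa_ratio(split, ds.matrix, part, cell, "maternal", fcfg, bcfg)
            ep = allelic_xaa_ratio(split, ds.matrix, part, cell, "paternal", fcfg, bcfg)
            assert em.point == pytest.approx(0.5, abs=0.12)
            assert ep.point == pytest.approx(0.5, abs=0.12)

    def test_fully_maternal_x_moves_all_signal_to_maternal(self, sim_timecourse):
        """Male cells: Xp:AA identically 0, Xm:AA tracks the total X:AA."""
        ds, part = sim_timecourse
        fr = estimate_allelic_fractions(ds.allele_counts, 3)
        split = split_expression(ds.matrix, fr)
        meta = ds.matrix.sample_meta
        cell = meta.index[meta["sex"] == "male"][0]
        fcfg, bcfg = FilterConfig(cutoff=1.0), BootstrapConfig(seed=2)
        ep = allelic_xaa_ratio(split, ds.matrix, part, cell, "paternal", fcfg, bcfg)
        em = allelic_xaa_ratio(split, ds.matrix, part, cell, "maternal", fcfg, bcfg)
        assert ep.point == 0.0 and ep.ci_high == 0.0
        assert em.ci_low <= 1.0 <= em.ci_high

    def test_too_few_informative_x_genes_names_sample(self):
        genes = [f"x{i}" for i in range(30)] + [f"a{i}" for i in range(40)]
        m = ExpressionMatrix(pd.DataFrame({"c9": [2.0] * 70}, index=genes))
        from xaratio import GeneAnnotation

        ann = GeneAnnotation({g: ("chrX" if g.startswith("x") else "chr3") for g in genes})
        part = partition_genes(m, ann)
        fr = estimate_allelic_fractions(counts_table([("x0", "c9", 5, 5)]), 1)
        split = split_expression(m, fr)
        with pytest.raises(GroupSizeError, match="c9"):
            allelic_xaa_ratio(split, m, part, "c9", "maternal", FilterConfig(1.0), BootstrapConfig(seed=0))


class TestTimecourse:
    def test_monotone_silencing_recovered(self, sim_timecourse):
        """Xm:AA rises and Xp:AA falls across the silencing schedule of
        female cells; stage means track the generative truth."""
        ds, part = sim_timecourse
        fr = estimate_allelic_fractions(ds.allele_counts, 3)
        split = split_expression(ds.matrix, fr)
        summaries = stage_timecourse(
            ds.matrix, split, part, FilterConfig(cutoff=1.0), BootstrapConfig(seed=4)
        )
        fem = {s.stage: s for s in summaries if s.sex == "female"}
        stages = [st.name for st in ds.truth.schedule.stages]
        xm = [fem[s].means["Xm_AA"] for s in stages]
        xp = [fem[s].means["Xp_AA"] for s in stages]
        assert xm[0] < xm[1] < xm[2]
        assert xp[0] > xp[1] > xp[2]
        for s in stages:
            exp = ds.truth.expected[(s, "female")]
            assert fem[s].means["Xm_AA"] == pytest.approx(exp.xm_aa, abs=0.1)
            assert fem[s].means["Xp_AA"] == pytest.approx(exp.xp_aa, abs=0.1)

    def test_identical_cells_mean_equals_common_point(self):
        genes = [f"x{i}" for i in range(30)] + [f"a{i}" for i in range(40)]
        values = pd.DataFrame(
            {"c1": [2.0] * 30 + [4.0] * 40, "c2": [2.0] * 30 + [4.0] * 40}, index=genes
        )
        meta = pd.DataFrame(
            {"stage": ["s0", "s0"], "sex": ["female", "female"]}, index=["c1", "c2"]
        )
        m = ExpressionMatrix(values, sample_meta=meta)
        from xaratio import GeneAnnotation

        ann = GeneAnnotation({g: ("chrX" if g.startswith("x") else "chr3") for g in genes})
        part = partition_genes(m, ann)
        rows = [(g, c, 5, 5) for g in genes if g.startswith("x") for c in ["c1", "c2"]]
        fr = estimate_allelic_fractions(counts_table(rows), 1)
        split = split_expression(m, fr)
        summaries = stage_timecourse(m, split, part, FilterConfig(1.0), BootstrapConfig(seed=0))
        (s,) = summaries
        # constant inputs: every cell's point is exactly 2/4 = 0.5 total,
        # 0.25 per allele; the stage mean equals the common per-cell point
        assert s.means["XA_total"] == s.per_cell["XA_total"].iloc[0] == 0.5
        assert s.means["Xm_AA"] == 0.25 and s.means["Xp_AA"] == 0.25

    def test_long_format_row_count(self, sim_timecourse):
        ds, part = sim_timecourse
        fr = estimate_allelic_fractions(ds.allele_counts, 3)
        split = split_expression(ds.matrix, fr)
        summaries = stage_timecourse(
            ds.matrix, split, part, FilterConfig(cutoff=1.0), BootstrapConfig(seed=4)
        )
        frame = timecourse_frame(summaries)
        n_cells = ds.matrix.n_samples
        n_groups = len(summaries)
        assert len(frame) == (n_cells + n_groups) * 4
        assert set(frame["ratio_type"]) == {"XA_total", "Xm_AA", "Xp_AA", "X_fpkm_sum"}


class TestSnpCoverage:
    def test_full_and_empty_coverage(self, tiny_matrix):
        from xaratio import GeneAnnotation

        ann = GeneAnnotation({"g1": "chr1", "g2": "chr1", "g3": "chrX"})
        full = counts_table([(g, "s1", 2, 2) for g in tiny_matrix.gene_ids])
        cov = snp_coverage_by_chromosome(full, tiny_matrix, ann, cutoffs=[0.0])
        assert (cov["fraction_informative"] == 1.0).all()
        empty = counts_table([(g, "s1", 0, 0) for g in tiny_matrix.gene_ids])
        cov0 = snp_coverage_by_chromosome(empty, tiny_matrix, ann, cutoffs=[0.0])
        assert (cov0["fraction_informative"] == 0.0).all()

    def test_uniform_informative_probability_recovered(self, sim_timecourse):
        """Per-chromosome informative fractions sit inside a generous
        binomial band around the generative probability."""
        ds, _ = sim_timecourse
        prob = ds.truth.params.snp_informative_prob
        cov = snp_coverage_by_chromosome(
            ds.allele_counts, ds.matrix, ds.annotation, cutoffs=[1.0]
        )
        per_chrom = cov[cov["chromosome"] != "overall"]
        for _, row in per_chrom.iterrows():
            n = row["n_expressed"]
            half_width = 4 * np.sqrt(prob * (1 - prob) / n)
            assert abs(row["fraction_informative"] - prob) < half_width + 0.02
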