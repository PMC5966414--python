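"""Expression linkage: upregulated genes, random background, z-test."""

import math

import numpy as np
import pandas as pd
import pytest

from dmrpipe.annotation import GeneIndex
from dmrpipe.association import (
    dmr_gene_enrichment,
    proportion_ztest,
    random_segments,
    upregulated_genes,
    _hit_stats,
)
from dmrpipe.io import DmrCall, GeneModel, SampleInfo


def expr_design(reps=3):
    sheet = []
    for age in (1.0, 15.0):
        for r in range(reps):
            sheet.append(SampleInfo(f"e_{age:g}_{r}", "liver", age, "WT", f"r{r+1}"))
    return sheet


class TestUpregulatedGenes:
    def test_fold_and_significance_rule(self):
        sheet = expr_design()
        cols = [s.sample_id for s in sheet]
        expr = pd.DataFrame(
            [
                [10, 11, 9, 40, 41, 39],  # clear 4-fold increase
                [40, 41, 39, 10, 11, 9],  # decrease: excluded regardless of p
                [10, 10, 10, 11, 10, 11],  # too small a change
            ],
            index=["up", "down", "flat"],
            columns=cols,
        ).astype(float)
        got = upregulated_genes(expr, sheet)
        assert got == {"up"}

    def test_planted_up_genes_recovered(self):
        rng = np.random.default_rng(21)
        sheet = expr_design()
        n = 500
        base = rng.lognormal(3, 1, size=n)
        vals = []
        for s in sheet:
            noise = rng.lognormal(0, 0.1, size=n)
            fold = np.ones(n)
            if s.age_weeks == 15.0:
                fold[:50] = 3.0  # planted up-genes
            vals.append(base * fold * noise)
        expr = pd.DataFrame(
            np.column_stack(vals),
            index=[f"g{i}" for i in range(n)],
            columns=[s.sample_id for s in sheet],
        )
        got = upregulated_genes(expr, sheet)
        planted = {f"g{i}" for i in range(50)}
        assert len(got & planted) >= 45

    def test_de_table_takes_precedence(self):
        de = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2fc": [2.0, -2.0, 1.0],
                "p": [0.001, 0.001, 0.2],
                "significant": [True, True, False],
            }
        )
        got = upregulated_genes(pd.DataFrame(), [], de_table=de)
        assert got == {"a"}

    def test_missing_age_group_is_error(self):
        sheet = expr_design()
        expr = pd.DataFrame(
            np.ones((2, len(sheet))),
            index=["a", "b"],
            columns=[s.sample_id for s in sheet],
        )
        with pytest.raises(ValueError, match="age"):
            upregulated_genes(expr, sheet, age_from=1.0, age_to=3.0)


class TestRandomSegments:
    SIZES = {"chr1": 1_000_000, "chr2": 3_000_000}

    def test_zero_segments(self):
        assert random_segments(self.SIZES, 0, 100, 0) == []

    def test_fixed_seed_is_deterministic(self):
        a = random_segments(self.SIZES, 50, 100, 7)
        b = random_segments(self.SIZES, 50, 100, 7)
        assert a == b

    def test_lengths_respected_and_in_bounds(self):
        lengths = np.array([100, 250, 400])
        segs = random_segments(self.SIZES, 3, lengths, 1)
        for (c, s, e), L in zip(segs, lengths):
            assert e - s == L
            assert 0 <= s and e <= self.SIZES[c]

    def test_chromosome_weighting_by_length(self):
        segs = random_segments(self.SIZES, 10_000, 100, 3)
        n1 = sum(1 for c, _, _ in segs if c == "chr1")
        p = 1 / 4  # chr1 is a quarter of the toy genome
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(n1 / 10_000 - p) < 5 * se

    def test_exclusion_respected(self):
        exclude = [("chr1", 0, 1_000_000)]  # all of chr1
        segs = random_segments(self.SIZES, 200, 100, 5, exclude=exclude)
        assert all(c == "chr2" for c, _, _ in segs)

    def test_infeasible_exclusion_errors(self):
        exclude = [("chr1", 0, 1_000_000), ("chr2", 0, 3_000_000)]
        with pytest.raises(ValueError, match="segment"):
            random_segments(self.SIZES, 5, 100, 0, exclude=exclude)

    def test_segment_longer_than_chromosome_errors(self):
        with pytest.raises(ValueError):
            random_segments({"chr1": 1_000}, 1, 5_000, 0)


class TestProportionZtest:
    def test_equal_proportions_give_zero(self):
        z, p = proportion_ztest(30, 100, 15, 50)
        assert z == 0.0 and p == 1.0

    def test_formula_example(self):
        z, p = proportion_ztest(30, 100, 15, 100)
        pool = 45 / 200
        se = math.sqrt(pool * (1 - pool) * (1 / 100 + 1 / 100))
        assert z == pytest.approx((0.30 - 0.15) / se, rel=1e-12)

    def test_swapping_groups_negates_z(self):
        z1, p1 = proportion_ztest(30, 100, 15, 100)
        z2, p2 = proportion_ztest(15, 100, 30, 100)
        assert z1 == -z2 and p1 == p2

    def test_degenerate_pooled_proportions(self):
        assert proportion_ztest(0, 10, 0, 10) == (0.0, 1.0)
        z, p = proportion_ztest(10, 10, 10, 10)
        assert z == 0.0 and p == 1.0
        z, p = proportion_ztest(0, 10, 0, 5)
        assert z == 0.0

    def test_matches_statsmodels_on_random_tuples(self):
        from statsmodels.stats.proportion import proportions_ztest

        rng = np.random.default_rng(22)
        checked = 0
        while checked < 100:
            n1, n2 = rng.integers(2, 500, size=2)
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            if (k1 + k2) in (0, n1 + n2):
                continue
            z, p = proportion_ztest(k1, int(n1), k2, int(n2))
            z_sm, p_sm = proportions_ztest([k1, k2], [int(n1), int(n2)])
            assert z == pytest.approx(z_sm, rel=1e-12)
            assert p == pytest.approx(p_sm, rel=1e-12)
            checked += 1


def toy_world(rng, n_genes=40, chrom_len=400_000):
    genes = []
    for i in range(n_genes):
        start = i * 10_000 + 2_000
        genes.append(
            GeneModel(f"g{i:02d}", "chr1", "+", start, start + 5_000, start, start + 5_000)
        )
    return genes, {"chr1": chrom_len}


class TestEnrichment:
    def test_foreground_equals_background_under_identical_inputs(self):
        rng = np.random.default_rng(30)
        genes, sizes = toy_world(rng)
        index = GeneIndex(genes)
        up = {"g00", "g01", "g02"}
        intervals = [("chr1", int(s), int(s) + 200) for s in rng.integers(0, 390_000, 80)]
        k1, n1 = _hit_stats(intervals, index, up, "intragenic_plus_promoter", 50_000)
        k2, n2 = _hit_stats(intervals, index, up, "intragenic_plus_promoter", 50_000)
        assert (k1, n1) == (k2, n2)

    def test_uniform_dmrs_show_no_enrichment(self):
        genes, sizes = toy_world(None)
        up = {f"g{i:02d}" for i in range(8)}  # 20% of genes
        n_calm = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            dmrs = [
                DmrCall("chr1", int(s), int(s) + 200, "tissue_hypo", 5)
                for s in rng.integers(0, 390_000, 150)
            ]
            res = dmr_gene_enrichment(dmrs, genes, up, sizes, rng_seed=seed)
            if res.p_value > 0.05:
                n_calm += 1
        assert n_calm >= 16  # null: non-significant in the vast majority of runs

    def test_planted_enrichment_detected(self):
        genes, sizes = toy_world(None)
        rng = np.random.default_rng(31)
        up = {f"g{i:02d}" for i in range(4)}  # 10% of genes upregulated
        dmrs = []
        for i in range(600):
            if i < 200:  # a third of DMRs inside upregulated genes
                g = int(rng.integers(0, 4))
            else:
                g = int(rng.integers(8, 40))
            start = g * 10_000 + 3_000 + int(rng.integers(0, 3_000))
            dmrs.append(DmrCall("chr1", start, start + 200, "tissue_hypo", 5))
        res = dmr_gene_enrichment(dmrs, genes, up, sizes, rng_seed=5)
        assert res.z_stat > 0
        assert res.p_value < 1e-6

    def test_empty_dmr_set_is_error(self):
        genes, sizes = toy_world(None)
        with pytest.raises(ValueError, match="empty"):
            dmr_gene_enrichment([], genes, set(), sizes)
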