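"""DMR-caller rules: tissue specificity, per-tile test, postnatal timing."""

import math

import numpy as np
import pandas as pd
import pytest

from dmrpipe.calling import (
    DmrParams,
    call_postnatal,
    call_tissue_specific,
    tile_test,
    tissue_means,
)

from conftest import design, make_matrix

TISSUES = ["liver", "lung", "heart", "brain", "fat", "neutrophils",
           "hippocampus", "kidney", "spleen"]


def means_frame(target, others):
    """One-tile means table: target value + 8 comparison tissues."""
    data = {"liver": [target]}
    for t, v in zip(TISSUES[1:], others):
        data[t] = [v]
    return pd.DataFrame(data)


class TestTissueMeans:
    def test_replicates_average(self):
        sheet = design(["liver"], [15.0], 2)
        m = make_matrix([[40.0, 60.0]], sheet)
        assert tissue_means(m)["liver"].iloc[0] == 50.0

    def test_single_replicate_identity(self):
        sheet = design(["liver"], [15.0], 1)
        m = make_matrix([[73.0]], sheet)
        assert tissue_means(m)["liver"].iloc[0] == 73.0

    def test_groupby_oracle_on_random_fixture(self):
        rng = np.random.default_rng(11)
        sheet = design(TISSUES[:4], [1.0, 15.0], 2)
        pct = rng.uniform(0, 100, size=(20, len(sheet)))
        pct[rng.random(pct.shape) < 0.2] = np.nan
        m = make_matrix(pct, sheet)
        got = tissue_means(m, age_filter=15.0)
        df = pd.DataFrame(pct, columns=[s.sample_id for s in sheet])
        for t in TISSUES[:4]:
            cols = [s.sample_id for s in sheet if s.tissue == t and s.age_weeks == 15.0]
            expected = df[cols].mean(axis=1, skipna=True)
            pd.testing.assert_series_equal(
                got[t], expected, check_names=False, check_index=False
            )


class TestCallTissueSpecific:
    def test_seven_discriminating_tissues_called_hypo(self):
        means = means_frame(10, [70, 75, 80, 90, 65, 60, 58, 85])
        # enumeration: differences >= 50 for 7 of 8 comparison tissues
        res = call_tissue_specific(means, "liver", "hypo", DmrParams())
        assert len(res.calls) == 1 and res.calls[0].n_discriminating == 7

    def test_single_discriminating_tissue_not_called(self):
        means = means_frame(10, [55, 58, 45, 50, 40, 30, 20, 35])
        # only 60 >= delta+target once: 1 tissue differs by >= 50
        res = call_tissue_specific(means, "liver", "hypo", DmrParams())
        assert res.calls == []

    def test_flat_profile_called_in_neither_direction(self):
        means = means_frame(80, [80] * 8)
        for direction in ("hypo", "denovo"):
            assert call_tissue_specific(means, "liver", direction, DmrParams()).calls == []

    def test_inclusive_threshold(self):
        means = means_frame(10, [60] * 8)  # exactly 50 points in all 8
        res = call_tissue_specific(means, "liver", "hypo", DmrParams())
        assert len(res.calls) == 1 and res.calls[0].n_discriminating == 8

    def test_missing_target_tissue_is_error(self):
        means = means_frame(10, [70] * 8).drop(columns=["liver"])
        with pytest.raises(ValueError, match="target"):
            call_tissue_specific(means, "liver", "hypo", DmrParams())

    def test_sparse_tiles_reported_untestable(self):
        means = means_frame(10, [70, 75, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan])
        res = call_tissue_specific(means, "liver", "hypo", DmrParams())
        assert list(res.untestable_index) == [0]
        assert res.calls == []  # only 2 tissues with data

    def test_monotone_in_delta_specific(self, small_matrix):
        means = tissue_means(small_matrix, age_filter=15.0)
        counts = [
            len(call_tissue_specific(means, "liver", "hypo",
                                     DmrParams(delta_specific=d)).calls)
            for d in (20, 35, 50, 65, 80)
        ]
        assert counts == sorted(counts, reverse=True)


def fisher_oracle(m1, t1, m2, t2):
    """Two-sided Fisher p by brute-force hypergeometric enumeration."""
    n1, n2 = t1, t2
    k = m1 + m2

    def hyper(x):
        return math.comb(n1, x) * math.comb(n2, k - x)

    lo, hi = max(0, k - n2), min(k, n1)
    probs = {x: hyper(x) for x in range(lo, hi + 1)}
    total = sum(probs.values())
    p_obs = probs[m1]
    return sum(p for p in probs.values() if p <= p_obs) / total


class TestTileTest:
    def test_extreme_difference_is_tiny(self):
        assert tile_test((90, 100), (20, 100)) < 1e-15

    def test_identical_tables_give_one(self):
        assert tile_test((50, 100), (50, 100)) == 1.0

    def test_matches_hypergeometric_enumeration(self):
        assert tile_test((6, 10), (4, 10)) == pytest.approx(
            fisher_oracle(6, 10, 4, 10), rel=1e-12
        )

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            t1, t2 = rng.integers(1, 30, size=2)
            m1 = int(rng.integers(0, t1 + 1))
            m2 = int(rng.integers(0, t2 + 1))
            assert tile_test((m1, int(t1)), (m2, int(t2))) == pytest.approx(
                fisher_oracle(m1, int(t1), m2, int(t2)), rel=1e-9
            )

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            tile_test((0, 0), (5, 10))


class TestCallPostnatal:
    def _run(self, newborn, wk3, adult, total=400):
        """One liver tile through the full call path at the given age means."""
        tissues = TISSUES  # 9 tissues
        sheet = design(tissues, [1.0, 3.0, 15.0], 1)
        row = []
        for s in sheet:
            if s.tissue != "liver":
                row.append(90.0)
            else:
                row.append({1.0: newborn, 3.0: wk3, 15.0: adult}[s.age_weeks])
        m = make_matrix([row], sheet, total=total)
        means = tissue_means(m, age_filter=15.0)
        specific = call_tissue_specific(means, "liver", "hypo", DmrParams(), tiles=m.tiles)
        dmrs = call_postnatal(m, specific, "liver")
        return dmrs

    def test_still_methylated_at_boundary_is_late(self):
        (d,) = self._run(85, 80, 15)
        assert d.timing == "late_postnatal"
        assert d.delta_newborn_adult == pytest.approx(70.0)

    def test_demethylated_by_boundary_is_early(self):
        (d,) = self._run(85, 20, 15)
        assert d.timing == "early_postnatal"

    def test_already_unmethylated_newborn_is_prenatal(self):
        (d,) = self._run(3, 3, 2)
        assert d.timing == "prenatal"

    def test_small_delta_gets_no_timing(self):
        (d,) = self._run(40, 35, 15)  # 25 points < 35
        assert d.timing == "none"

    def test_insignificant_delta_gets_no_timing(self):
        # large delta but 3 reads total: Fisher cannot reach p < 0.05
        (d,) = self._run(100, 100, 0, total=3)
        assert d.timing == "none"

    def test_missing_boundary_age_flags_unknown(self):
        sheet = design(TISSUES, [1.0, 15.0], 1)
        row = [90.0 if s.tissue != "liver" else {1.0: 85.0, 15.0: 15.0}[s.age_weeks]
               for s in sheet]
        m = make_matrix([row], sheet, total=400)
        means = tissue_means(m, age_filter=15.0)
        specific = call_tissue_specific(means, "liver", "hypo", DmrParams(), tiles=m.tiles)
        (d,) = call_postnatal(m, specific, "liver")
        assert d.timing == "early_or_late_unknown"

    def test_missing_age_group_is_error(self):
        sheet = design(TISSUES, [15.0], 1)
        m = make_matrix([[10.0] + [90.0] * (len(sheet) - 1)], sheet)
        means = tissue_means(m, age_filter=15.0)
        specific = call_tissue_specific(means, "liver", "hypo", DmrParams(), tiles=m.tiles)
        with pytest.raises(ValueError, match="age"):
            call_postnatal(m, specific, "liver")

    def test_each_call_gets_exactly_one_timing_label(self, small_matrix):
        means = tissue_means(small_matrix, age_filter=15.0)
        specific = call_tissue_specific(
            means, "liver", "hypo", DmrParams(), tiles=small_matrix.tiles
        )
        dmrs = call_postnatal(small_matrix, specific, "liver")
        labels = {"prenatal", "early_postnatal", "late_postnatal",
                  "early_or_late_unknown", "none"}
        assert len(dmrs) == len(specific.calls)
        assert all(d.timing in labels for d in dmrs)


class TestDirectionSymmetry:
    def test_flipping_methylation_maps_hypo_to_denovo(self, small_matrix):
        import dataclasses

        m = small_matrix
        flipped = dataclasses.replace(
            m, pct=100.0 - m.pct, meth=np.where(m.mask, m.total - m.meth, 0)
        )
        params = DmrParams()
        means = tissue_means(m, age_filter=15.0)
        means_f = tissue_means(flipped, age_filter=15.0)
        hypo = call_tissue_specific(means, "liver", "hypo", params, tiles=m.tiles)
        denovo_f = call_tissue_specific(means_f, "liver", "denovo", params, tiles=m.tiles)
        np.testing.assert_array_equal(hypo.called_index, denovo_f.called_index)
        np.testing.assert_array_equal(hypo.n_discriminating, denovo_f.n_discriminating)


class TestRecovery:
    def test_planted_hypo_tiles_recovered_with_low_false_calls(self, small_sim, small_matrix):
        truth = small_sim.truth.tiles
        planted = set(
            truth.loc[truth["cls"].isin(["prenatal", "early", "late"]), "tile_id"]
        )
        means = tissue_means(small_matrix, age_filter=15.0)
        res = call_tissue_specific(
            means, "liver", "hypo", DmrParams(), tiles=small_matrix.tiles
        )
        # matrix rows map to truth tiles via (chrom, start)
        key = dict(zip(zip(truth["chrom"], truth["start"]), truth["tile_id"]))
        called_ids = {
            key[(small_matrix.tiles["chrom"].iat[i], small_matrix.tiles["start"].iat[i])]
            for i in res.called_index
        }
        tp = len(called_ids & planted)
        sensitivity = tp / len(planted)
        false_calls = len(called_ids - planted)
        null_tiles = len(truth) - len(planted)
        assert sensitivity >= 0.9
        assert false_calls / null_tiles <= 0.01
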