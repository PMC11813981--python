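import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thalcon.group_inference import (
    behavior_correlation,
    chi_square_2x2,
    cr_mf,
    demographics_table,
    perm_cluster_fwe,
    roi_pair_contrast,
    sensory_subgroup_compare,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_computed_pooled(self):
        # pooled variance 1, mean difference -3: t = -3 / sqrt(2/3)
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == 4

    def test_matches_exact_permutation_oracle(self, rng):
        a = rng.standard_normal(4)
        b = rng.standard_normal(4) + 0.5
        res = two_sample_t(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            sel = np.zeros(8, bool)
            sel[list(combo)] = True
            count += abs(pooled[sel].mean() - pooled[~sel].mean()) >= obs - 1e-12
            total += 1
        p_perm = count / total
        assert res.p == pytest.approx(p_perm, abs=0.15)

    def test_sign_flips_on_group_exchange(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 1
        r1, r2 = two_sample_t(a, b), two_sample_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_zero_variance_unequal_means(self):
        with pytest.raises(ValueError, match="zero variance"):
            two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_welch_variant(self, rng):
        from scipy import stats

        a, b = rng.standard_normal(10), 3 * rng.standard_normal(15)
        res = two_sample_t(a, b, variant="welch")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic)


class TestRoiPairContrast:
    @staticmethod
    def _table(rng, delta=0.0, n_pat=39, n_ctl=64):
        rows = []
        for side in ("left", "right"):
            for roi in ("prefrontal", "motor", "temporal", "posterior_parietal",
                        "somatosensory", "occipital"):
                d = delta if roi == "somatosensory" else 0.0
                for i in range(n_pat):
                    rows.append({"group": "patient", "side": side, "roi": roi,
                                 "z": 0.9 + d + rng.normal(0, 0.22)})
                for i in range(n_ctl):
                    rows.append({"group": "control", "side": side, "roi": roi,
                                 "z": 0.9 + rng.normal(0, 0.22)})
        return pd.DataFrame(rows)

    def test_twelve_tests(self, rng):
        out = roi_pair_contrast(self._table(rng))
        assert len(out) == 12

    def test_power_with_planted_effect(self):
        """Planted |dz| = 0.3 at n = 39/64 is detected with the right sign
        in >= 90% of replicates."""
        hits = 0
        reps = 50
        for i in range(reps):
            rng = np.random.default_rng(10_000 + i)
            out = roi_pair_contrast(self._table(rng, delta=-0.3))
            row = out[(out["side"] == "right") & (out["roi"] == "somatosensory")]
            hits += bool(row["significant"].item() and row["t"].item() < 0)
        assert hits >= 0.9 * reps

    def test_null_calibration(self):
        """Type-I rate of the prefrontal test stays in the 2-9% band."""
        reps = 400
        rejections = 0
        for i in range(reps):
            rng = np.random.default_rng(50_000 + i)
            out = roi_pair_contrast(self._table(rng, delta=0.0))
            row = out[(out["side"] == "left") & (out["roi"] == "prefrontal")]
            rejections += bool(row["significant"].item())
        assert 0.02 <= rejections / reps <= 0.09

    def test_deterministic(self):
        rng1, rng2 = np.random.default_rng(7), np.random.default_rng(7)
        out1 = roi_pair_contrast(self._table(rng1))
        out2 = roi_pair_contrast(self._table(rng2))
        pd.testing.assert_frame_equal(out1, out2)

    def test_fdr_column(self, rng):
        out = roi_pair_contrast(self._table(rng), fdr=True)
        assert "p_fdr" in out.columns
        assert (out["p_fdr"] >= out["p"] - 1e-12).all()


class TestPermClusterFwe:
    @staticmethod
    def _null_maps(rng, n=8, shape=(10, 10, 10)):
        return rng.standard_normal((n, *shape))

    def test_p_lower_bound_attained(self, rng):
        """A huge planted effect: no permutation beats the observed extent,
        so corrected p equals 1 / (1 + n_perm)."""
        shape = (10, 10, 10)
        a = self._null_maps(rng, 10, shape)
        b = self._null_maps(rng, 10, shape)
        a[:, 2:6, 2:6, 2:6] += 5.0
        res = perm_cluster_fwe(a, b, np.ones(shape, bool), np.eye(4),
                               n_perm=199, seed=1)
        top = res.clusters[0]
        assert top.extent >= 4 ** 3
        assert top.p_corr == pytest.approx(1 / 200)
        assert top.contrast == "a>b"

    def test_p_monotone_in_extent(self, rng):
        shape = (12, 12, 12)
        a = self._null_maps(rng, 10, shape)
        b = self._null_maps(rng, 10, shape)
        a[:, 1:5, 1:5, 1:5] += 4.0
        a[:, 8:10, 8:10, 8:10] += 4.0
        res = perm_cluster_fwe(a, b, np.ones(shape, bool), np.eye(4),
                               n_perm=99, seed=2)
        extents = [c.extent for c in res.clusters]
        ps = [c.p_corr for c in res.clusters]
        for (e1, p1), (e2, p2) in itertools.combinations(zip(extents, ps), 2):
            if e1 > e2:
                assert p1 <= p2
            elif e2 > e1:
                assert p2 <= p1

    def test_peak_coordinates_in_world_mm(self, rng):
        shape = (10, 10, 10)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = -9.0
        a = self._null_maps(rng, 8, shape)
        b = self._null_maps(rng, 8, shape)
        a[:, 4, 5, 6] += 6.0
        a[:, 3:6, 4:7, 5:8] += 2.5
        res = perm_cluster_fwe(a, b, np.ones(shape, bool), affine,
                               n_perm=99, seed=3)
        top = res.clusters[0]
        expected = affine @ np.array([4, 5, 6, 1.0])
        assert top.peak_mm == pytest.approx(tuple(expected[:3]))

    def test_planted_block_recovered(self):
        """Power: the planted block is the top significant cluster."""
        shape = (12, 12, 12)
        hits = 0
        for i in range(10):
            rng = np.random.default_rng(300 + i)
            a = self._null_maps(rng, 10, shape)
            b = self._null_maps(rng, 10, shape)
            b[:, 3:7, 3:7, 3:7] += 2.0  # strong focal delta
            res = perm_cluster_fwe(a, b, np.ones(shape, bool), np.eye(4),
                                   n_perm=199, seed=i)
            sig = res.significant(0.05)
            if sig and sig[0].contrast == "b>a":
                i0, j0, k0 = sig[0].peak_mm
                if 3 <= i0 < 7 and 3 <= j0 < 7 and 3 <= k0 < 7:
                    hits += 1
        assert hits >= 9

    def test_exact_enumeration_small_n(self, rng):
        a = self._null_maps(rng, 5, (6, 6, 6))
        b = self._null_maps(rng, 5, (6, 6, 6))
        a += 0.0
        res = perm_cluster_fwe(a, b, np.ones((6, 6, 6), bool), np.eye(4),
                               n_perm=1000, seed=0)
        assert res.exact
        assert res.n_perm == 252  # C(10, 5)

    def test_too_few_maps(self, rng):
        a = self._null_maps(rng, 4)
        b = self._null_maps(rng, 8)
        with pytest.raises(ValueError, match="at least 5"):
            perm_cluster_fwe(a, b, np.ones((10, 10, 10), bool), np.eye(4))

    def test_low_n_perm_warns(self, rng):
        a = self._null_maps(rng, 8)
        b = self._null_maps(rng, 8)
        with pytest.warns(UserWarning, match="n_perm"):
            perm_cluster_fwe(a, b, np.ones((10, 10, 10), bool), np.eye(4),
                             n_perm=50, seed=0)


class TestCrMf:
    def test_table_group_means(self):
        # direct evaluation on the cohort-level group means (52.7, 22.6)
        assert cr_mf(52.7, 22.6) == pytest.approx(0.39973, abs=1e-5)

    def test_equal_scores_zero(self):
        assert cr_mf(31.0, 31.0) == 0.0

    def test_bound_attained(self):
        assert cr_mf(66.0, 0.0) == 1.0

    def test_undefined_when_both_zero(self):
        assert np.isnan(cr_mf(0.0, 0.0))

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            cr_mf(-1.0, 5.0)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(0, 66), b=st.floats(0, 66))
    def test_antisymmetric(self, a, b):
        if a + b > 0:
            assert cr_mf(a, b) == pytest.approx(-cr_mf(b, a), abs=1e-12)
            assert -1.0 <= cr_mf(a, b) <= 1.0


class TestBehaviorCorrelation:
    def test_perfect_linear_pearson(self, rng):
        x = rng.standard_normal(30)
        res = behavior_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.method == "pearson"

    def test_spearman_branch_equals_rank_pearson(self, rng):
        from scipy import stats

        x = np.exp(rng.standard_normal(40) * 2)  # heavily skewed
        y = x ** 2 + rng.standard_normal(40) * 0.1
        res = behavior_correlation(x, y)
        assert res.method == "spearman"
        rank_r = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert res.r == pytest.approx(rank_r, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            behavior_correlation(np.ones(10), np.arange(10.0))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            behavior_correlation([1.0, 2.0], [1.0, 2.0])

    def test_nan_pairs_dropped(self, rng):
        x = rng.standard_normal(20)
        y = x + rng.normal(0, 0.1, 20)
        x[3] = np.nan
        res = behavior_correlation(x, y)
        assert res.n == 19


class TestSensorySubgroup:
    def test_all_nonimpaired_rejected(self, rng):
        z = rng.standard_normal(10)
        with pytest.raises(ValueError, match="subgroup too small"):
            sensory_subgroup_compare(z, z, np.zeros(10))

    def test_power_with_planted_gap(self):
        """Planted d = 1.3 on both measures, n = 19/20: both tests
        significant in >= 90% of replicates (scalar-level oracle).

        Note d = 1.0 cannot reach 90%: the noncentral-t power of a single
        two-sided test at alpha 0.05 is only ~0.86 there (ncp 3.12), so the
        joint rate tops out near 0.73; d = 1.3 gives ~0.97 per test.
        """
        hits = 0
        reps = 50
        for i in range(reps):
            rng = np.random.default_rng(777 + i)
            sens = np.array([1] * 19 + [0] * 20)
            z = rng.normal(0, 1, 39) - 1.3 * sens
            fma = rng.normal(50, 10, 39) - 13.0 * sens
            res = sensory_subgroup_compare(z, fma, sens)
            hits += (res["connectivity"].p < 0.05 and res["fma"].p < 0.05)
        assert hits >= 0.9 * reps

    def test_default_plan_sizes(self, truth24):
        from thalcon.synthetic_cohort import plan_cohort

        plan = plan_cohort(truth24, seed=0)
        flags = [plan.impaired[r.subject_id] for r in plan.patients]
        assert (sum(flags), len(flags) - sum(flags)) == (19, 20)
        # the manifest's sensory item matches the planted flags
        for rec in plan.patients:
            assert (rec.nihss_sensory_t1 > 0) == plan.impaired[rec.subject_id]


class TestChiSquare:
    @pytest.mark.parametrize("a,b,c,d,expected", [
        (29, 10, 24, 8, 0.004),   # male split
        (17, 22, 9, 23, 1.811),   # smoker split
        (27, 12, 19, 13, 0.748),  # hypertension
        (13, 26, 6, 26, 1.907),   # diabetes
        (22, 17, 14, 18, 1.127),  # dyslipidemia
    ])
    def test_reference_tables(self, a, b, c, d, expected):
        chi2, p, df = chi_square_2x2(a, b, c, d)
        assert round(chi2, 3) == expected
        assert df == 1

    def test_independence_gives_zero(self):
        chi2, p, _ = chi_square_2x2(10, 20, 5, 10)  # ad == bc
        assert chi2 == 0.0 and p == 1.0

    def test_row_and_column_swap_invariance(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(1, 50, 4)
            chi2, *_ = chi_square_2x2(a, b, c, d)
            swapped, *_ = chi_square_2x2(d, c, b, a)
            assert chi2 == pytest.approx(swapped, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            chi_square_2x2(0, 0, 5, 5)


class TestDemographics:
    def test_synthetic_manifest_smoke(self, truth24):
        from thalcon.core_io import records_to_frame
        from thalcon.synthetic_cohort import plan_cohort

        plan = plan_cohort(truth24, seed=1)
        table = demographics_table(records_to_frame(plan.records))
        assert set(table["variable"]) == {"age", "bmi", "mmse", "male", "smoke",
                                          "hypertension", "diabetes",
                                          "dyslipidemia"}
        assert np.isfinite(table["statistic"]).all()
        assert np.isfinite(table["p"]).all()

    def test_identical_binary_trait_gives_zero(self):
        df = pd.DataFrame({
            "group": ["patient"] * 4 + ["control"] * 4,
            "male": [1, 0, 1, 0, 1, 0, 1, 0],
            "age": [50, 60, 55, 65, 52, 58, 54, 66],
        })
        table = demographics_table(df)
        male = table[table["variable"] == "male"]
        assert male["statistic"].item() == 0.0
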