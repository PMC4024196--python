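"""Voxel-wise GLM: design, contrasts, permutation FWE, ROI summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mpmaging as m
from mpmaging.glm import (build_design, fit_voxelwise, t_contrast, f_contrast,
                          fwe_correct, roi_slope_summary,
                          roi_difference_age_test)


def make_manifest(n=40, seed=0):
    cov = m.sample_covariates(m.CohortSpec(n_subjects=n), seed)
    rng = np.random.default_rng(seed + 1)
    cov["tiv_mm3"] = 1_400_000 + rng.normal(0, 60_000, n)
    return cov


@pytest.fixture(scope="module")
def design():
    return build_design(make_manifest())


class TestBuildDesign:
    def test_cohort_of_138_gives_138_by_5(self):
        d = build_design(make_manifest(138))
        assert d.matrix.shape == (138, 5)
        assert d.columns == ("intercept", "age", "sex", "tiv", "scanner")

    def test_single_sex_cohort_raises_rank_error(self):
        man = make_manifest(20)
        man["sex"] = "F"
        with pytest.raises(ValueError, match="rank"):
            build_design(man)

    def test_row_permutation_permutes_design_rows(self):
        man = make_manifest(15)
        d = build_design(man)
        perm = np.random.default_rng(0).permutation(15)
        d_perm = build_design(man.iloc[perm].reset_index(drop=True))
        assert np.allclose(d_perm.matrix, d.matrix[perm])

    def test_missing_covariate_rejected(self):
        man = make_manifest(10).drop(columns=["scanner"])
        with pytest.raises(ValueError, match="scanner"):
            build_design(man)

    def test_centered_codings(self, design):
        assert set(np.unique(design.matrix[:, design.column_index("sex")])) == \
            {-0.5, 0.5}
        assert set(np.unique(design.matrix[:, design.column_index("scanner")])) == \
            {-0.5, 0.5}


class TestFitVoxelwise:
    def test_exact_recovery_of_noiseless_betas(self, design, rng):
        b = rng.normal(size=(5, 50))
        y = design.matrix @ b
        fit = fit_voxelwise(y, design)
        assert np.allclose(fit.beta, b, atol=1e-8)
        assert np.all(fit.zero_variance)

    def test_constant_shift_moves_only_intercept(self, design, rng):
        y = rng.normal(size=(design.matrix.shape[0], 30))
        f0 = fit_voxelwise(y, design)
        f1 = fit_voxelwise(y + 10.0, design)
        assert np.allclose(f1.beta[0], f0.beta[0] + 10.0)
        assert np.allclose(f1.beta[1:], f0.beta[1:], atol=1e-10)

    def test_zero_noise_cohort_age_slope_recovered_exactly(self, geometry24,
                                                           zero_noise_aging):
        """Generator round trip without acquisition noise: regressing the
        ground-truth genu MT means on the design recovers the configured
        slope to 1e-8."""
        spec = m.CohortSpec(n_subjects=20)
        cov = make_manifest(20, seed=3)
        vals = []
        for _, row in cov.iterrows():
            sub = m.sample_subject(spec, zero_noise_aging, geometry24,
                                   row["age"], row["sex"], int(row["scanner"]),
                                   np.random.default_rng(0))
            vals.append(sub.maps["mt_sat"][geometry24.roi_mask("genu")].mean())
        d = build_design(cov)
        fit = fit_voxelwise(np.asarray(vals)[:, None], d)
        truth = zero_noise_aging.rois["genu"].slope.mt_sat
        assert fit.beta[d.column_index("age"), 0] == pytest.approx(truth,
                                                                   abs=1e-8)

    def test_statsmodels_agreement_on_single_voxel(self, design, rng):
        import statsmodels.api as sm

        y = rng.normal(size=(design.matrix.shape[0], 1))
        fit = fit_voxelwise(y, design)
        res = sm.OLS(y[:, 0], design.matrix).fit()
        assert np.allclose(fit.beta[:, 0], res.params, atol=1e-10)
        t_mine = t_contrast(fit, design.contrast("age"), tail="two")
        assert t_mine.stat[0] == pytest.approx(res.tvalues[1], abs=1e-10)
        assert t_mine.p_uncorrected[0] == pytest.approx(res.pvalues[1],
                                                        abs=1e-12)


class TestContrasts:
    def test_null_t_mean_zero_and_p_uniform(self, design, rng):
        y = rng.normal(size=(design.matrix.shape[0], 4000))
        res = t_contrast(fit_voxelwise(y, design), design.contrast("age"),
                         tail="two")
        assert abs(res.stat.mean()) < 0.05
        ks = stats.kstest(res.p_uncorrected, "uniform")
        assert ks.pvalue > 0.01

    def test_sign_flip_negates_t(self, design, rng):
        y = rng.normal(size=(design.matrix.shape[0], 20))
        fit = fit_voxelwise(y, design)
        t_pos = t_contrast(fit, design.contrast("age"), tail="two")
        t_neg = t_contrast(fit, design.contrast("age", -1.0), tail="two")
        assert np.allclose(t_neg.stat, -t_pos.stat)

    def test_two_tailed_p_from_one_tailed(self, design, rng):
        y = rng.normal(size=(design.matrix.shape[0], 50))
        fit = fit_voxelwise(y, design)
        c = design.contrast("age")
        one = t_contrast(fit, c, tail="one-neg").p_uncorrected
        two = t_contrast(fit, c, tail="two").p_uncorrected
        assert np.allclose(two, 2 * np.minimum(one, 1 - one), atol=1e-12)

    def test_t_invariant_to_covariate_rescaling(self, rng):
        man = make_manifest(30, seed=5)
        d1 = build_design(man)
        man2 = man.copy()
        man2["tiv_mm3"] = man2["tiv_mm3"] / 1000.0  # litres instead of mm^3
        d2 = build_design(man2)
        y = rng.normal(size=(30, 25))
        r1 = t_contrast(fit_voxelwise(y, d1), d1.contrast("age"), tail="two")
        r2 = t_contrast(fit_voxelwise(y, d2), d2.contrast("age"), tail="two")
        assert np.allclose(r1.stat, r2.stat, atol=1e-8)

    def test_single_row_f_equals_t_squared(self, design, rng):
        y = rng.normal(size=(design.matrix.shape[0], 30))
        fit = fit_voxelwise(y, design)
        c = design.contrast("scanner")
        t_res = t_contrast(fit, c, tail="two")
        f_res = f_contrast(fit, c[None, :])
        assert np.allclose(f_res.stat, t_res.stat**2, rtol=1e-10)
        assert np.allclose(f_res.p_uncorrected, t_res.p_uncorrected, rtol=1e-8)

    def test_null_scanner_f_type_one_error_near_nominal(self):
        rng = np.random.default_rng(11)
        man = make_manifest(24, seed=7)
        d = build_design(man)
        c = d.contrast("scanner")[None, :]
        rejections = []
        for _ in range(400):
            y = rng.normal(size=(24, 1))
            res = f_contrast(fit_voxelwise(y, d), c)
            rejections.append(res.p_uncorrected[0] < 0.05)
        rate = np.mean(rejections)
        assert 0.02 < rate < 0.085  # binomial 95% band around 0.05, n=400

    def test_injected_scanner_effect_detected(self, rng):
        man = make_manifest(138, seed=9)
        d = build_design(man)
        scanner = d.matrix[:, d.column_index("scanner")]
        y = rng.normal(0, 0.01, (138, 1)) + 0.01 * scanner[:, None]
        res = f_contrast(fit_voxelwise(y, d), d.contrast("scanner")[None, :])
        assert res.p_uncorrected[0] < 0.01

    def test_dependent_contrast_rows_rejected(self, design, rng):
        y = rng.normal(size=(design.matrix.shape[0], 5))
        fit = fit_voxelwise(y, design)
        c = np.vstack([design.contrast("age"), 2 * design.contrast("age")])
        with pytest.raises(ValueError):
            f_contrast(fit, c)


class TestFWE:
    def test_single_voxel_maxt_matches_uncorrected(self, rng):
        man = make_manifest(30, seed=2)
        d = build_design(man)
        age = d.matrix[:, 1]
        y = (0.05 * age + rng.normal(0, 1.0, 30))[:, None]
        res = fwe_correct(y, d, d.contrast("age"), tail="two", n_perm=999,
                          rng=rng)
        assert res.p_fwe[0] == pytest.approx(res.p_uncorrected[0], abs=0.03)

    def test_bonferroni_dominates_maxt_under_spatial_correlation(self, rng):
        man = make_manifest(30, seed=4)
        d = build_design(man)
        base = rng.normal(size=(30, 6))
        # strongly correlated voxels: shared signal + small idiosyncratic noise
        y = np.repeat(base, 40, axis=1) + rng.normal(0, 0.1, (30, 240))
        c = d.contrast("age")
        maxt = fwe_correct(y, d, c, tail="two", n_perm=499, rng=rng)
        bonf = fwe_correct(y, d, c, tail="two", method="bonferroni")
        ok = np.isfinite(maxt.p_fwe)
        assert np.all(bonf.p_fwe[ok] >= maxt.p_fwe[ok] - 0.02)

    def test_fwe_adjusted_p_never_below_uncorrected(self, rng):
        man = make_manifest(25, seed=6)
        d = build_design(man)
        y = rng.normal(size=(25, 100))
        res = fwe_correct(y, d, d.contrast("age"), tail="one-neg", n_perm=199,
                          rng=rng)
        assert np.all(res.p_fwe >= res.p_uncorrected - 1e-12)

    def test_strong_effect_survives_fwe(self, rng):
        man = make_manifest(60, seed=8)
        d = build_design(man)
        age = d.matrix[:, 1]
        y = rng.normal(0, 1.0, (60, 50))
        y[:, 7] += 0.5 * (age - age.mean())  # huge age effect in one voxel
        res = fwe_correct(y, d, d.contrast("age"), tail="two", n_perm=499,
                          rng=rng, alpha=0.05)
        assert res.significant[7]
        assert res.significant.sum() <= 3

    def test_too_few_permutations_rejected(self, design, rng):
        y = rng.normal(size=(design.matrix.shape[0], 5))
        with pytest.raises(ValueError):
            fwe_correct(y, design, design.contrast("age"), n_perm=50, rng=rng)


class TestROISummaries:
    def test_single_roi_effect_localized(self, geometry24):
        slope = np.zeros(geometry24.shape)
        genu = geometry24.roi_mask("genu")
        slope[genu] = -0.002
        sig = genu.copy()
        table = roi_slope_summary(slope, geometry24.roi_volume,
                                  geometry24.roi_table, significant_mask=sig)
        nonzero = table[table["n_voxels"] > 0]
        assert list(nonzero["roi"]) == ["genu"]
        assert nonzero["mean_slope"].iloc[0] == pytest.approx(-0.002)

    def test_empty_roi_reported_with_zero_count(self, geometry24):
        slope = np.full(geometry24.shape, np.nan)
        table = roi_slope_summary(slope, geometry24.roi_volume,
                                  geometry24.roi_table)
        assert (table["n_voxels"] == 0).all()
        assert table["mean_slope"].isna().all()

    def test_roi_rate_difference_detected(self):
        """Paired-difference age regression separates two ROIs aging at
        different configured rates."""
        rng = np.random.default_rng(0)
        ages = rng.uniform(19, 75, 138)
        genu = 2.1 - 0.0019 * (ages - 46.6) + rng.normal(0, 0.02, 138)
        splen = 2.2 - 0.0005 * (ages - 46.6) + rng.normal(0, 0.02, 138)
        diff_slope, t, p = roi_difference_age_test(genu, splen, ages)
        assert diff_slope == pytest.approx(-0.0014, abs=5e-4)
        assert p < 0.01

    def test_no_rate_difference_gives_large_p(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(19, 75, 100)
        a = 2.0 - 0.001 * ages + rng.normal(0, 0.05, 100)
        b = 1.5 - 0.001 * ages + rng.normal(0, 0.05, 100)
        _, _, p = roi_difference_age_test(a, b, ages)
        assert p > 0.05
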