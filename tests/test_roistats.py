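import dataclasses

import numpy as np
import pytest
import scipy.stats

from rehoscope import (BoldSeries, DegenerateDataError, DesignError,
                       ancova_group_effect, bonferroni_gate, extract_roi_means,
                       gm_index, mean_t2star_map, partial_correlation,
                       pearson_correlation, simulate_cohort, total_gm_volume,
                       two_sample_scalar_test)

AFF = np.diag([3.0, 3.0, 3.0, 1.0])


class TestRoiMeans:
    def test_constant_map(self):
        roi = np.zeros((4, 4, 4), bool)
        roi[1:3, 1:3, 1:3] = True
        maps = [np.full((4, 4, 4), 1.3)]
        assert extract_roi_means(maps, roi)[0] == pytest.approx(1.3)

    def test_two_voxel_average_and_single_voxel(self):
        m = np.zeros((4, 4, 4))
        m[0, 0, 0] = 0.8
        m[0, 0, 1] = 1.2
        roi2 = np.zeros((4, 4, 4), bool)
        roi2[0, 0, :2] = True
        assert extract_roi_means([m], roi2)[0] == pytest.approx(1.0)
        roi1 = np.zeros((4, 4, 4), bool)
        roi1[0, 0, 1] = True
        assert extract_roi_means([m], roi1)[0] == pytest.approx(1.2)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            extract_roi_means([np.zeros((4, 4, 4))], np.zeros((4, 4, 4), bool))


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        r, p, n = pearson_correlation(x, y)
        cx, cy = x - x.mean(), y - y.mean()
        oracle = (cx @ cy) / np.sqrt((cx @ cx) * (cy @ cy))
        assert r == pytest.approx(oracle, abs=1e-12)
        assert n == 4

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_correlation(np.ones(5), np.arange(5.0))


class TestBonferroni:
    def test_family_of_two_boundary_cases(self):
        # p=0.024 clears 0.05/2, p=0.038 does not
        assert bonferroni_gate([0.024, 0.038], 2, 0.05) == [True, False]

    def test_strict_inequality_at_the_limit(self):
        assert bonferroni_gate([0.05], 1, 0.05) == [False]


class TestGmIndex:
    def test_fraction_arithmetic(self):
        gm = np.ones((10, 10, 10))
        roi = np.zeros((10, 10, 10), bool)
        roi.flat[:100] = True
        # 100 voxels of 27 mm^3 against 1,350,000 mm^3 total
        assert gm_index(gm, roi, 1_350_000.0, 27.0) == pytest.approx(0.002)

    def test_zero_gm_in_roi(self):
        gm = np.ones((5, 5, 5))
        roi = np.zeros((5, 5, 5), bool)
        roi[0, 0, 0] = True
        gm[0, 0, 0] = 0.0
        assert gm_index(gm, roi, 1000.0, 27.0) == 0.0

    def test_linearity_in_roi_values(self, rng):
        gm = rng.random((6, 6, 6))
        roi = np.zeros((6, 6, 6), bool)
        roi[2:4, 2:4, 2:4] = True
        full = gm_index(gm, roi, 5000.0, 27.0)
        gm2 = gm.copy()
        gm2[roi] *= 0.5
        assert gm_index(gm2, roi, 5000.0, 27.0) == pytest.approx(full / 2)

    def test_total_volume_and_binarize(self):
        gm = np.full((4, 4, 4), 0.6)
        assert total_gm_volume(gm, 27.0) == pytest.approx(64 * 0.6 * 27)
        assert total_gm_volume(gm, 27.0, binarize=True) == pytest.approx(64 * 27)


class TestAncova:
    def test_zero_variance_covariate_reduces_to_one_way_f(self, rng):
        y = rng.standard_normal(20) + np.r_[np.ones(10), np.zeros(10)]
        g = np.r_[np.ones(10), np.zeros(10)]
        f, p = ancova_group_effect(y, g, np.full(20, 3.0))
        t, _ = two_sample_scalar_test(y[:10], y[10:])
        # one-way F at (1, N-3) equals t^2 of the pooled two-sample t
        assert f == pytest.approx(t ** 2, abs=1e-8)

    def test_constant_outcome_gives_zero_f(self):
        g = np.r_[np.ones(5), np.zeros(5)]
        f, p = ancova_group_effect(np.ones(10), g, np.arange(10.0))
        assert f == 0.0

    def test_covariate_equal_to_outcome_absorbs_group_effect(self, rng):
        g = np.r_[np.ones(10), np.zeros(10)]
        y = rng.standard_normal(20) + 2 * g
        f, _ = ancova_group_effect(y, g, y)
        assert f == pytest.approx(0.0, abs=1e-6)

    def test_group_collinear_covariate_rejected(self):
        g = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(DesignError):
            ancova_group_effect(np.arange(10.0), g, g)

    def test_matches_scipy_f_distribution_p(self, rng):
        g = np.r_[np.ones(15), np.zeros(15)]
        y = rng.standard_normal(30) + 0.8 * g
        z = rng.standard_normal(30)
        f, p = ancova_group_effect(y, g, z)
        assert p == pytest.approx(scipy.stats.f.sf(f, 1, 27), abs=1e-12)


class TestPartialCorrelation:
    def test_zero_covariate_equals_plain_pearson(self, rng):
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        r_plain = pearson_correlation(x, y)[0]
        r_part, _ = partial_correlation(x, y, np.zeros(20))
        assert r_part == pytest.approx(r_plain, abs=1e-12)

    def test_y_equal_to_z_gives_zero(self, rng):
        x = rng.standard_normal(15)
        z = rng.standard_normal(15)
        r, _ = partial_correlation(x, z, z)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_matches_residual_oracle(self, rng):
        x, y, z = rng.standard_normal((3, 20))
        r, p = partial_correlation(x, y, z)

        def resid(v):
            a = np.column_stack([np.ones(20), z])
            return v - a @ np.linalg.lstsq(a, v, rcond=None)[0]

        oracle = np.corrcoef(resid(x), resid(y))[0, 1]
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_affine_rescaling_of_z(self, rng):
        x, y, z = rng.standard_normal((3, 25))
        r1, p1 = partial_correlation(x, y, z)
        r2, p2 = partial_correlation(x, y, 5.0 * z - 3.0)
        assert r1 == pytest.approx(r2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)


class TestMeanVolumeMap:
    def _bold(self, data):
        return BoldSeries(data=data, affine=AFF, tr=2.0)

    def test_identical_volumes_reproduced(self, rng):
        v = rng.standard_normal((4, 4, 4))
        data = np.repeat(v[..., None], 25, axis=-1)
        out = mean_t2star_map([self._bold(data)] * 3, volume_index=19)
        np.testing.assert_allclose(out, v)

    def test_opposite_volumes_cancel(self, rng):
        data = rng.standard_normal((4, 4, 4, 25))
        out = mean_t2star_map([self._bold(data), self._bold(-data)], 19)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_variance_shrinks_as_one_over_n(self, rng):
        bolds = [self._bold(rng.standard_normal((6, 6, 6, 25)))
                 for _ in range(30)]
        out = mean_t2star_map(bolds, 19)
        assert out.var() == pytest.approx(1 / 30, rel=0.35)

    def test_volume_index_out_of_range(self, rng):
        with pytest.raises(ValueError, match="out of range"):
            mean_t2star_map([self._bold(rng.standard_normal((3, 3, 3, 10)))],
                            volume_index=19)


class TestTwoSampleScalar:
    def test_identical_samples(self, rng):
        x = rng.standard_normal(10)
        t, p = two_sample_scalar_test(x, x)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_shift_is_significant(self, rng):
        y = rng.standard_normal(40)
        t, p = two_sample_scalar_test(y + 10, y)
        assert p < 0.001 and t > 0

    def test_df_is_sum_minus_two(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30) + 0.5
        t, p = two_sample_scalar_test(x, y)
        assert p == pytest.approx(2 * scipy.stats.t.sf(abs(t), 58), abs=1e-12)

    def test_zero_pooled_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            two_sample_scalar_test(np.ones(5), np.full(5, 2.0))


class TestGmCovariateControl:
    """Covariate-control behavior on planted cohorts."""

    def _roi_reho_means(self, cohort, cfg):
        from rehoscope import preprocess_bold, reho_map
        spec = cohort.spec
        roi = spec.rois[spec.gm_deficit_roi].mask(spec.grid)
        out = []
        for bold in cohort.bolds:
            m = reho_map(preprocess_bold(bold, cfg), cohort.mask)
            out.append(m.data[roi].mean())
        return np.asarray(out)

    def test_mediated_deficit_shrinks_f_after_gm_control(self, tiny_spec):
        """When the GM deficit drives the coherence deficit, controlling the
        GM index reduces the group F in >=9/10 replicates."""
        from rehoscope import PipelineConfig
        wins = 0
        cfg = PipelineConfig(n_discard=0)
        for rep in range(10):
            spec = dataclasses.replace(tiny_spec, gm_mediates=True,
                                       n_per_group=12, seed=400 + rep)
            cohort = simulate_cohort(spec)
            y = self._roi_reho_means(cohort, cfg)
            g = cohort.group_indicator().astype(float)
            roi = spec.rois[spec.gm_deficit_roi].mask(spec.grid)
            z = np.array([
                gm_index(gm, roi, total_gm_volume(gm, 27.0), 27.0)
                for gm in cohort.gm_maps])
            t_unc, _ = two_sample_scalar_test(y[g == 1], y[g == 0])
            f_ctrl, _ = ancova_group_effect(y, g, z)
            wins += f_ctrl < t_unc ** 2
        assert wins >= 9

    def test_independent_effects_survive_gm_control(self, tiny_spec):
        """Independently planted GM and coherence deficits: the group effect
        stays significant after GM-index control in >=9/10 replicates."""
        from rehoscope import PipelineConfig
        wins = 0
        cfg = PipelineConfig(n_discard=0)
        for rep in range(10):
            spec = dataclasses.replace(tiny_spec, n_per_group=12,
                                       seed=500 + rep)
            cohort = simulate_cohort(spec)
            y = self._roi_reho_means(cohort, cfg)
            g = cohort.group_indicator().astype(float)
            roi = spec.rois[spec.gm_deficit_roi].mask(spec.grid)
            z = np.array([
                gm_index(gm, roi, total_gm_volume(gm, 27.0), 27.0)
                for gm in cohort.gm_maps])
            _, p_ctrl = ancova_group_effect(y, g, z)
            wins += p_ctrl < 0.05
        assert wins >= 9
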