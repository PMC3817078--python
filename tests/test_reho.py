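import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

from rehoscope import (BoldSeries, BrainMask, expected_kcc, kendalls_w,
                       normalize_reho, rank_time_series, reho_map,
                       simulate_subject, smooth_map)
from rehoscope.cohort import RoiBox, SimulationSpec

AFF = np.diag([3.0, 3.0, 3.0, 1.0])


def eq1_rank_sum_oracle(ranks):
    """Direct evaluation of the rank-sum concordance formula."""
    n, k = ranks.shape
    r_i = ranks.sum(axis=1)
    rbar = (n + 1) * k / 2.0
    return float(((r_i - rbar) ** 2).sum() / ((1 / 12) * k ** 2 * (n ** 3 - n)))


def mean_spearman_oracle(x):
    """W from the mean of all pairwise Spearman correlations (tie-free)."""
    n, k = x.shape
    rho = [spearmanr(x[:, i], x[:, j]).statistic
           for i in range(k) for j in range(i + 1, k)]
    return ((k - 1) * float(np.mean(rho)) + 1.0) / k


class TestRanks:
    def test_simple_ordering(self):
        ranks, degen = rank_time_series(np.array([3.1, -2.0, 7.5]))
        np.testing.assert_array_equal(ranks, [2, 1, 3])
        assert not degen

    def test_midranks_on_ties(self):
        ranks, _ = rank_time_series(np.array([5.0, 5.0, 1.0]))
        np.testing.assert_array_equal(ranks, [2.5, 2.5, 1.0])

    def test_constant_series_flagged_degenerate(self):
        ranks, degen = rank_time_series(np.array([4.0, 4.0, 4.0, 4.0]))
        assert degen
        np.testing.assert_array_equal(ranks, [2.5] * 4)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_time_series(np.array([1.0, np.nan, 2.0]))


class TestKendallsW:
    def test_perfect_concordance(self):
        ranks = np.tile(np.array([1.0, 2, 3, 4])[:, None], (1, 3))
        assert kendalls_w(ranks) == pytest.approx(1.0)

    def test_perfect_discordance_two_series(self):
        ranks = np.column_stack([[1, 2, 3], [3, 2, 1]])
        assert kendalls_w(ranks) == pytest.approx(0.0)

    def test_all_degenerate_columns_give_zero(self):
        ranks = np.full((5, 3), 3.0)  # all-tie midranks
        assert kendalls_w(ranks) == 0.0

    def test_matches_both_independent_oracles(self, rng):
        """Tie-free random blocks: the rank-sum evaluation agrees to 1e-12
        and the mean-pairwise-Spearman identity to 1e-10."""
        for _ in range(120):
            n = int(rng.integers(4, 41))
            k = int(rng.integers(2, 28))
            x = rng.standard_normal((n, k))
            ranks = rankdata(x, axis=0)
            w = kendalls_w(ranks)
            assert w == pytest.approx(eq1_rank_sum_oracle(ranks), abs=1e-12)
            assert w == pytest.approx(mean_spearman_oracle(x), abs=1e-10)
            assert 0.0 <= w <= 1.0

    def test_permutation_of_series_order_invariant(self, rng):
        x = rng.standard_normal((12, 9))
        ranks = rankdata(x, axis=0)
        w = kendalls_w(ranks)
        for _ in range(5):
            perm = rng.permutation(9)
            assert kendalls_w(ranks[:, perm]) == pytest.approx(w, abs=1e-12)


class TestKendallsWProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=2, max_value=30),
           st.integers(min_value=2, max_value=27))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_range_and_order_invariance(self, seed, n, k):
        """0 <= W <= 1 for any rank block, and W ignores both the order of
        the k series and any common monotone relabeling of the ranks."""
        r = np.random.default_rng(seed)
        x = r.standard_normal((n, k))
        ranks = rankdata(x, axis=0)
        w = kendalls_w(ranks)
        assert 0.0 <= w <= 1.0
        perm = r.permutation(k)
        assert kendalls_w(ranks[:, perm]) == pytest.approx(w, abs=1e-12)
        assert kendalls_w(rankdata(np.exp(x), axis=0)) == \
            pytest.approx(w, abs=1e-12)


class TestReHoMap:
    def _mask(self, shape=(6, 6, 6)):
        return BrainMask(data=np.ones(shape, dtype=bool), affine=AFF)

    def test_identical_series_everywhere_gives_w_one(self, rng):
        ts = rng.standard_normal(20)
        data = np.broadcast_to(ts, (6, 6, 6, 20)).copy()
        bold = BoldSeries(data=data, affine=AFF, tr=2.0)
        m = reho_map(bold, self._mask())
        interior = m.data[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior, 1.0, atol=1e-10)

    def test_matches_per_voxel_kendalls_w(self, rng):
        """The vectorized map equals voxel-by-voxel evaluation of W over the
        in-mask neighborhood, at interior voxels and at mask edges."""
        shape = (5, 5, 5)
        mask = BrainMask(data=rng.random(shape) > 0.2, affine=AFF)
        bold = BoldSeries(data=rng.standard_normal(shape + (15,)),
                          affine=AFF, tr=2.0)
        m = reho_map(bold, mask, neighborhood=27)
        for idx in np.argwhere(mask.data)[::7]:
            cols = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        p = idx + np.array([di, dj, dk])
                        if ((0 <= p) & (p < np.array(shape))).all() and \
                                mask.data[tuple(p)]:
                            cols.append(rankdata(bold.data[tuple(p)]))
            k = len(cols)
            assert m.k_used[tuple(idx)] == k
            expected = kendalls_w(np.column_stack(cols)) if k >= 2 else 0.0
            assert m.data[tuple(idx)] == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("neighborhood,interior_k", [(7, 7), (19, 19), (27, 27)])
    def test_neighborhood_sizes(self, rng, neighborhood, interior_k):
        bold = BoldSeries(data=rng.standard_normal((5, 5, 5, 8)),
                          affine=AFF, tr=2.0)
        m = reho_map(bold, self._mask((5, 5, 5)), neighborhood=neighborhood)
        assert m.k_used[2, 2, 2] == interior_k

    def test_isolated_mask_voxel_gets_zero(self, rng):
        mask_data = np.zeros((5, 5, 5), dtype=bool)
        mask_data[2, 2, 2] = True
        mask = BrainMask(data=mask_data, affine=AFF)
        bold = BoldSeries(data=rng.standard_normal((5, 5, 5, 10)),
                          affine=AFF, tr=2.0)
        m = reho_map(bold, mask)
        assert m.data[2, 2, 2] == 0.0
        assert m.k_used[2, 2, 2] == 1

    def test_monotone_response_to_planted_coherence(self):
        """Mean ROI ReHo strictly increases over rho in {0, 0.3, 0.6} with
        clear (3 SE) separation, matching the equicorrelation model."""
        means = {rho: [] for rho in (0.0, 0.3, 0.6)}
        roi = RoiBox((1, 1, 1), (7, 7, 7))
        for rho in means:
            for rep in range(4):
                spec = SimulationSpec(
                    n_per_group=1, grid=(8, 8, 8), n_volumes=120,
                    rois={"roi": roi},
                    coherence_control={"roi": rho},
                    coherence_patient={"roi": rho},
                    background_coherence=0.0, behav_corr={},
                    gm_deficit_roi="roi",
                    drift_amplitude=0.0, cardio_amplitude=0.0, seed=0)
                bold, _, _ = simulate_subject(spec, "control", 1000 + rep,
                                              coherences={"roi": rho})
                mask = BrainMask(data=np.ones((8, 8, 8), bool), affine=AFF)
                m = reho_map(bold, mask)
                means[rho].append(m.data[2:6, 2:6, 2:6].mean())
        stats = {rho: (np.mean(v), np.std(v) / np.sqrt(len(v)))
                 for rho, v in means.items()}
        assert stats[0.3][0] - stats[0.0][0] > 3 * (stats[0.3][1] + stats[0.0][1])
        assert stats[0.6][0] - stats[0.3][0] > 3 * (stats[0.6][1] + stats[0.3][1])
        # and the closed-form calibration is in the right neighborhood
        assert stats[0.6][0] == pytest.approx(expected_kcc(0.6, 27), rel=0.1)


class TestNormalize:
    def _map(self, data, rng=None):
        mask = BrainMask(data=np.ones(data.shape, bool), affine=AFF)
        bold = BoldSeries(
            data=np.random.default_rng(0).standard_normal(data.shape + (8,)),
            affine=AFF, tr=2.0)
        m = reho_map(bold, mask)
        m.data = np.asarray(data, dtype=float)
        return m

    def test_uniform_map_becomes_one(self):
        m = normalize_reho(self._map(np.full((4, 4, 4), 0.2)))
        np.testing.assert_allclose(m.data, 1.0)
        assert m.normalized

    def test_half_and_half(self):
        data = np.full((4, 4, 4), 0.1)
        data[2:] = 0.3
        m = normalize_reho(self._map(data))
        np.testing.assert_allclose(np.unique(np.round(m.data, 10)), [0.5, 1.5])

    def test_mask_mean_is_one(self, rng, noise_bold, full_mask):
        m = reho_map(noise_bold(shape=(6, 6, 6), t_len=20), full_mask((6, 6, 6)))
        normalized = normalize_reho(m)
        assert normalized.data[normalized.valid].mean() == pytest.approx(1.0, abs=1e-6)

    def test_double_normalization_rejected(self, noise_bold, full_mask):
        m = normalize_reho(reho_map(noise_bold(shape=(6, 6, 6), t_len=20),
                                    full_mask((6, 6, 6))))
        with pytest.raises(ValueError):
            normalize_reho(m)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        x = rng.standard_normal((9, 9, 9))
        np.testing.assert_array_equal(smooth_map(x, 0.0, (3, 3, 3)), x)

    def test_constant_map_preserved(self):
        x = np.full((15, 15, 15), 2.5)
        out = smooth_map(x, 8.0, (3, 3, 3))
        np.testing.assert_allclose(out, 2.5, atol=1e-8)

    def test_impulse_matches_closed_form_gaussian(self):
        x = np.zeros((21, 21, 21))
        x[10, 10, 10] = 1.0
        out = smooth_map(x, 8.0, (3, 3, 3))
        sigma = 8.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))) / 3.0
        d = np.arange(21) - 10
        g1 = np.exp(-d ** 2 / (2 * sigma ** 2))
        g1 /= g1.sum()
        expected_axis = g1 * g1[10] * g1[10]
        np.testing.assert_allclose(out[:, 10, 10], expected_axis, atol=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_map(np.zeros((4, 4, 4)), -1.0, (3, 3, 3))

    def test_full_grid_mask_mean_preserved_within_one_percent(self):
        """On the map the pipeline actually smooths (a preprocessed subject
        at study conditions), smoothing moves the full-grid mean <1%."""
        from rehoscope import PipelineConfig, preprocess_bold
        spec = SimulationSpec(seed=3)
        bold, _, _ = simulate_subject(spec, "control", 11)
        pre = preprocess_bold(bold, PipelineConfig())
        mask = BrainMask(data=np.ones(spec.grid, bool), affine=spec.affine())
        m = normalize_reho(reho_map(pre, mask))
        smoothed = smooth_map(m.data, 8.0, (3, 3, 3))
        assert abs(smoothed.mean() - 1.0) < 0.01
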