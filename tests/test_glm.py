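import numpy as np
import pytest
from scipy import ndimage, stats

from valmux import glm, synth
from valmux.config import StudyConfig


@pytest.fixture(scope="module")
def trials():
    return synth.generate_ratings(StudyConfig(seed=41), 7)


@pytest.fixture(scope="module")
def n_scans(trials):
    return synth.n_scans_for(StudyConfig(seed=41), trials)


class TestPreprocess:
    def test_linear_ramp_removed(self):
        series = np.tile(np.linspace(0.0, 5.0, 100), (3, 3, 3, 1))
        out, valid = glm.preprocess(series, zscore=False)
        assert np.abs(out).max() < 1e-8
        assert not valid.any()  # nothing but trend: zero residual variance

    def test_z_transform_contract(self, rng):
        series = rng.normal(size=(4, 4, 4, 120))
        out, valid = glm.preprocess(series)
        assert valid.all()
        assert np.abs(out.mean(-1)).max() < 1e-6
        assert np.abs(out.std(-1) - 1.0).max() < 1e-6

    def test_highpass_removes_slow_cosine(self, rng):
        n = 200
        t = np.arange(n)
        slow = np.cos(np.pi * 2 * (2 * t + 1) / (2 * n))  # 1 cycle per scan
        series = np.broadcast_to(slow, (2, 2, 2, n)).copy()
        series += rng.normal(0, 1e-3, size=series.shape)
        out, _ = glm.preprocess(series, zscore=False)
        assert out.std() < 0.01

    def test_zero_fwhm_smoothing_is_identity(self, rng):
        series = rng.normal(size=(5, 5, 5, 60))
        a, _ = glm.preprocess(series, smooth_fwhm_mm=0.0, zscore=False)
        b, _ = glm.preprocess(series, smooth_fwhm_mm=0.0, zscore=False)
        assert np.array_equal(a, b)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            glm.preprocess(np.zeros((2, 2, 2, 4)))


class TestDesign:
    def test_main_variant_has_eight_task_regressors(self, trials):
        des = glm.build_design(trials, 1200, 2.0, "main")
        assert int(des.is_task.sum()) == 8
        assert des.names[:3] == ["na_cue", "na_cue_value", "na_cue_saliency"]

    def test_cond16_variant_has_sixteen_cue_regressors(self, trials):
        des = glm.build_design(trials, 1200, 2.0, "cond16")
        assert int(des.is_task.sum()) == 16

    def test_rating9_covers_observed_levels_only(self, trials):
        des = glm.build_design(trials, 1200, 2.0, "rating9")
        nact = ~trials["actualized"] & trials["rating"].notna()
        observed = sorted(trials.loc[nact, "rating"].unique())
        names = [n for n in des.names if n.startswith("rating")]
        assert names == [f"rating{int(v)}" for v in observed]

    def test_modulator_weights_demeaned(self, trials):
        # the unconvolved value weights sum to zero: the modulator column is
        # orthogonal to the cue column at the event level
        des = glm.build_design(trials, 1200, 2.0, "main")
        nact = ~trials["actualized"] & trials["rating"].notna()
        w = trials.loc[nact, "rating"] - trials.loc[nact, "rating"].mean()
        assert abs(w.sum()) < 1e-10

    def test_convolution_matches_brute_force_oracle(self):
        # independent oracle: explicit double loop over events and lags on a
        # 50-TR toy design at the TR resolution
        tr, n = 2.0, 50
        onsets = np.array([4.0, 20.0, 60.0])
        weights = np.array([1.0, -0.5, 2.0])
        fast = glm.convolve_events(onsets, np.full(3, 6.0), weights, n, tr, oversample=1)
        hrf = glm.double_gamma_hrf(tr)
        stim = np.zeros(n)
        for o, w in zip(onsets, weights):
            for k in range(int(6.0 / tr)):
                idx = int(round(o / tr)) + k
                if idx < n:
                    stim[idx] += w
        slow = np.zeros(n)
        for t in range(n):
            for u in range(len(hrf)):
                if t - u >= 0:
                    slow[t] += stim[t - u] * hrf[u] * tr
        assert np.corrcoef(fast, slow)[0, 1] > 0.99
        assert np.allclose(fast, slow, atol=1e-10)

    def test_unknown_variant_rejected(self, trials):
        with pytest.raises(ValueError, match="variant"):
            glm.build_design(trials, 100, 2.0, "bogus")


class TestFitOls:
    def test_residuals_orthogonal_to_design(self, trials, n_scans, rng):
        des = glm.build_design(trials, n_scans, 2.0, "main")
        series = rng.normal(size=(3, 3, 3, n_scans))
        _, resid = glm.fit_ols(series, des)
        dots = des.matrix.T @ resid.reshape(-1, n_scans).T
        assert np.abs(dots).max() < 1e-6

    def test_duplicated_column_named_in_error(self, trials, n_scans):
        des = glm.build_design(trials, n_scans, 2.0, "main")
        dup = glm.DesignMatrix(
            np.column_stack([des.matrix, des.matrix[:, 1]]),
            des.names + ["na_cue_value_copy"],
        )
        with pytest.raises(np.linalg.LinAlgError, match="na_cue_value"):
            glm.fit_ols(np.zeros((2, 2, 2, n_scans)), dup)

    def test_series_length_mismatch(self, trials, n_scans):
        des = glm.build_design(trials, n_scans, 2.0, "main")
        with pytest.raises(ValueError, match="length"):
            glm.fit_ols(np.zeros((2, 2, 2, 99)), des)


class TestGroupTtest:
    def test_df_is_n_minus_one(self, rng):
        t, df = glm.group_ttest(rng.normal(size=(18, 4, 4, 4)))
        assert df == 17

    def test_matches_scalar_oracle_at_one_voxel(self, rng):
        stack = rng.normal(0.3, 1.0, size=(18, 3, 3, 3))
        t, _ = glm.group_ttest(stack)
        ref = stats.ttest_1samp(stack[:, 1, 2, 0], 0.0).statistic
        assert t[1, 2, 0] == pytest.approx(ref)

    def test_zero_variance_voxel_masked(self, rng):
        stack = rng.normal(size=(6, 2, 2, 2))
        stack[:, 0, 0, 0] = 0.0
        t, _ = glm.group_ttest(stack)
        assert np.isnan(t[0, 0, 0])


class TestSmoothness:
    def test_iid_noise_estimates_subvoxel(self, rng):
        resid = rng.normal(size=(24, 24, 24, 100))
        mask = np.ones((24, 24, 24), bool)
        fwhm = glm.estimate_smoothness(resid, mask, (3.0, 3.0, 3.0))
        assert np.all(fwhm <= 1.2 * 3.0)

    def test_applied_smoothing_recovered_within_25_percent(self, rng):
        resid = rng.normal(size=(24, 24, 24, 40))
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        resid = ndimage.gaussian_filter(resid, sigma=[sigma, sigma, sigma, 0.0])
        mask = np.ones((24, 24, 24), bool)
        fwhm = glm.estimate_smoothness(resid, mask, (3.0, 3.0, 3.0))
        assert np.all(np.abs(fwhm - 6.0) / 6.0 < 0.25)

    def test_monotone_in_applied_smoothing(self, rng):
        mask = np.ones((20, 20, 20), bool)
        noise = rng.normal(size=(20, 20, 20, 30))
        est = []
        for s in (0.5, 1.0, 2.0):
            sm = ndimage.gaussian_filter(noise, sigma=[s, s, s, 0.0])
            est.append(glm.estimate_smoothness(sm, mask, (3.0, 3.0, 3.0)).mean())
        assert est[0] < est[1] < est[2]


class TestClusterThreshold:
    def test_alpha_one_gives_one(self, rng):
        mask = np.ones((10, 10, 10), bool)
        k = glm.cluster_threshold(
            mask.shape, mask, np.zeros(3), (3, 3, 3), alpha=1.0,
            n_sims=100, rng=rng,
        )
        assert k == 1

    def test_nondecreasing_in_smoothness(self):
        mask = np.ones((20, 20, 20), bool)
        ks = []
        for fwhm in (0.0, 4.0, 8.0):
            k = glm.cluster_threshold(
                mask.shape, mask, np.full(3, fwhm), (3.0, 3.0, 3.0),
                n_sims=200, rng=np.random.default_rng(5),
            )
            ks.append(k)
        assert ks[0] <= ks[1] <= ks[2]

    def test_nonincreasing_in_voxel_p(self):
        mask = np.ones((20, 20, 20), bool)
        ks = []
        for p in (0.01, 0.005, 0.001):
            k = glm.cluster_threshold(
                mask.shape, mask, np.zeros(3), (3.0, 3.0, 3.0), voxel_p=p,
                n_sims=200, rng=np.random.default_rng(6),
            )
            ks.append(k)
        assert ks[0] >= ks[1] >= ks[2]

    def test_too_few_sims_rejected(self, rng):
        mask = np.ones((5, 5, 5), bool)
        with pytest.raises(ValueError, match="n_sims"):
            glm.cluster_threshold(mask.shape, mask, np.zeros(3), (3, 3, 3), n_sims=10, rng=rng)


def _flood_fill_sizes(binary):
    """Independent 6-connectivity component sizes by explicit BFS."""
    visited = np.zeros(binary.shape, bool)
    sizes = []
    idx = np.argwhere(binary)
    for start in map(tuple, idx):
        if visited[start]:
            continue
        stack, size = [start], 0
        visited[start] = True
        while stack:
            x, y, z = stack.pop()
            size += 1
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                p = (x + dx, y + dy, z + dz)
                if (
                    0 <= p[0] < binary.shape[0]
                    and 0 <= p[1] < binary.shape[1]
                    and 0 <= p[2] < binary.shape[2]
                    and binary[p]
                    and not visited[p]
                ):
                    visited[p] = True
                    stack.append(p)
        sizes.append(size)
    return sorted(sizes)


class TestApplyThreshold:
    def test_empty_map_gives_no_clusters(self):
        clusters, surviving = glm.apply_threshold(np.zeros((5, 5, 5)), 2.0, 1)
        assert clusters == [] and not surviving.any()

    def test_cluster_size_boundary(self):
        stat = np.zeros((10, 10, 10))
        stat[2:7, 3, 3] = 5.0  # a 5-voxel line
        kept, _ = glm.apply_threshold(stat, 2.0, cluster_k=5)
        dropped, _ = glm.apply_threshold(stat, 2.0, cluster_k=6)
        assert len(kept) == 1 and kept[0].size == 5
        assert dropped == []

    def test_sizes_match_flood_fill_oracle(self, rng):
        stat = (rng.random((12, 12, 12)) < 0.2).astype(float) * 3.0
        clusters, _ = glm.apply_threshold(stat, 1.0, cluster_k=1, two_tailed=False)
        assert sorted(c.size for c in clusters) == _flood_fill_sizes(stat > 1.0)

    def test_reports_center_and_peak(self):
        stat = np.zeros((8, 8, 8))
        stat[2:5, 4, 4] = [3.0, 6.0, 3.0]
        clusters, _ = glm.apply_threshold(stat, 2.0, 1)
        c = clusters[0]
        assert np.allclose(c.center_of_gravity, [3, 4, 4])
        assert tuple(c.peak_voxel) == (3, 4, 4)
        assert c.peak_stat == 6.0
        assert c.mean_stat == pytest.approx(4.0)


class TestConjunction:
    def test_disjoint_maps_empty(self):
        a = np.zeros((5, 5, 5))
        b = np.zeros((5, 5, 5))
        a[0, 0, 0] = b[4, 4, 4] = 5.0
        assert not glm.conjunction(a, b, 2.0).any()

    def test_identical_maps_reproduce_suprathreshold_set(self, rng):
        a = rng.normal(size=(6, 6, 6))
        conj = glm.conjunction(a, a.copy(), 1.0)
        assert np.array_equal(conj, a > 1.0)

    def test_commutative(self, rng):
        a, b = rng.normal(size=(6, 6, 6)), rng.normal(size=(6, 6, 6))
        assert np.array_equal(glm.conjunction(a, b, 1.0), glm.conjunction(b, a, 1.0))

    def test_min_cluster_filters_specks(self):
        a = np.zeros((10, 10, 10))
        a[1, 1, 1] = 5.0
        a[5:9, 5, 5] = 5.0
        conj = glm.conjunction(a, a.copy(), 2.0, min_cluster=2)
        assert not conj[1, 1, 1] and conj[5:9, 5, 5].all()
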