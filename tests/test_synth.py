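import numpy as np
import pandas as pd
import pytest

from valmux import glm, synth
from valmux.config import (
    CONDITIONS,
    EffectSpec,
    NoiseSpec,
    StudyConfig,
    box_roi,
)


class TestSchedule:
    def test_balanced_conditions_and_actualization(self):
        cfg = StudyConfig(seed=1)
        t = synth.generate_trial_schedule(cfg, 42)
        assert len(t) == 96
        counts = t.groupby(["category", "level"]).size()
        assert (counts == 6).all() and len(counts) == 16
        act = t.groupby(["category", "level"])["actualized"].sum()
        assert (act == 2).all()

    def test_fixed_iti_gives_constant_cue_spacing(self):
        cfg = StudyConfig(iti_range_s=(10.0, 10.0), seed=2)
        t = synth.generate_trial_schedule(cfg, 0)
        gaps = np.diff(t["cue_onset_s"].to_numpy())
        assert np.allclose(gaps, 22.0)

    def test_itis_snap_to_tr_grid(self):
        cfg = StudyConfig(seed=3)
        t = synth.generate_trial_schedule(cfg, 5)
        onsets = t["cue_onset_s"].to_numpy()
        assert np.allclose(onsets % cfg.tr_s, 0.0)
        assert (np.diff(onsets) > 0).all()

    def test_same_seed_reproduces_table(self):
        cfg = StudyConfig(seed=4)
        a = synth.generate_trial_schedule(cfg, 9)
        b = synth.generate_trial_schedule(cfg, 9)
        pd.testing.assert_frame_equal(a, b)


class TestRatings:
    def test_noiseless_monotone_construction(self):
        # slope +1 from neutral 5: gain levels 1..4 -> 6,7,8,9; shock mirrored
        cfg = StudyConfig(
            seed=0, rating_subject_sd=0.0, rating_noise_sd=1e-9,
            rating_slopes={"gain": 1.0, "loss": -1.0, "face": 1.0, "shock": -1.0},
        )
        t = synth.generate_ratings(cfg, 0)
        by_cell = t.groupby(["category", "level"])["rating"].first()
        for lvl in (1, 2, 3, 4):
            assert by_cell[("gain", lvl)] == 5 + lvl
            assert by_cell[("shock", lvl)] == 5 - lvl

    def test_ratings_clipped_to_scale(self):
        cfg = StudyConfig(seed=0, rating_noise_sd=5.0)
        t = synth.generate_ratings(cfg, 123)
        assert t["rating"].between(1, 9).all()

    def test_opposing_trends_in_expectation(self):
        # averaged over many subjects: level 4 above level 1 for rewards,
        # below for punishments
        cfg = StudyConfig(seed=6)
        cells = []
        for ss in np.random.SeedSequence(99).spawn(200):
            t = synth.generate_ratings(cfg, ss)
            cells.append(t.groupby(["category", "level"])["rating"].mean())
        mean = pd.concat(cells, axis=1).mean(axis=1)
        for cat in ("gain", "face"):
            assert mean[(cat, 4)] > mean[(cat, 1)]
        for cat in ("loss", "shock"):
            assert mean[(cat, 4)] < mean[(cat, 1)]

    def test_missing_rate_marks_trials(self):
        cfg = StudyConfig(seed=1, missing_rate=0.2)
        t = synth.generate_ratings(cfg, 7)
        assert t["rating"].isna().sum() > 0


class TestBold:
    def test_noiseless_series_proportional_to_convolved_regressor(self, small_shape, small_roi):
        cfg = StudyConfig(
            n_subjects=1, grid_shape=small_shape, seed=5,
            effects=[EffectSpec("value_linear", small_roi, 0.2)],
        )
        ss = cfg.subject_seeds()[0]
        trials = synth.generate_ratings(cfg, ss)
        truth = synth.make_ground_truth(cfg, ss)
        series = synth.generate_bold(cfg, trials, truth, noise_rng=None)
        nact = ~trials["actualized"] & trials["rating"].notna()
        reg = glm.convolve_events(
            trials.loc[nact, "cue_onset_s"].to_numpy(),
            np.full(nact.sum(), 6.0),
            trials.loc[nact, "rating"].to_numpy(),
            series.shape[-1],
            cfg.tr_s,
        )
        inside = series[small_roi][0]
        assert np.allclose(inside, 0.2 * reg, atol=1e-10)
        assert np.abs(series[~small_roi]).max() == 0.0

    def test_white_noise_has_no_autocorrelation(self):
        cfg = StudyConfig(
            n_subjects=1, grid_shape=(6, 6, 6), seed=8,
            noise=NoiseSpec(sigma=1.0, ar1_rho=0.0, smooth_fwhm_mm=0.0),
        )
        noise = synth.make_noise(cfg, 500, np.random.default_rng(0))
        flat = noise.reshape(-1, 500)
        r1 = np.mean(
            [np.corrcoef(v[:-1], v[1:])[0, 1] for v in flat[::10]]
        )
        assert abs(r1) < 0.1

    def test_ar1_noise_has_requested_autocorrelation(self):
        cfg = StudyConfig(
            n_subjects=1, grid_shape=(6, 6, 6), seed=8,
            noise=NoiseSpec(sigma=1.0, ar1_rho=0.5, smooth_fwhm_mm=0.0),
        )
        noise = synth.make_noise(cfg, 1000, np.random.default_rng(1))
        flat = noise.reshape(-1, 1000)
        r1 = np.mean([np.corrcoef(v[:-1], v[1:])[0, 1] for v in flat[::10]])
        assert r1 == pytest.approx(0.5, abs=0.08)

    def test_mean_offset_round_trip_through_glm(self, noiseless_config, small_roi):
        cfg = noiseless_config
        ss = cfg.subject_seeds()[0]
        trials = synth.generate_ratings(cfg, ss)
        truth = synth.make_ground_truth(cfg, ss)
        series = synth.generate_bold(cfg, trials, truth, noise_rng=None)
        design = glm.build_design(trials, series.shape[-1], cfg.tr_s, "main")
        betas, _ = glm.fit_ols(series.astype(float), design)
        assert betas["na_cue_value"][small_roi].mean() == pytest.approx(0.1, rel=1e-6)


class TestConditionBetas:
    def test_betas_encode_condition_means(self, small_shape, small_roi):
        cfg = StudyConfig(
            n_subjects=1, grid_shape=small_shape, seed=2,
            effects=[EffectSpec("value_linear", small_roi, 0.5)],
        )
        ss = cfg.subject_seeds()[0]
        trials = synth.generate_ratings(cfg, ss)
        truth = synth.make_ground_truth(cfg, ss)
        betas = synth.generate_condition_betas(cfg, trials, truth, noise_rng=None)
        mods = synth.condition_modulators(trials)
        for i, (cat, lvl) in enumerate(CONDITIONS):
            expected = 0.5 * mods.loc[(cat, lvl), "rating"]
            assert betas[i][small_roi] == pytest.approx(expected)
            assert np.all(betas[i][~small_roi] == 0)

    def test_category_patterns_zero_mean_unit_norm(self, small_shape, small_roi):
        cfg = StudyConfig(
            n_subjects=1, grid_shape=small_shape, seed=2,
            effects=[EffectSpec("category_pattern", small_roi, 3.0)],
        )
        truth = synth.make_ground_truth(cfg, cfg.subject_seeds()[0])
        for pat in truth.category_patterns.values():
            vec = pat[small_roi]
            assert vec.mean() == pytest.approx(0.0, abs=1e-12)
            assert np.linalg.norm(vec) == pytest.approx(3.0)
            assert np.all(pat[~small_roi] == 0)

    def test_orthogonalized_weights_uncorrelated_with_value(self):
        cfg = StudyConfig(seed=3)
        trials = synth.generate_ratings(cfg, 17)
        w = synth.category_condition_weights(trials, orthogonalize_to_value=True)
        r = synth.condition_modulators(trials)["rating"].to_numpy()
        for cat in w.columns:
            assert abs(np.dot(w[cat], r - r.mean())) < 1e-9
            assert abs(w[cat].sum()) < 1e-9


class TestCohort:
    def test_cohort_size_and_determinism(self, small_shape):
        cfg = StudyConfig(n_subjects=4, grid_shape=small_shape, seed=21)
        a = synth.generate_cohort(cfg, betas_only=True)
        b = synth.generate_cohort(cfg, betas_only=True)
        assert len(a) == 4
        for (ta, da, _), (tb, db, _) in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)
            assert np.array_equal(da, db)

    def test_subjects_differ_pairwise(self, small_shape):
        cfg = StudyConfig(n_subjects=3, grid_shape=small_shape, seed=22)
        cohort = synth.generate_cohort(cfg, betas_only=True)
        for i in range(3):
            for j in range(i + 1, 3):
                assert not np.array_equal(cohort[i][1], cohort[j][1])
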