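import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from valmux import rsa, synth
from valmux.config import CONDITIONS, StudyConfig


@pytest.fixture(scope="module")
def cond_means():
    trials = synth.generate_ratings(StudyConfig(seed=51), 3)
    return synth.condition_modulators(trials)


class TestPearsonDistance:
    def test_identity_and_anticorrelation(self, rng):
        b = rng.normal(size=27)
        assert rsa.pearson_distance(b, b) == pytest.approx(0.0, abs=1e-12)
        assert rsa.pearson_distance(b, -b) == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_example(self):
        # centered (1,2,3) -> (-1,0,1); centered (1,3,2) -> (-1,1,0)
        # corr = 1 / (sqrt(2) sqrt(2)) = 0.5 -> distance 0.5
        assert rsa.pearson_distance([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_positive_affine_invariance(self, rng):
        b = rng.normal(size=27)
        assert rsa.pearson_distance(b, 3.2 * b + 7.0) == pytest.approx(0.0, abs=1e-12)

    def test_constant_pattern_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rsa.pearson_distance(np.ones(5), np.arange(5.0))


class TestNeuralRdm:
    def test_identical_patterns_give_zero_rdm(self):
        p = np.tile(np.arange(10.0), (16, 1))
        assert np.allclose(rsa.build_neural_rdm(p), 0.0)

    def test_random_patterns_center_near_one(self, rng):
        vals = []
        for _ in range(300):
            rdm = rsa.build_neural_rdm(rng.normal(size=(16, 27)))
            vals.append(rsa.lower_triangle(rdm).mean())
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_lower_triangle_has_120_entries(self, rng):
        rdm = rsa.build_neural_rdm(rng.normal(size=(16, 27)))
        assert rsa.lower_triangle(rdm).shape == (120,)

    def test_missing_condition_excludes_subject(self, rng):
        p = rng.normal(size=(16, 27))
        p[3] = np.nan
        with pytest.raises(ValueError, match="excluded"):
            rsa.build_neural_rdm(p)

    def test_scale_and_offset_invariance(self, rng):
        # shared positive scaling of every voxel, or a shared offset added
        # uniformly across voxels, leaves the RDM unchanged
        p = rng.normal(size=(16, 27))
        base = rsa.build_neural_rdm(p)
        assert np.allclose(rsa.build_neural_rdm(4.2 * p), base, atol=1e-10)
        assert np.allclose(rsa.build_neural_rdm(p + 11.0), base, atol=1e-10)


class TestModelRdms:
    def test_category_model_combinatorics(self):
        rdm = rsa.build_model_rdm("category")
        lower = rsa.lower_triangle(rdm)
        # brute-force enumeration over condition pairs
        zeros = sum(
            1
            for (ca, _), (cb, _) in itertools.combinations(CONDITIONS, 2)
            if ca == cb
        )
        assert (lower == 0).sum() == zeros == 24
        assert (lower == 1).sum() == 120 - zeros == 96

    def test_money_face_shock_combinatorics(self):
        rdm = rsa.build_model_rdm("money_face_shock")
        group = {"gain": "money", "loss": "money", "face": "face", "shock": "shock"}
        zeros = sum(
            1
            for (ca, _), (cb, _) in itertools.combinations(CONDITIONS, 2)
            if group[ca] == group[cb]
        )
        assert (rsa.lower_triangle(rdm) == 0).sum() == zeros == 40

    def test_gains_losses_primary_combinatorics(self):
        rdm = rsa.build_model_rdm("gains_losses_primary")
        assert (rsa.lower_triangle(rdm) == 0).sum() == 40

    def test_value_model_is_absolute_mean_difference(self, cond_means):
        rdm = rsa.build_model_rdm("value", cond_means)
        r = cond_means["rating"].to_numpy()
        i, j = 2, 9
        assert rdm[i, j] == pytest.approx(abs(r[i] - r[j]))

    def test_positive_negative_groups_gain_with_face(self):
        rdm = rsa.build_model_rdm("positive_negative")
        idx = {c: i for i, c in enumerate([f"{c}{l}" for c, l in CONDITIONS])}
        assert rdm[idx["gain1"], idx["face3"]] == 0
        assert rdm[idx["gain1"], idx["loss1"]] == 1
        assert rdm[idx["face2"], idx["shock2"]] == 1

    def test_category_mean_value_zero_within_category(self, cond_means):
        rdm = rsa.build_model_rdm("category_mean_value", cond_means)
        assert rdm[0, 3] == 0  # gain1 vs gain4
        cat_means = cond_means.groupby(level="category", sort=False)["rating"].mean()
        assert rdm[0, 4] == pytest.approx(abs(cat_means["gain"] - cat_means["loss"]))

    def test_all_models_valid_rdms(self, cond_means):
        for name in rsa.MODEL_NAMES:
            rdm = rsa.build_model_rdm(name, cond_means)
            assert np.allclose(rdm, rdm.T)
            assert np.allclose(np.diag(rdm), 0.0)
            assert (rdm >= 0).all()
        for name in ("category", "primary_secondary", "positive_negative",
                     "money_face_shock", "gains_losses_primary"):
            rdm = rsa.build_model_rdm(name)
            assert set(np.unique(rdm)) <= {0.0, 1.0}

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            rsa.build_model_rdm("telepathy")


class TestCompareRdms:
    def test_identical_lower_triangles_give_rho_one(self, rng):
        rdm = rsa.build_neural_rdm(rng.normal(size=(16, 27)))
        assert rsa.compare_rdms(rdm, rdm) == pytest.approx(1.0)

    def test_monotone_transform_preserves_rho(self, rng):
        rdm = rsa.build_neural_rdm(rng.normal(size=(16, 27)))
        assert rsa.compare_rdms(rdm**2, rdm) == pytest.approx(1.0)

    def test_matches_rank_then_correlate_oracle(self, rng):
        a = rsa.build_neural_rdm(rng.normal(size=(16, 27)))
        b = rsa.build_neural_rdm(rng.normal(size=(16, 27)))
        va, vb = rsa.lower_triangle(a), rsa.lower_triangle(b)
        ra = stats.rankdata(va)
        rb = stats.rankdata(vb)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rsa.compare_rdms(a, b) == pytest.approx(oracle)

    def test_constant_model_rejected(self, rng):
        rdm = rsa.build_neural_rdm(rng.normal(size=(16, 27)))
        with pytest.raises(ValueError, match="constant"):
            rsa.compare_rdms(rdm, np.zeros((16, 16)))


@pytest.fixture(scope="module")
def betas():
    return np.random.default_rng(8).normal(size=(16, 8, 8, 8))


class TestSearchlight:
    def test_interior_pattern_length_27(self, betas):
        # interior searchlight rho equals a direct 27-voxel computation
        mask = np.ones((8, 8, 8), bool)
        model = rsa.build_model_rdm("category")
        rho = rsa.searchlight(betas, mask, {"category": model})["category"]
        c = (4, 4, 4)
        cube = betas[:, 3:6, 3:6, 3:6].reshape(16, 27)
        ref = rsa.compare_rdms(rsa.build_neural_rdm(cube), model)
        assert rho[c] == pytest.approx(ref, abs=1e-10)

    def test_corner_skipped_under_min_voxels(self, betas):
        mask = np.ones((8, 8, 8), bool)
        rho = rsa.searchlight(
            betas, mask, {"category": rsa.build_model_rdm("category")}, min_voxels=14
        )["category"]
        assert np.isnan(rho[0, 0, 0])  # corner cube has 8 in-mask voxels
        assert not np.isnan(rho[4, 4, 4])

    def test_corner_kept_when_min_voxels_low(self, betas):
        mask = np.ones((8, 8, 8), bool)
        rho = rsa.searchlight(
            betas, mask, {"category": rsa.build_model_rdm("category")}, min_voxels=8
        )["category"]
        assert not np.isnan(rho[0, 0, 0])

    def test_translation_equivariance(self, betas):
        mask = np.ones((8, 8, 8), bool)
        model = {"category": rsa.build_model_rdm("category")}
        rho = rsa.searchlight(betas, mask, model)["category"]
        shifted = np.roll(betas, 2, axis=3)
        rho_s = rsa.searchlight(shifted, mask, model)["category"]
        assert np.allclose(
            rho[2:-2, 2:-2, 1:-3], rho_s[2:-2, 2:-2, 3:-1], equal_nan=True
        )


class TestSignedRank:
    def test_all_positive_exact_p(self):
        z, p = rsa.signed_rank_test(np.arange(1, 18, dtype=float))
        assert p == pytest.approx(2.0**-17, rel=1e-12)
        assert z > 3

    def test_symmetric_values_give_zero_z(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        z, p = rsa.signed_rank_test(x)
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_exact_oracle(self, rng):
        x = rng.normal(0.4, 1.0, size=17)
        _, p = rsa.signed_rank_test(x)
        ref = stats.wilcoxon(x, alternative="greater", method="exact").pvalue
        assert p == pytest.approx(ref, rel=1e-12)

    def test_all_zero_input(self):
        z, p = rsa.signed_rank_test(np.zeros(10))
        assert (z, p) == (0.0, 1.0)

    def test_group_inference_matches_scalar_path(self, rng):
        stack = rng.normal(0.1, 0.3, size=(17, 4, 4, 4))
        z_map, p_map = rsa.group_inference(stack)
        z_ref, p_ref = rsa.signed_rank_test(stack[:, 2, 1, 3])
        assert z_map[2, 1, 3] == pytest.approx(z_ref)
        assert p_map[2, 1, 3] == pytest.approx(p_ref)

    def test_group_inference_requires_min_subjects(self, rng):
        stack = rng.normal(size=(17, 3, 3, 3))
        stack[0:14, 0, 0, 0] = np.nan
        z_map, p_map = rsa.group_inference(stack, min_subjects=5)
        assert np.isnan(z_map[0, 0, 0])


def test_rdm_export_round_trip(tmp_path, rng):
    rdm = rsa.build_neural_rdm(rng.normal(size=(16, 27)))
    path = tmp_path / "rdm.tsv"
    rsa.export_rdm(rdm, path)
    back = pd.read_csv(path, sep="\t", index_col=0)
    assert list(back.columns) == ["gain1", "gain2", "gain3", "gain4",
                                  "loss1", "loss2", "loss3", "loss4",
                                  "face1", "face2", "face3", "face4",
                                  "shock1", "shock2", "shock3", "shock4"]
    assert np.allclose(back.to_numpy(), rdm)
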