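"""Signature training, LOO-CV, permutation and bootstrap inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emosig as es
from emosig.lasso_pcr import _stack_set, fit_lasso_pcr


class TestFitLassoPCR:
    def test_noiseless_recovery(self, noiseless_truth, noiseless_maps):
        model = es.fit_signature(noiseless_maps, seed=0)
        cos = es.cosine_similarity(model.weights, noiseless_truth.pattern_gt)
        assert abs(cos) > 0.99

    def test_training_mean_map_predicts_training_mean_outcome(self, fixture_maps):
        X, y, g, _ = _stack_set(fixture_maps["ground_truth"])
        model = fit_lasso_pcr(X, y, seed=0, groups=g)
        assert model.predict(X.mean(axis=0)) == pytest.approx(y.mean())

    def test_back_projection_consistency(self, fixture_maps):
        # voxel-space dot product + intercept equals component-space pipeline
        X, y, g, _ = _stack_set(fixture_maps["ground_truth"])
        model = fit_lasso_pcr(X, y, seed=0, groups=g)
        from sklearn.linear_model import Lasso

        mean = X.mean(axis=0)
        U, S, Vt = np.linalg.svd(X - mean, full_matrices=False)
        k = model.metadata["n_components"]
        scores = U[:, :k] * S[:k]
        lasso = Lasso(alpha=model.metadata["alpha"], max_iter=50000).fit(scores, y)
        pred_component = lasso.predict(scores)
        pred_voxel = model.predict(X)
        assert np.abs(pred_component - pred_voxel).max() < 1e-8

    def test_unpenalized_full_component_limit_equals_pcr_ols(self):
        # tiny full-rank instance: near-zero penalty reduces to OLS on the
        # principal subspace (here all of voxel space)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + 0.1 * rng.normal(size=30)
        from sklearn.linear_model import Lasso

        mean = X.mean(axis=0)
        U, S, Vt = np.linalg.svd(X - mean, full_matrices=False)
        scores = U * S
        tiny = Lasso(alpha=1e-10, max_iter=200000).fit(scores, y)
        w = Vt.T @ tiny.coef_
        Xd = np.column_stack([X, np.ones(30)])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert np.abs(w - beta[:8]).max() < 1e-5

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            fit_lasso_pcr(rng.normal(size=(10, 5)), np.ones(10))  # constant outcome
        with pytest.raises(ValueError):
            fit_lasso_pcr(rng.normal(size=(1, 5)), np.array([1.0]))


class TestLooCV:
    def test_noiseless_mean_r_is_one(self, noiseless_maps):
        cv = es.loo_cv(noiseless_maps, seed=0)
        assert cv.mean_r == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.abs(cv.per_subject_r) <= 1.0 + 1e-12)

    def test_no_leakage_from_held_out_labels(self, noiseless_maps):
        cv = es.loo_cv(noiseless_maps, seed=0)
        s0 = cv.subject_ids[0]
        # corrupt the held-out subject's labels: their predictions are produced
        # by other subjects' fits and must not move
        corrupted = {s: np.array([float(l) for l in noiseless_maps.levels(s)])
                     for s in noiseless_maps.subjects()}
        corrupted[s0] = corrupted[s0][::-1].copy()
        cv2 = es.loo_cv(noiseless_maps, seed=0, outcomes=corrupted)
        assert np.allclose(cv.predictions[s0], cv2.predictions[s0])

    def test_needs_three_subjects(self, noiseless_truth):
        from dataclasses import replace
        tiny = replace(noiseless_truth, n_subjects=2,
                       pattern_gt=noiseless_truth.pattern_gt,
                       pattern_inf=noiseless_truth.pattern_inf)
        maps = es.gen_beta_maps(tiny, seed=1)
        with pytest.raises(ValueError):
            es.loo_cv(maps)


class TestPermutationTest:
    def test_rank_definition_and_determinism(self, noiseless_maps):
        p1, perm1, obs = es.permutation_test(noiseless_maps, n_perm=10, seed=1)
        p2, perm2, _ = es.permutation_test(noiseless_maps, n_perm=10, seed=1)
        assert np.array_equal(perm1, perm2) and p1 == p2
        assert obs == pytest.approx(1.0, abs=1e-9)
        # add-one rank definition holds exactly
        assert p1 == pytest.approx((1.0 + np.sum(perm1 >= obs)) / 11.0)
        assert p1 >= 1.0 / 11.0

    def test_inverted_rank_gives_large_p(self):
        # if observed r falls below all permuted r's, p must approach 1
        rng = np.random.default_rng(0)
        perm = rng.uniform(0.2, 0.9, 99)
        obs = 0.05
        p = (1.0 + np.sum(perm >= obs)) / (99 + 1.0)
        assert p == 1.0


class TestFdrBH:
    def test_degenerate_extremes(self):
        assert es.fdr_bh(np.zeros(5), 0.05).all()
        assert not es.fdr_bh(np.ones(5), 0.05).any()
        assert es.fdr_bh(np.array([]), 0.05).size == 0

    def test_worked_example(self):
        reject = es.fdr_bh(np.array([0.01, 0.02, 0.5, 0.9]), q=0.05)
        assert reject.tolist() == [True, True, False, False]

    @staticmethod
    def brute_force_bh(p, q):
        # literal step-up rule: largest k with p_(k) <= k*q/m, reject smallest k
        m = len(p)
        order = np.argsort(p)
        ranked = np.asarray(p)[order]
        kmax = 0
        for k in range(1, m + 1):
            if ranked[k - 1] <= k * q / m:
                kmax = k
        reject = np.zeros(m, dtype=bool)
        reject[order[:kmax]] = True
        return reject

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        assert np.array_equal(es.fdr_bh(p, 0.05), self.brute_force_bh(p, 0.05))


class TestBootstrapWeights:
    @pytest.fixture(scope="class")
    def block_maps(self):
        # signal lives in the first quarter of voxels only
        n_vox = 120
        pattern = np.zeros(n_vox)
        pattern[:30] = 1.0
        pattern /= np.linalg.norm(pattern)
        other = np.zeros(n_vox)
        other[30:60] = 1.0
        other /= np.linalg.norm(other)
        truth = es.SyntheticTruth(n_subjects=15, n_voxels=n_vox, pattern_cosine=0.0,
                                  noise_sd=0.15, subject_sd=0.1, mixing=0.0,
                                  pattern_gt=pattern, pattern_inf=other, seed=8)
        return truth, es.gen_beta_maps(truth, seed=9)

    def test_signal_voxels_survive_noise_voxels_controlled(self, block_maps):
        truth, maps = block_maps
        res = es.bootstrap_weights(maps, n_boot=120, q=0.05, seed=2)
        signal = truth.pattern_gt > 0
        noise = slice(60, 120)
        assert res.fdr_mask[signal].mean() > 0.9
        assert res.fdr_mask[noise].mean() <= 0.05 + 0.03

    def test_z_sign_matches_mean_and_determinism(self, block_maps):
        _, maps = block_maps
        r1 = es.bootstrap_weights(maps, n_boot=30, seed=5)
        r2 = es.bootstrap_weights(maps, n_boot=30, seed=5)
        assert np.array_equal(r1.z, r2.z)
        nz = r1.z != 0
        assert np.all(np.sign(r1.z[nz]) == np.sign(r1.boot_mean[nz]))


class TestParameterRecoverySNR:
    def test_recovered_cosine_monotone_in_snr(self):
        # averaged over seeds: single fits are noisy at low SNR because the
        # CV-selected penalty can collapse to the null model
        cosines = []
        for noise in (2.5, 1.2, 0.5, 0.1):
            cs = []
            for seed in range(5):
                truth = es.SyntheticTruth(n_subjects=12, n_voxels=300,
                                          noise_sd=noise, subject_sd=0.5,
                                          mixing=0.0, seed=17 + seed)
                maps = es.gen_beta_maps(truth, seed=18 + seed)
                w = es.fit_signature(maps, seed=0).weights
                cs.append(0.0 if np.linalg.norm(w) == 0
                          else abs(es.cosine_similarity(w, truth.pattern_gt)))
            cosines.append(np.mean(cs))
        assert all(b >= a - 0.05 for a, b in zip(cosines, cosines[1:]))
        assert cosines[-1] > 0.95
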