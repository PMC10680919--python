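"""Linear-SVM separability, ROC/AUC equivalences, chance calibration."""

import itertools

import numpy as np
import pytest
from scipy import stats

import emosig as es
from emosig.separability import roc_curve


class TestROC:
    def test_perfect_ordering(self):
        fpr, tpr, auc = roc_curve(np.array([0.1, 0.2, 0.9, 1.4]),
                                  np.array([0, 0, 1, 1]))
        assert auc == 1.0
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        aucs = [roc_curve(rng.normal(size=40), rng.integers(0, 2, 40))[2]
                for _ in range(200)]
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_hand_example_matches_u_statistic(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.2])
        labels = np.array([0, 0, 1, 1, 1, 0])
        _, _, auc = roc_curve(scores, labels)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                               alternative="two-sided").statistic
        assert auc == pytest.approx(u / (3 * 3))

    def test_auc_equals_normalized_u_exhaustive_small_n(self):
        # every label arrangement with n <= 8 samples, scores with ties
        rng = np.random.default_rng(1)
        for n in (4, 6, 8):
            scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
            for ones in itertools.combinations(range(n), n // 2):
                labels = np.zeros(n, dtype=int)
                labels[list(ones)] = 1
                _, _, auc = roc_curve(scores, labels)
                u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                                       alternative="two-sided").statistic
                assert auc == pytest.approx(u / ((n // 2) * (n - n // 2)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([1.0, 2.0]), np.array([1, 1]))


class TestPerLevelSVM:
    def test_well_separated_fixture_perfect_accuracy(self):
        gt_pat = np.r_[np.ones(50), np.zeros(50)] / np.sqrt(50)
        inf_pat = np.r_[np.zeros(50), np.ones(50)] / np.sqrt(50)
        truth = es.SyntheticTruth(n_subjects=12, n_voxels=100, pattern_cosine=0.0,
                                  noise_sd=0.05, subject_sd=0.0, mixing=0.0,
                                  pattern_gt=gt_pat, pattern_inf=inf_pat, seed=1)
        gt = es.gen_beta_maps(truth, condition="ground_truth", seed=2)
        inf = es.gen_beta_maps(truth, condition="inference", seed=3)
        res = es.train_svm_per_level(gt, inf, level=5)
        assert res.accuracy == 1.0
        assert res.auc == 1.0
        assert res.p_binomial < 0.001

    def test_identical_distributions_near_chance(self):
        accs = []
        for seed in range(12):
            truth = es.SyntheticTruth(n_subjects=12, n_voxels=80, effect_gt=0.0,
                                      effect_inf=0.0, mixing=0.0, seed=seed)
            a = es.gen_beta_maps(truth, condition="ground_truth", seed=100 + seed)
            b = es.gen_beta_maps(truth, condition="inference", seed=200 + seed)
            accs.append(es.train_svm_per_level(a, b, level=3).accuracy)
        # both classes drawn from the same generator: binomial band around 0.5
        assert abs(np.mean(accs) - 0.5) < 2 * 0.5 / np.sqrt(24 * 12)

    def test_fold_predictions_ignore_held_out_labels(self, fixture_maps):
        gt, inf = fixture_maps["ground_truth"], fixture_maps["inference"]
        res = es.train_svm_per_level(gt, inf, level=4)
        # flip one subject's map assignment: its fold's training set is
        # unchanged, so its decision values must be identical
        s = res.subjects[0]
        gt2_maps = dict(gt.maps)
        inf2_maps = dict(inf.maps)
        gt2_maps[(s, 4)], inf2_maps[(s, 4)] = inf.maps[(s, 4)], gt.maps[(s, 4)]
        gt2 = es.BetaMapSet(condition="ground_truth", maps=gt2_maps)
        inf2 = es.BetaMapSet(condition="inference", maps=inf2_maps)
        res2 = es.train_svm_per_level(gt2, inf2, level=4)
        i = res.subjects.index(s)
        dv1 = np.sort(res.fold_decision_values[2 * i: 2 * i + 2])
        dv2 = np.sort(res2.fold_decision_values[2 * i: 2 * i + 2])
        assert np.allclose(dv1, dv2)

    def test_single_class_fold_rejected(self):
        from emosig.separability import _loso_svm

        X = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(ValueError):
            _loso_svm(X, np.zeros(4, dtype=int), np.array(["a", "a", "b", "b"]))


class TestAccuracyVsSnr:
    def test_accuracy_non_decreasing_in_snr(self):
        mean_acc = []
        for noise in (3.0, 1.5, 0.7, 0.2):
            accs = []
            for seed in range(3):
                truth = es.SyntheticTruth(n_subjects=10, n_voxels=120,
                                          noise_sd=noise, seed=300 + seed)
                a = es.gen_beta_maps(truth, condition="ground_truth", seed=400 + seed)
                b = es.gen_beta_maps(truth, condition="inference", seed=500 + seed)
                accs.append(es.train_svm_per_level(a, b, level=5).accuracy)
            mean_acc.append(np.mean(accs))
        assert all(b >= a - 0.1 for a, b in zip(mean_acc, mean_acc[1:]))
        # subject random effects (sd 1.0) cap attainable accuracy below 1
        assert mean_acc[-1] > 0.8


class TestBootstrapSVMWeights:
    def test_divergent_voxels_survive_with_correct_sign(self):
        gt_pat = np.r_[np.ones(40), np.zeros(40)] / np.sqrt(40)
        inf_pat = np.r_[np.zeros(40), np.ones(40)] / np.sqrt(40)
        truth = es.SyntheticTruth(n_subjects=14, n_voxels=80, pattern_cosine=0.0,
                                  noise_sd=0.2, subject_sd=0.1, mixing=0.0,
                                  pattern_gt=gt_pat, pattern_inf=inf_pat, seed=4)
        gt = es.gen_beta_maps(truth, condition="ground_truth", seed=5)
        inf = es.gen_beta_maps(truth, condition="inference", seed=6)
        res = es.bootstrap_svm_weights(gt, inf, level=5, n_boot=100, seed=7)
        gap = truth.pattern_gt - truth.pattern_inf  # positive gt-block, negative inf-block
        surviving = res.fdr_mask
        assert surviving[:40].mean() > 0.8 and surviving[40:].mean() > 0.8
        # class 1 = inference: weights negative where gt dominates
        assert np.all(np.sign(res.boot_mean[surviving]) == -np.sign(gap[surviving]))
        res2 = es.bootstrap_svm_weights(gt, inf, level=5, n_boot=100, seed=7)
        assert np.array_equal(res.z, res2.z)


class TestModelVsAccuracyMaps:
    def test_distinct_structure_separable_identical_not(self, fixture_truth, fixture_maps):
        ea = es.gen_accuracy_maps(fixture_truth, seed=90)
        results = es.classify_vs_accuracy_maps(fixture_maps["ground_truth"], ea)
        assert set(results) == {(l, t) for l in range(1, 6) for t in ("low", "high")}
        high_level = results[(5, "high")]
        assert high_level.accuracy > 0.5
        assert set(np.unique(high_level.labels)) == {0, 1}
        # same generator on both sides: near chance
        a = es.gen_beta_maps(fixture_truth, condition="ground_truth", seed=91)
        null = es.train_svm_per_level(fixture_maps["ground_truth"], a, level=3)
        assert 0.2 <= null.accuracy <= 0.8


class TestChanceCalibration:
    def test_label_permutation_distribution_covers_half(self, fixture_maps):
        # permute which member of each pair is called "ground truth"
        from emosig.separability import _loso_svm, _stack_pair

        X, y, groups, _ = _stack_pair(fixture_maps["ground_truth"],
                                      fixture_maps["inference"], 2)
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(50):
            y_perm = y.copy()
            flips = rng.random(len(groups) // 2) < 0.5
            for j, flip in enumerate(flips):
                if flip:
                    y_perm[2 * j: 2 * j + 2] = y_perm[2 * j: 2 * j + 2][::-1]
            preds, _ = _loso_svm(X, y_perm, groups)
            accs.append(np.mean(preds == y_perm))
        lo, hi = np.quantile(accs, [0.025, 0.975])
        assert lo <= 0.5 <= hi
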