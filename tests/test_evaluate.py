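import numpy as np
import pytest
from scipy import stats as scipy_stats

from strokegraph import (ConfigurationError, InputError, NoiseSpec, accuracy,
                         add_awgn, confusion_counts, dsc, fold_significance,
                         jaccard, metrics_from_counts, patient_kfold,
                         precision, roc_curve, sensitivity)


def _random_masks(rng, shape=(16, 16)):
    return ((rng.random(shape) > 0.5).astype(np.uint8),
            (rng.random(shape) > 0.7).astype(np.uint8))


class TestConfusionAndMetrics:
    def test_identical_masks_are_perfect(self, rng):
        m = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        m[0, 0] = 1  # non-empty
        tp, fp, fn, tn = confusion_counts(m, m)
        assert fp == fn == 0 and tp + tn == 100
        for fn_metric in (dsc, jaccard, sensitivity, precision, accuracy):
            assert fn_metric(m, m) == 1.0

    def test_counts_match_pixel_loop_oracle(self, rng):
        pred, truth = _random_masks(rng)
        tp = fp = fn = tn = 0
        for p, t in zip(pred.ravel(), truth.ravel()):
            tp += p and t
            fp += p and not t
            fn += (not p) and t
            tn += (not p) and (not t)
        assert confusion_counts(pred, truth) == (tp, fp, fn, tn)
        assert sum(confusion_counts(pred, truth)) == pred.size

    def test_half_overlap_square(self):
        n = 8
        pred = np.zeros((n, n), dtype=np.uint8)
        truth = np.zeros((n, n), dtype=np.uint8)
        pred[:, : n // 2] = 1   # left half
        truth[: n // 2, :] = 1  # top half
        assert dsc(pred, truth) == 0.5
        assert jaccard(pred, truth) == pytest.approx(1 / 3)
        assert sensitivity(pred, truth) == 0.5
        assert precision(pred, truth) == 0.5
        assert accuracy(pred, truth) == 0.5

    def test_disjoint_masks_score_zero(self):
        pred = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        truth = np.array([[0, 0], [0, 1]], dtype=np.uint8)
        assert dsc(pred, truth) == 0.0 and jaccard(pred, truth) == 0.0

    def test_empty_reference_conventions(self):
        empty = np.zeros((4, 4), dtype=np.uint8)
        some = np.eye(4, dtype=np.uint8)
        assert dsc(empty, empty) == 1.0
        assert sensitivity(some, empty) == 1.0   # no true lesion to find
        assert precision(empty, some) == 1.0     # no positive predictions
        tp, fp, fn, tn = confusion_counts(empty, empty)
        assert tp == 0 and tn == 16

    def test_dice_jaccard_identity_on_pooled_counts(self, rng):
        for _ in range(20):
            pred, truth = _random_masks(rng)
            d = dsc(pred, truth)
            assert jaccard(pred, truth) == pytest.approx(d / (2 - d))
        report = metrics_from_counts(12, 3, 5, 100)
        assert report.jaccard == pytest.approx(report.dsc / (2 - report.dsc))
        for v in (report.dsc, report.jaccard, report.sensitivity,
                  report.precision, report.accuracy):
            assert 0.0 <= v <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestRoc:
    def test_perfect_separation_auc_one(self):
        labels = np.array([0, 0, 0, 1, 1])
        probs = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        *_, auc = roc_curve(probs, labels)
        assert auc == 1.0

    def test_permuted_labels_auc_near_half(self, rng):
        probs = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        *_, auc = roc_curve(probs, labels)
        assert abs(auc - 0.5) < 0.05

    def test_auc_equals_mann_whitney_statistic(self, rng):
        for _ in range(5):
            probs = rng.random(60)
            labels = rng.integers(0, 2, 60)
            if len(np.unique(labels)) < 2:
                continue
            *_, auc = roc_curve(probs, labels)
            u = scipy_stats.mannwhitneyu(probs[labels == 1], probs[labels == 0],
                                         alternative="two-sided").statistic
            n1, n0 = (labels == 1).sum(), (labels == 0).sum()
            assert auc == pytest.approx(u / (n1 * n0))

    def test_monotone_transform_invariance(self, rng):
        probs = rng.random(50)
        labels = (probs + 0.3 * rng.standard_normal(50) > 0.5).astype(int)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        *_, a1 = roc_curve(probs, labels)
        *_, a2 = roc_curve(probs ** 3, labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_error_names_missing_class(self):
        with pytest.raises(InputError, match="class 1"):
            roc_curve(np.array([0.2, 0.4]), np.array([0, 0]))


class TestPatientKfold:
    def test_ten_patients_ten_folds_one_each(self):
        folds = patient_kfold([f"p{i}" for i in range(10)], k=10, seed=0)
        counts = np.bincount(list(folds.mapping.values()), minlength=10)
        assert counts.tolist() == [1] * 10

    def test_partition_no_patient_in_two_folds(self, rng):
        ids = [f"p{i}" for i in range(17)]
        folds = patient_kfold(ids, k=5, seed=3)
        assert sorted(folds.mapping) == sorted(ids)
        all_fold_members = [p for f in range(5) for p in folds.patients_in_fold(f)]
        assert sorted(all_fold_members) == sorted(ids)

    def test_23_patients_10_folds_size_multiset(self):
        folds = patient_kfold([f"p{i:02d}" for i in range(23)], k=10, seed=1)
        sizes = sorted(np.bincount(list(folds.mapping.values()), minlength=10))
        assert sizes == [2] * 7 + [3] * 3

    def test_deterministic_under_seed_and_input_order(self, rng):
        ids = [f"p{i}" for i in range(12)]
        shuffled = list(rng.permutation(ids))
        assert patient_kfold(ids, 4, seed=9).mapping == \
            patient_kfold(shuffled, 4, seed=9).mapping

    def test_too_many_folds_rejected(self):
        with pytest.raises(ConfigurationError):
            patient_kfold(["a", "b"], k=3)


class TestAddAwgn:
    def test_realized_snr_within_tolerance(self, rng):
        image = rng.uniform(20, 100, size=(256, 256))
        for target in (-4, 0, 5):
            noisy = add_awgn(image, NoiseSpec(snr_db=target, seed=42))
            p_noise = np.mean((noisy - image) ** 2)
            realized = 10 * np.log10(np.mean(image ** 2) / p_noise)
            assert abs(realized - target) < 0.2

    def test_zero_db_equalizes_powers(self, rng):
        image = rng.uniform(20, 100, size=(256, 256))
        noisy = add_awgn(image, NoiseSpec(snr_db=0.0, seed=7))
        ratio = np.mean((noisy - image) ** 2) / np.mean(image ** 2)
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_high_snr_limit_vanishing_noise(self, rng):
        image = rng.uniform(20, 100, size=(64, 64))
        noisy = add_awgn(image, NoiseSpec(snr_db=120.0, seed=1))
        assert np.max(np.abs(noisy - image)) < 1e-3 * image.max()

    def test_all_zero_image_rejected(self):
        with pytest.raises(InputError):
            add_awgn(np.zeros((8, 8)), NoiseSpec(snr_db=0.0))


class TestFoldSignificance:
    def test_equal_folds_sentinel(self):
        a = np.linspace(0.5, 0.9, 10)
        assert fold_significance(a, a) == (1.0, 1.0)

    def test_constant_shift_degenerate_t_flagged(self):
        a = np.full(10, 0.8)
        t_p, w_p = fold_significance(a, a - 0.05)
        assert t_p == 0.0  # infinite t statistic sentinel
        assert w_p < 0.05

    def test_matches_hand_computed_references(self):
        a = np.array([0.71, 0.74, 0.69, 0.81, 0.77, 0.73, 0.75, 0.70, 0.79, 0.76])
        b = np.array([0.68, 0.75, 0.66, 0.78, 0.74, 0.70, 0.76, 0.65, 0.77, 0.72])
        t_p, w_p = fold_significance(a, b)
        # paired t from the closed-form statistic
        d = a - b
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t_ref = 2 * scipy_stats.t.sf(abs(t_stat), df=len(d) - 1)
        assert t_p == pytest.approx(t_ref)
        # Wilcoxon signed-rank p by exhaustive sign enumeration
        ranks = scipy_stats.rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        n = len(d)
        for bits in range(2 ** n):
            signs = [(bits >> i) & 1 for i in range(n)]
            w_plus = sum(r for r, s in zip(ranks, signs) if s)
            if min(w_plus, ranks.sum() - w_plus) <= w_obs:
                count += 1
        assert w_p == pytest.approx(count / 2 ** n)

    def test_too_few_folds_rejected(self):
        with pytest.raises(InputError):
            fold_significance([1, 2], [2, 3])
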