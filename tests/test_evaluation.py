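"""LOOCV harness, metrics, permutation test, Holm, and McNemar."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from kernelfuse import (
    CVResult,
    KernelSVC,
    ValidationError,
    compute_bsmca,
    holm_bonferroni,
    loocv,
    mcnemar,
    permutation_test,
    pooled_mcnemar,
)


class ConstantClassifier(BaseEstimator, ClassifierMixin):
    """Always predicts +1; decision value +1."""

    def fit(self, Ks, y):
        return self

    def decision_function(self, Ks_cross):
        return np.ones(np.asarray(Ks_cross).shape[1])

    def predict(self, Ks_cross):
        return np.ones(np.asarray(Ks_cross).shape[1], dtype=int)


class TestMetrics:
    def test_accuracy_is_exact_fraction(self):
        y = np.repeat([1, -1], 19)
        pred = y.copy()
        pred[:12] *= -1  # 12 of the 19 positives wrong -> 26/38 correct
        res = CVResult(tuple(range(38)), y, pred)
        assert res.accuracy == 26 / 38
        assert round(100 * res.accuracy, 2) == 68.42

    def test_balanced_accuracy_is_mean_of_sensitivity_specificity(self):
        # sensitivity 11/19 = 57.89%, specificity 13/19 = 68.42%
        y = np.repeat([1, -1], 19)
        pred = y.copy()
        pred[:8] *= -1  # 8 positives wrong
        pred[19:25] *= -1  # 6 negatives wrong
        res = CVResult(tuple(range(38)), y, pred)
        assert round(100 * res.sensitivity, 2) == 57.89
        assert round(100 * res.specificity, 2) == 68.42
        assert round(100 * res.balanced_accuracy, 2) == 63.16
        assert res.balanced_accuracy == (res.sensitivity + res.specificity) / 2

    def test_equal_groups_identity_holds_on_every_result(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = np.repeat([1, -1], 10)
            pred = rng.choice([-1, 1], size=20)
            res = CVResult(tuple(range(20)), y, pred)
            assert res.accuracy == pytest.approx(res.balanced_accuracy, abs=1e-12)


class TestLOOCV:
    def test_separated_clusters_are_perfectly_classified(self):
        x = np.array([[-10.2], [-9.9], [10.1], [9.8]])
        y = np.array([-1, -1, 1, 1])
        res = loocv(KernelSVC(), (x @ x.T)[None], y)
        assert res.accuracy == 1.0

    def test_fold_collapsing_to_one_class_is_named(self):
        x = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1, 1, -1])
        with pytest.raises(ValidationError, match="s002"):
            loocv(KernelSVC(), (x @ x.T)[None], y)

    def test_slicing_equals_recomputing_per_fold(self, tiny_dataset):
        # for linear kernels, rows/cols of the full-data kernel are the
        # fold kernel; cross-check the harness against explicit refits
        ds = tiny_dataset
        K = ds.kernel("m1", normalize=True).values
        res = loocv(KernelSVC(), K[None], ds.labels, subject_ids=ds.subject_ids)
        m = ds.n_subjects
        X = ds.modalities["m1"]
        Xu = X / np.linalg.norm(X, axis=1, keepdims=True)
        for i in range(m):
            tr = np.arange(m) != i
            model = KernelSVC().fit(Xu[tr] @ Xu[tr].T, ds.labels[tr])
            f = model.decision_function(Xu[[i]] @ Xu[tr].T)[0]
            assert abs(f - res.decision_values[i]) < 1e-8

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            loocv(KernelSVC(), np.eye(2)[None], np.array([1, -1]))


class TestPermutationTest:
    def test_separable_data_get_zero_p(self):
        x = np.concatenate([np.linspace(-12, -9, 6), np.linspace(9, 12, 6)])[:, None]
        y = np.repeat([-1, 1], 6)
        perm = permutation_test(KernelSVC(), (x @ x.T)[None], y, n_perm=100, seed=0)
        assert perm.true_accuracy == 1.0
        assert perm.p_value == 0.0

    def test_constant_classifier_is_never_significant(self):
        y = np.repeat([1, -1], 5)
        perm = permutation_test(ConstantClassifier(), np.eye(10)[None], y, n_perm=50, seed=0)
        assert perm.true_accuracy == 0.5
        assert perm.p_value == 1.0

    def test_p_value_invariant_to_global_label_flip(self, rng):
        X = rng.normal(size=(12, 30))
        y = np.repeat([1, -1], 6)
        K = (X @ X.T)[None]
        p1 = permutation_test(KernelSVC(), K, y, n_perm=30, seed=4).p_value
        p2 = permutation_test(KernelSVC(), K, -y, n_perm=30, seed=4).p_value
        assert p1 == p2

    def test_replicates_are_seed_deterministic(self, rng):
        X = rng.normal(size=(10, 8))
        y = np.repeat([1, -1], 5)
        a = permutation_test(KernelSVC(), (X @ X.T)[None], y, n_perm=20, seed=9)
        b = permutation_test(KernelSVC(), (X @ X.T)[None], y, n_perm=20, seed=9)
        assert np.array_equal(a.null_accuracies, b.null_accuracies)

    def test_plus_one_variant(self):
        y = np.repeat([1, -1], 5)
        perm = permutation_test(ConstantClassifier(), np.eye(10)[None], y, n_perm=49, seed=0, plus_one=True)
        assert perm.p_value == 1.0  # (49 + 1) / (49 + 1)


class TestHolmBonferroni:
    def test_step_down_stops_at_first_failure(self):
        reject, adjusted = holm_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
        # thresholds 0.05/3, 0.05/2, 0.05: 0.01 rejected, 0.03 > 0.025 stops
        assert reject.tolist() == [True, False, False]
        assert np.allclose(adjusted, [0.03, 0.06, 0.06])

    def test_single_p_reduces_to_plain_comparison(self):
        reject, adjusted = holm_bonferroni([0.04], alpha=0.05)
        assert reject.tolist() == [True] and adjusted[0] == 0.04

    def test_all_ones(self):
        reject, adjusted = holm_bonferroni([1.0, 1.0, 1.0])
        assert not reject.any() and (adjusted == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_bonferroni([0.2, 1.4])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_rejects_superset_of_plain_bonferroni(self, ps):
        reject, _ = holm_bonferroni(ps, alpha=0.05)
        bonf = np.asarray(ps) <= 0.05 / len(ps)
        assert (reject | ~bonf).all()


def _preds_with_discordance(b, c, n_extra=4):
    """Build (preds_a, preds_b, truth) with exactly (b, c) discordant pairs."""
    n = b + c + n_extra
    truth = np.ones(n, dtype=int)
    a = np.ones(n, dtype=int)
    bb = np.ones(n, dtype=int)
    bb[:b] = -1  # a right, b wrong
    a[b : b + c] = -1  # a wrong, b right
    return a, bb, truth


class TestMcNemar:
    def test_exact_two_sided_example(self):
        res = mcnemar(*_preds_with_discordance(8, 2))
        assert res.method == "exact"
        assert (res.b, res.c) == (8, 2)
        assert res.p_value == 0.109375

    def test_balanced_discordance_caps_at_one(self):
        assert mcnemar(*_preds_with_discordance(5, 5)).p_value == 1.0

    def test_no_discordant_pairs_flagged(self):
        res = mcnemar(*_preds_with_discordance(0, 0))
        assert res.p_value == 1.0 and "no discordant pairs" in res.note

    def test_symmetry_in_classifier_order(self, rng):
        for _ in range(10):
            truth = rng.choice([-1, 1], size=30)
            a = rng.choice([-1, 1], size=30)
            b = rng.choice([-1, 1], size=30)
            r1, r2 = mcnemar(a, b, truth), mcnemar(b, a, truth)
            assert (r1.b, r1.c) == (r2.c, r2.b)
            assert r1.p_value == r2.p_value

    @pytest.mark.parametrize("b,c", [(b, c) for b in range(6) for c in range(6) if 0 < b + c <= 10])
    def test_exact_branch_agrees_with_statsmodels(self, b, c):
        ours = mcnemar(*_preds_with_discordance(b, c))
        table = [[3, b], [c, 3]]
        ref = sm_mcnemar(table, exact=True)
        assert ours.p_value == pytest.approx(min(1.0, ref.pvalue), abs=1e-12)

    def test_large_counts_use_continuity_corrected_chi2(self):
        ours = mcnemar(*_preds_with_discordance(20, 10))
        ref = sm_mcnemar([[3, 20], [10, 3]], exact=False, correction=True)
        assert ours.method == "chi2"
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mcnemar([1, -1], [1], [1, -1])


class TestPooledMcNemar:
    def test_single_context_identical_to_mcnemar(self, rng):
        truth = rng.choice([-1, 1], size=20)
        a = rng.choice([-1, 1], size=20)
        b = rng.choice([-1, 1], size=20)
        assert pooled_mcnemar([(a, b, truth)]).p_value == mcnemar(a, b, truth).p_value

    def test_discordance_adds_across_contexts(self):
        ctx1 = _preds_with_discordance(3, 1)
        ctx2 = _preds_with_discordance(5, 1)
        res = pooled_mcnemar([ctx1, ctx2])
        assert (res.b, res.c) == (8, 2)
        assert res.p_value == 0.109375

    def test_identical_classifiers_are_not_distinguishable(self, rng):
        truth = rng.choice([-1, 1], size=15)
        a = rng.choice([-1, 1], size=15)
        res = pooled_mcnemar([(a, a, truth), (a, a, truth)])
        assert (res.b, res.c) == (0, 0) and res.p_value == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            pooled_mcnemar([])


class TestBSMCA:
    def _result(self, acc, n=38):
        y = np.repeat([1, -1], n // 2)
        pred = y.copy()
        wrong = round(n * (1 - acc))
        # distribute errors evenly over classes to keep groups balanced
        pred[: wrong // 2] *= -1
        pred[n // 2 : n // 2 + (wrong - wrong // 2)] *= -1
        return CVResult(tuple(range(n)), y, pred)

    def test_best_kernel_from_table_values(self):
        results = {"sMRI": self._result(26 / 38), "DTI": self._result(25 / 38)}
        best = compute_bsmca(results, ("sMRI", "DTI"))
        assert best.kernel == "sMRI"
        assert round(100 * best.accuracy, 2) == 68.42

    def test_single_kernel_combination(self):
        results = {"a": self._result(0.6)}
        assert compute_bsmca(results, ("a",)).kernel == "a"

    def test_exact_tie_takes_first_in_canonical_order(self):
        results = {"a": self._result(0.7), "b": self._result(0.7)}
        best = compute_bsmca(results, ("b", "a"))
        assert best.kernel == "b" and best.tied

    def test_missing_result_rejected(self):
        with pytest.raises(ValidationError, match="dti"):
            compute_bsmca({"smri": self._result(0.6)}, ("smri", "dti"))
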