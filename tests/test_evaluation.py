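"""Accuracy measures, split/CV protocols, and rank-based AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import encoded_from_arrays

from sumohunt.evaluation import (
    ConfusionCounts,
    compute_metrics,
    evaluate_split,
    forest_trainer,
    k_fold_cv,
    k_fold_plan,
    loocv,
    percentage_split,
    roc_auc,
    self_consistency,
    window_sweep,
)
from sumohunt.errors import MetricsError, SplitError


class TestComputeMetrics:
    def test_worked_example_93_split(self):
        # 23 positives all correct, 17 of 18 negatives correct.
        report = compute_metrics(ConfusionCounts(tp=23, fp=1, tn=17, fn=0))
        assert report.sn == pytest.approx(100.0)
        assert report.sp == pytest.approx(94.44, abs=0.01)
        assert report.ac == pytest.approx(97.56, abs=0.01)
        assert report.mcc == pytest.approx(0.95, abs=0.005)

    def test_perfect_prediction(self):
        report = compute_metrics(ConfusionCounts(10, 0, 10, 0))
        assert (report.ac, report.mcc) == (100.0, 1.0)

    def test_chance_symmetry(self):
        assert compute_metrics(ConfusionCounts(5, 5, 5, 5)).mcc == 0.0

    def test_inverse_prediction(self):
        assert compute_metrics(ConfusionCounts(0, 5, 0, 5)).mcc == -1.0

    def test_zero_mcc_denominator_convention(self):
        # No predicted positives: (TP+FP)=0 -> MCC defined as 0.
        report = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert report.mcc == 0.0
        assert report.sn == 0.0 and report.sp == 100.0

    def test_all_zero_counts_error(self):
        with pytest.raises(MetricsError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_missing_class_errors(self):
        with pytest.raises(MetricsError):
            compute_metrics(ConfusionCounts(0, 5, 5, 0))  # no true positives+fn
        with pytest.raises(MetricsError):
            compute_metrics(ConfusionCounts(5, 0, 0, 5))  # no true negatives+fp

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(deadline=None, derandomize=True)
    def test_identities(self, tp, fp, tn, fn):
        if tp + fn == 0 or tn + fp == 0:
            return
        report = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        fn_rate = 100.0 * fn / (tp + fn)
        assert report.sn + fn_rate == pytest.approx(100.0)
        assert -1.0 <= report.mcc <= 1.0
        if fp == 0 and fn == 0 and tp > 0 and tn > 0:
            assert report.mcc == pytest.approx(1.0)
        if tp == 0 and tn == 0 and fp > 0 and fn > 0:
            assert report.mcc == pytest.approx(-1.0)


class TestPercentageSplit:
    def _dataset(self, n):
        rng = np.random.default_rng(0)
        y = np.arange(n) % 2 == 0
        return encoded_from_arrays(rng.normal(size=(n, 2)), y)

    def test_sizes_584_at_93(self):
        plan = percentage_split(self._dataset(584), 93, seed=0)
        assert (len(plan.train), len(plan.test)) == (543, 41)

    def test_even_halves(self):
        plan = percentage_split(self._dataset(10), 50, seed=1)
        assert (len(plan.train), len(plan.test)) == (5, 5)

    def test_train_pct_100_rejected(self):
        with pytest.raises(SplitError):
            percentage_split(self._dataset(10), 100, seed=0)

    def test_partition_of_indices(self):
        n = 97
        plan = percentage_split(self._dataset(n), 80, seed=3)
        assert sorted(plan.train + plan.test) == list(range(n))


class TestKFold:
    def test_folds_partition_indices(self):
        plans = k_fold_plan(23, 5, seed=4)
        test_sets = [set(p.test) for p in plans]
        assert sorted(i for s in test_sets for i in s) == list(range(23))
        for p in plans:
            assert set(p.train).isdisjoint(set(p.test))
            assert sorted(p.train + p.test) == list(range(23))

    def test_k_equals_n_matches_loocv_structure(self):
        plans = k_fold_plan(9, 9, seed=0)
        assert all(len(p.test) == 1 for p in plans)
        assert sorted(i for p in plans for i in p.test) == list(range(9))

    def test_pooled_counts_match_brute_recount(self):
        # Deterministic stub scorer: positive iff feature0 > 0.
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 1))
        y = rng.random(30) > 0.4
        data = encoded_from_arrays(X, y)

        def stub_trainer(train, seed):
            return lambda M: (M[:, 0] > 0).astype(float)

        report, _ = k_fold_cv(data, 6, stub_trainer, seed=2)
        predicted = X[:, 0] > 0
        assert report.counts.tp == int(np.sum(y & predicted))
        assert report.counts.tn == int(np.sum(~y & ~predicted))
        assert report.counts.fp == int(np.sum(~y & predicted))
        assert report.counts.fn == int(np.sum(y & ~predicted))

    def test_loocv_is_k_equals_n(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 2))
        y = np.arange(12) % 2 == 0
        data = encoded_from_arrays(X, y)

        def stub_trainer(train, seed):
            return lambda M: (M[:, 0] > 0).astype(float)

        full, _ = k_fold_cv(data, 12, stub_trainer, seed=7)
        jack = loocv(data, stub_trainer, seed=7)
        assert jack.counts == full.counts
        assert jack.protocol == "loocv"


class TestSelfConsistency:
    def test_memorizing_stub_is_perfect(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        y = np.arange(20) % 2 == 0
        data = encoded_from_arrays(X, y)
        lookup = {tuple(row): float(lab) for row, lab in zip(X, y)}

        def memorizer(train, seed):
            return lambda M: np.array([lookup[tuple(r)] for r in M])

        report = self_consistency(data, memorizer, seed=0)
        assert report.ac == 100.0 and report.mcc == 1.0

    def test_constant_positive_classifier(self):
        data = encoded_from_arrays(np.zeros((10, 1)), np.arange(10) % 2 == 0)

        def constant(train, seed):
            return lambda M: np.ones(len(M))

        report = self_consistency(data, constant, seed=0)
        assert report.sn == 100.0 and report.sp == 0.0


class TestRocAuc:
    def test_perfect_separation(self):
        auc, points = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == 1.0
        assert points[-1].tolist() == [1.0, 1.0]

    def test_all_scores_tied(self):
        auc, _ = roc_auc([0.5] * 6, [True, False, True, False, True, False])
        assert auc == 0.5

    def test_three_of_four_pairs_concordant(self):
        auc, _ = roc_auc([0.9, 0.8, 0.4, 0.3], [True, False, True, False])
        assert auc == pytest.approx(0.75)

    def test_single_class_error(self):
        with pytest.raises(MetricsError):
            roc_auc([0.1, 0.9], [True, True])

    @given(
        st.lists(
            st.tuples(st.floats(0, 1, allow_nan=False), st.booleans()),
            min_size=4,
            max_size=40,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_pair_count_agreement_and_inversion(self, pairs):
        scores = np.array([p[0] for p in pairs])
        truth = np.array([p[1] for p in pairs])
        if truth.all() or not truth.any():
            return
        auc, _ = roc_auc(scores, truth)
        # Brute force over all positive-negative pairs with half-credit ties.
        pos = scores[truth]
        neg = scores[~truth]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))
        inv, _ = roc_auc(-scores, truth)
        assert inv == pytest.approx(1.0 - auc)
        # scaling by a power of two is exact, hence strictly monotone
        mono, _ = roc_auc(4.0 * scores, truth)
        assert mono == pytest.approx(auc)

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        scores = rng.random(200).round(2)  # force ties
        truth = rng.random(200) > 0.6
        auc, _ = roc_auc(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores))


@pytest.fixture(scope="module")
def small_benchmark():
    from sumohunt.synthetic import make_benchmark

    _, encoded = make_benchmark(60, 60, seed=0, encode_flank=3)
    return encoded


class TestEndToEndProtocols:
    def test_evaluate_split_reports_auc(self, small_benchmark):
        report = evaluate_split(small_benchmark, 80, forest_trainer(10), seed=0)
        assert 0.0 <= report.auc <= 1.0
        assert report.counts.total == 24

    def test_window_sweep_shape_and_determinism(self):
        from sumohunt.aaindex import load_property_table
        from sumohunt.dataset import trim
        from sumohunt.encoding import encode_dataset
        from sumohunt.synthetic import make_benchmark

        windows, _ = make_benchmark(40, 40, seed=1)
        table = load_property_table()
        datasets = {
            f: encode_dataset(trim(windows, f), table) for f in (3, 5, 10)
        }
        sweep1 = window_sweep(datasets, forest_trainer(10), seed=0, train_pct=80)
        sweep2 = window_sweep(datasets, forest_trainer(10), seed=0, train_pct=80)
        assert list(sweep1["window"]) == [7, 11, 21]
        assert {"+train", "-train", "+test", "-test"} <= set(sweep1.columns)
        assert sweep1.equals(sweep2)
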