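"""Splits, confusion metrics, ROC-AUC and significance machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from fswolf.metrics import (
    ConfusionCounts,
    SplitSpec,
    compare_models,
    confusion,
    grid_search,
    metrics,
    roc_auc,
    split_dataset,
    split_indices,
)


class TestSplits:
    def test_balanced_100_gives_60_20_20(self):
        labels = np.array([0] * 50 + [1] * 50)
        tr, va, te = split_indices(labels, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (60, 20, 20)
        for idx in (tr, va, te):
            vals, counts = np.unique(labels[idx], return_counts=True)
            assert counts[0] == counts[1]

    def test_partition_exact_and_deterministic(self):
        labels = np.array([0] * 17 + [1] * 23)
        tr, va, te = split_indices(labels, SplitSpec(seed=5))
        union = np.sort(np.concatenate([tr, va, te]))
        assert np.array_equal(union, np.arange(40))
        tr2, va2, te2 = split_indices(labels, SplitSpec(seed=5))
        assert np.array_equal(tr, tr2) and np.array_equal(va, va2) and np.array_equal(te, te2)

    def test_stratification_within_one_sample(self):
        labels = np.array([0] * 31 + [1] * 29)
        tr, va, te = split_indices(labels, SplitSpec(seed=1))
        for idx, frac in ((tr, 0.6), (va, 0.2), (te, 0.2)):
            for c, n_c in ((0, 31), (1, 29)):
                got = int((labels[idx] == c).sum())
                assert abs(got - frac * n_c) <= 1

    def test_small_class_rejected(self, tiny_dataset):
        small = tiny_dataset.subset(range(4))
        with pytest.raises(ValueError):
            split_dataset(small, SplitSpec(seed=0))


class TestConfusion:
    def test_all_correct(self):
        y = np.array([1] * 10 + [0] * 10)
        c = confusion(y, y)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_inversion_swaps_counts(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=30)
        p = rng.integers(0, 2, size=30)
        c = confusion(y, p)
        ci = confusion(y, 1 - p)
        assert (c.tp, c.fn) == (ci.fn, ci.tp)
        assert (c.tn, c.fp) == (ci.fp, ci.tn)

    def test_hand_tally(self):
        y = np.array([1, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        p = np.array([1, 0, 0, 1, 1, 0, 1, 0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 0, 1, 1])
        c = confusion(y, p)
        assert (c.tp, c.fn, c.tn, c.fp) == (7, 3, 7, 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [1])


class TestMetrics:
    def test_worked_case(self):
        rep = metrics(ConfusionCounts(tp=9, fp=1, tn=9, fn=1))
        assert rep.precision == pytest.approx(0.9)
        assert rep.recall == pytest.approx(0.9)
        assert rep.f1 == pytest.approx(0.9)
        assert rep.accuracy == pytest.approx(0.9)

    def test_perfect_classifier(self):
        rep = metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert (rep.precision, rep.recall, rep.f1, rep.accuracy) == (1.0, 1.0, 1.0, 1.0)

    def test_undefined_precision_flagged(self):
        rep = metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=2))
        assert rep.precision is None
        assert "precision_undefined" in rep.flags
        assert rep.accuracy == pytest.approx(4 / 6)

    def test_exhaustive_sweep_against_hand_formulas(self):
        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            rep = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            assert rep.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            if tp + fp > 0:
                assert rep.precision == pytest.approx(tp / (tp + fp))
            else:
                assert rep.precision is None
            if tp + fn > 0:
                assert rep.recall == pytest.approx(tp / (tp + fn))
            else:
                assert rep.recall is None
            if rep.precision is not None and rep.recall is not None and rep.precision + rep.recall > 0:
                assert rep.f1 == pytest.approx(
                    2 * rep.precision * rep.recall / (rep.precision + rep.recall)
                )


def _auc_bruteforce(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=1000)
        labels = rng.integers(0, 2, size=1000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.05

    def test_equals_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                _auc_bruteforce(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(size=50)
        labels = (rng.uniform(size=50) < scores).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(np.exp(5 * scores), labels) == pytest.approx(
            roc_auc(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCompareModels:
    def test_identical_vectors_degenerate(self):
        rep = compare_models([0.8] * 6, [0.8] * 6)
        assert rep.mean_difference == 0.0
        assert rep.p_value == 1.0
        assert "constant_zero_differences" in rep.flags

    def test_clear_shift_significant(self):
        rng = np.random.default_rng(0)
        b = 0.7 + 0.01 * rng.standard_normal(10)
        a = b + 1.0 + 0.01 * rng.standard_normal(10)
        rep = compare_models(a, b)
        assert rep.p_value < 0.01
        assert rep.mean_difference == pytest.approx(1.0, abs=0.02)
        assert rep.ci_low < 1.0 < rep.ci_high

    def test_gate_consistency_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(6, 15))
            a = rng.standard_normal(n)
            b = a + rng.choice([0.0, 0.5]) + 0.3 * rng.standard_normal(n)
            rep = compare_models(a, b)
            if rep.shapiro_p is None:
                assert rep.test_name in ("sign", "degenerate")
            elif rep.shapiro_p > 0.05:
                assert rep.test_name == "paired_t"
            else:
                assert rep.test_name == "wilcoxon"
            # cross-check p-value against scipy directly
            diff_test = (
                stats.ttest_rel(a, b) if rep.test_name == "paired_t" else None
            )
            if diff_test is not None:
                assert rep.p_value == pytest.approx(float(diff_test.pvalue))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            compare_models([1, 2, 3], [1, 2, 3])


class TestGridSearch:
    def test_single_point_grid(self):
        labels = np.array([0, 1] * 10)
        cfg, table = grid_search(labels, [{"learning_rate": 1e-3, "batch_size": 32}],
                                 lambda c, f, v: 0.8, folds=5)
        assert cfg == {"learning_rate": 1e-3, "batch_size": 32}
        assert len(table) == 1

    def test_planted_optimum_wins(self):
        labels = np.array([0, 1] * 15)
        grid = [
            {"learning_rate": lr, "batch_size": bs}
            for lr in (1e-4, 1e-3)
            for bs in (32, 64)
        ]

        def trainer(cfg, fit_idx, val_idx):
            return 0.9 if (cfg["learning_rate"], cfg["batch_size"]) == (1e-3, 64) else 0.6

        winner, _ = grid_search(labels, grid, trainer, folds=5)
        assert (winner["learning_rate"], winner["batch_size"]) == (1e-3, 64)

    def test_full_grid_logged(self):
        labels = np.array([0, 1] * 10)
        calls = []

        def trainer(cfg, fit_idx, val_idx):
            calls.append(cfg)
            return 0.5

        grid = [{"learning_rate": lr, "batch_size": b} for lr in (1e-4, 1e-3, 1e-2) for b in (32, 64, 128)]
        _, table = grid_search(labels, grid, trainer, folds=5)
        assert len(calls) == 9 * 5
        assert len(table) == 9

    def test_tiebreak_lower_lr_then_smaller_batch(self):
        labels = np.array([0, 1] * 10)
        grid = [
            {"learning_rate": 1e-2, "batch_size": 64},
            {"learning_rate": 1e-3, "batch_size": 128},
            {"learning_rate": 1e-3, "batch_size": 32},
        ]
        winner, _ = grid_search(labels, grid, lambda c, f, v: 0.7, folds=5)
        assert (winner["learning_rate"], winner["batch_size"]) == (1e-3, 32)
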