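import numpy as np
import pandas as pd
import pytest

from ctrss import (
    AggregationLevel,
    GridConfig,
    ModelFamily,
    ModelSpec,
    SelectionMethod,
    SplitConfig,
    auc,
    bootstrap_ci,
    derive_seed,
    holdout_split,
    learning_curve,
    pivot,
    reduce_training,
    reduction_ladder,
    roc_result,
    run_grid,
)
from ctrss.evaluation import EvaluationError, _auc_rows, roc_points
from ctrss.feature_matrix import FeatureMatrix


def pair_counting_auc(scores, labels):
    """Independent oracle: concordant pairs with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg))


def random_instance(rng, heavy_ties=False):
    n = int(rng.integers(4, 60))
    labels = np.zeros(n, dtype=bool)
    labels[: int(rng.integers(1, n))] = True
    rng.shuffle(labels)
    if heavy_ties:
        scores = rng.integers(0, 4, n).astype(float)
    else:
        scores = rng.normal(size=n)
    return scores, labels


class TestAUC:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([0.9, 0.8], [0.3, 0.2], 1.0),      # perfect separation
            ([0.9, 0.4], [0.6, 0.2], 0.75),     # 3 of 4 pairs concordant
            ([0.5, 0.5], [0.5, 0.5], 0.5),      # all tied -> midpoint credit
        ],
    )
    def test_worked_examples(self, pos, neg, expected):
        scores = np.array(pos + neg)
        labels = np.array([True] * len(pos) + [False] * len(neg))
        assert auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for i in range(200):
            scores, labels = random_instance(rng, heavy_ties=(i % 2 == 0))
            assert auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_vectorised_bootstrap_route_equals_auc(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            scores, labels = random_instance(rng, heavy_ties=True)
            vec = _auc_rows(scores[None, :], labels[None, :])[0]
            assert vec == pytest.approx(auc(scores, labels), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(EvaluationError):
            auc(np.array([0.1, 0.2]), np.array([True, True]))

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores, labels = random_instance(rng)
            pts = roc_points(scores, labels)
            assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
            assert (np.diff(pts[:, 0]) >= -1e-12).all()
            assert (np.diff(pts[:, 1]) >= -1e-12).all()


class TestBootstrapCI:
    def test_perfect_separation_ci_is_degenerate(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.05])
        labels = np.array([True, True, True, False, False, False])
        assert bootstrap_ci(scores, labels, n_boot=200, seed=0) == (1.0, 1.0)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(3)
        scores, labels = random_instance(rng)
        ci1 = bootstrap_ci(scores, labels, n_boot=300, seed=9)
        ci2 = bootstrap_ci(scores, labels, n_boot=300, seed=9)
        assert ci1 == ci2

    def test_ci_brackets_auc_and_orders(self):
        rng = np.random.default_rng(4)
        scores, labels = random_instance(rng)
        res = roc_result(scores, labels, n_boot=500, seed=1)
        assert res.ci_low <= res.ci_high
        # percentile CIs contain the point estimate up to bootstrap noise
        assert res.ci_low - 0.05 <= res.auc <= res.ci_high + 0.05

    def test_width_shrinks_with_test_set_size(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (50, 200, 800):
            w = []
            for seed in range(20):
                scores = rng.normal(size=n) + np.repeat([0.5, 0.0], n // 2)
                labels = np.repeat([True, False], n // 2)
                lo, hi = bootstrap_ci(scores, labels, n_boot=300, seed=seed)
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]

    def test_n_boot_too_small_rejected(self):
        with pytest.raises(EvaluationError):
            bootstrap_ci(np.array([1.0, 0.0]), np.array([True, False]), n_boot=1)


class TestHoldoutSplit:
    def make(self, n_pos, n_neg):
        n = n_pos + n_neg
        X = pd.DataFrame({"dx:A": np.arange(n) % 2, "age": 40, "gender": 0},
                         index=[f"p{i:04d}" for i in range(n)])
        y = pd.Series([True] * n_pos + [False] * n_neg, index=X.index)
        return FeatureMatrix(X, y)

    def test_sizes_one_third(self):
        tr, te = holdout_split(self.make(90, 210), SplitConfig(seed=0))
        assert te.n_patients == 100 and tr.n_patients == 200

    def test_stratification_preserves_class_fraction(self):
        tr, te = holdout_split(self.make(90, 210), SplitConfig(seed=0))
        assert abs(int(te.y.sum()) - 30) <= 1

    def test_partition_disjoint_exhaustive(self):
        m = self.make(40, 80)
        tr, te = holdout_split(m, SplitConfig(seed=3))
        assert set(tr.patients) | set(te.patients) == set(m.patients)
        assert not set(tr.patients) & set(te.patients)

    def test_deterministic(self):
        m = self.make(40, 80)
        a = holdout_split(m, SplitConfig(seed=7))[0].patients
        b = holdout_split(m, SplitConfig(seed=7))[0].patients
        assert a == b

    def test_single_eligible_patient_rejected(self):
        with pytest.raises(EvaluationError):
            holdout_split(self.make(1, 30), SplitConfig())


class TestReduceTraining:
    def make(self, n):
        X = pd.DataFrame({"dx:A": 1, "age": 40, "gender": 0},
                         index=[f"p{i:04d}" for i in range(n)])
        y = pd.Series([i % 3 == 0 for i in range(n)], index=X.index)
        return FeatureMatrix(X, y)

    @pytest.mark.parametrize("n, remaining", [(300, 210), (210, 147)])
    def test_removes_thirty_percent(self, n, remaining):
        reduced = reduce_training(self.make(n), seed=0)
        assert reduced.n_patients == remaining

    def test_ladder_arithmetic_from_200(self):
        """n_next = n - round(0.3 n), stopping when the remainder falls below 10."""
        ladder = reduction_ladder(self.make(200), seed=0)
        assert [m.n_patients for m in ladder] == [200, 140, 98, 69, 48, 34, 24, 17, 12]

    def test_stop_signal_below_minimum(self):
        assert reduce_training(self.make(12), seed=0, min_size=10) is None

    def test_subsets_are_nested(self):
        ladder = reduction_ladder(self.make(100), seed=1)
        for bigger, smaller in zip(ladder, ladder[1:]):
            assert set(smaller.patients) <= set(bigger.patients)


class TestLearningCurve:
    def test_separable_cohort_all_points_perfect(self, separable_cohort):
        matrix = pivot(separable_cohort)
        points = learning_curve(
            matrix,
            ModelSpec(ModelFamily.LOGISTIC, seed=0),
            SelectionMethod.ASSOCIATION,
            k=5,
            split_config=SplitConfig(seed=2),
            n_boot=50,
        )
        sizes = [p.training_n for p in points]
        assert sizes == sorted(sizes, reverse=True)
        assert all(p.auc == 1.0 for p in points)

    def test_curve_length_matches_reduction_arithmetic(self, separable_cohort):
        matrix = pivot(separable_cohort)
        points = learning_curve(
            matrix, ModelSpec(ModelFamily.LOGISTIC, seed=0),
            split_config=SplitConfig(seed=2), n_boot=50,
        )
        expected = [40, 28, 20, 14, 10]  # from 40 training patients
        assert [p.training_n for p in points] == expected


class TestRunGrid:
    def small_config(self, **kw):
        defaults = dict(
            families=[ModelFamily.CART_TREE, ModelFamily.LOGISTIC],
            levels=[AggregationLevel.NONE, AggregationLevel.CATEGORY, AggregationLevel.BLOCK],
            methods=[SelectionMethod.ASSOCIATION],
            k_values=[10],
            n_boot=50,
            min_train_size=60,
            master_seed=17,
        )
        defaults.update(kw)
        return GridConfig(**defaults)

    def test_row_count_is_full_cross_product(self, small_synth):
        cfg = self.small_config()
        result = run_grid(small_synth.cohort, cfg, small_synth.block_map)
        # ladder from 200 training patients with min 60: 200, 140, 98, 69 -> 4 sizes
        assert len(result) == 2 * 3 * 1 * 1 * 4
        assert (result.status == "ok").all()

    def test_rerun_identical(self, small_synth):
        cfg = self.small_config(families=[ModelFamily.CART_TREE])
        r1 = run_grid(small_synth.cohort, cfg, small_synth.block_map)
        r2 = run_grid(small_synth.cohort, cfg, small_synth.block_map)
        pd.testing.assert_frame_equal(r1, r2)

    def test_block_level_without_map_rejected(self, small_synth):
        with pytest.raises(EvaluationError, match="block map"):
            run_grid(small_synth.cohort, self.small_config(), None)


def test_derive_seed_stable_and_bounded():
    s = derive_seed(42, "random_forest", "block", 20)
    assert s == derive_seed(42, "random_forest", "block", 20)
    assert 0 <= s < 2**31
    assert s != derive_seed(43, "random_forest", "block", 20)
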