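"""Rank-based tests, effect sizes, ARI, Spearman, threshold classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainlayers import (
    ThresholdClassifier,
    adjusted_rand,
    cohens_d_from_r,
    compare_modularity_curves,
    modularity_classifier,
    rank_biserial,
    ranksum,
    spearman,
)
from brainlayers.community import Partition
from oracles import exact_ranksum_pvalue, hand_adjusted_rand, pair_count_rank_biserial

small_samples = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=2, max_size=5
)


class TestRanksum:
    def test_complete_separation_exact_p(self):
        z, p = ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 / C(6,3)
        assert z < 0  # x below y

    def test_identical_samples_z_zero(self):
        z, p = ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_all_values_identical_degenerate(self):
        z, p = ranksum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert (z, p) == (0.0, 1.0)

    def test_shifting_one_sample_drives_p_down(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        ps = [ranksum(x, y + shift)[1] for shift in (0.0, 1.0, 2.0, 4.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(small_samples, small_samples)
    def test_exact_p_matches_enumeration_oracle(self, x, y):
        _, p = ranksum(x, y)
        assert p == pytest.approx(exact_ranksum_pvalue(x, y), abs=1e-9)


class TestRankBiserial:
    def test_complete_separation(self):
        assert rank_biserial([1, 2, 3], [4, 5, 6]) == -1.0
        assert rank_biserial([4, 5, 6], [1, 2, 3]) == 1.0

    def test_interleaved_zero(self):
        assert rank_biserial([1, 4], [2, 3]) == 0.0

    def test_half_overlap(self):
        assert rank_biserial([1, 3], [2, 4]) == -0.5

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(small_samples, small_samples)
    def test_matches_pair_counting_oracle(self, x, y):
        assert rank_biserial(x, y) == pytest.approx(
            pair_count_rank_biserial(x, y), abs=1e-12
        )


class TestCohensD:
    def test_paper_printed_pair(self):
        assert cohens_d_from_r(-0.553) == pytest.approx(-1.33, abs=5e-3)

    def test_zero_maps_to_zero(self):
        assert cohens_d_from_r(0.0) == 0.0

    def test_simple_value(self):
        assert cohens_d_from_r(0.6) == pytest.approx(1.5, abs=1e-12)

    def test_unit_r_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_from_r(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(min_value=-0.99, max_value=0.99))
    def test_roundtrip_with_inverse_map(self, r):
        d = cohens_d_from_r(r)
        assert d / np.sqrt(d * d + 4.0) == pytest.approx(r, abs=1e-12)


class TestAdjustedRand:
    def test_identical_partitions(self):
        assert adjusted_rand([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_crossed_partition_value(self):
        assert adjusted_rand([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_singletons_vs_one_block(self):
        assert adjusted_rand([1, 1, 1, 1], [1, 2, 3, 4]) == pytest.approx(0.0)

    def test_accepts_partition_objects(self):
        p1 = Partition(np.array([[1, 1, 2, 2]]))
        p2 = Partition(np.array([[2, 2, 1, 1]]))
        assert adjusted_rand(p1, p2) == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_hand_contingency_and_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a = r.integers(1, 4, size=12)
        b = r.integers(1, 4, size=12)
        assert adjusted_rand(a, b) == pytest.approx(hand_adjusted_rand(a, b), abs=1e-12)
        assert adjusted_rand(a, b) == pytest.approx(adjusted_rand(b, a), abs=1e-12)
        # invariance under relabeling
        perm = {1: 3, 2: 1, 3: 2}
        b2 = np.array([perm[v] for v in b])
        assert adjusted_rand(a, b2) == pytest.approx(adjusted_rand(a, b), abs=1e-12)


class TestSpearman:
    def test_monotone_is_one(self):
        r, _ = spearman([1, 2, 3, 4, 5], [10, 20, 25, 30, 100])
        assert r == pytest.approx(1.0)

    def test_known_rho(self):
        # Σd² = 4 → rho = 1 − 6·4/(5·24) = 0.8
        r, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_partial_self_control_near_zero(self, rng):
        x = rng.normal(size=50)
        y = 0.8 * x + 0.2 * rng.normal(size=50)
        r, _ = spearman(x, y, controlling_for=x)
        assert abs(r) < 0.15

    def test_partial_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = 0.5 * x + 0.5 * z + 0.3 * rng.normal(size=40)
        r, p = spearman(x, y, controlling_for=z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestClassifier:
    def test_perfect_separation_cv_accuracy_one(self):
        x = np.concatenate([np.zeros(8), np.ones(8)])
        y = np.array(["a"] * 8 + ["b"] * 8)
        res = modularity_classifier(x, y, k_folds=4, seed=0)
        assert res.cv_accuracy == 1.0
        assert res.accuracy == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        accs = []
        for rep in range(200):
            x = rng.normal(size=16)
            y = np.array(["a"] * 8 + ["b"] * 8)
            rng.shuffle(y)
            accs.append(modularity_classifier(x, y, k_folds=4, seed=rep).cv_accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_planted_gap_beats_chance_bound(self, rng):
        # 1-pooled-SD group gap: mean held-out accuracy over replicates must
        # clear the above-chance bound
        accs = []
        for rep in range(20):
            x = np.concatenate([rng.normal(0, 1, 15), rng.normal(1.0, 1, 15)])
            y = np.array(["a"] * 15 + ["b"] * 15)
            accs.append(modularity_classifier(x, y, k_folds=4, seed=rep).cv_accuracy)
        assert np.mean(accs) > 0.54

    def test_kfolds_above_class_size_rejected(self):
        with pytest.raises(ValueError):
            modularity_classifier([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"], k_folds=3)

    def test_sklearn_estimator_api(self):
        clf = ThresholdClassifier()
        X = np.array([0.0, 0.1, 0.9, 1.0])
        y = np.array([0, 0, 1, 1])
        assert np.array_equal(clf.fit(X, y).predict([0.05, 0.95]), [0, 1])
        assert clf.get_params() == {}


class TestCompareCurves:
    def test_row_per_c_value(self, rng):
        QA = rng.normal(size=(5, 101))
        QB = rng.normal(size=(5, 101))
        res = compare_modularity_curves(QA, QB)
        assert len(res.table) == 101

    def test_identical_groups_nominal_false_positives(self, rng):
        QA = rng.normal(size=(10, 50))
        QB = rng.normal(size=(10, 50))
        res = compare_modularity_curves(QA, QB)
        assert (res.table["p"] < 0.05).mean() < 0.15

    def test_lower_group_gives_negative_r_everywhere(self, rng):
        QA = rng.normal(0.0, 0.1, size=(12, 11))
        QB = QA.mean() + 1.0 + rng.normal(0.0, 0.1, size=(12, 11))
        res = compare_modularity_curves(QA, QB)
        assert (res.table["r"] < 0).all()
        assert res.mean_r < 0
        assert res.cohens_d < 0
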