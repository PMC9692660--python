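import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazefusion.classification import ScoreSet
from gazefusion.errors import AlignmentError, ConfigurationError, DataError
from gazefusion.score_fusion import (WEIGHT_GRID, FusionWeights, ScoreMatrix,
                                     bayes_fuse, bayes_pair_scores,
                                     classifier_score_fusion,
                                     search_weights_and_combinations,
                                     weighted_product_fuse, weighted_sum_fuse)


def scoreset(pos_scores, family="svm", accuracy=0.8, labels=("a", "b"),
             ids=None):
    pos = np.asarray(pos_scores, dtype=float)
    ids = np.array([f"s{i}" for i in range(len(pos))]) if ids is None else ids
    return ScoreSet(family=family, params={}, k=2, sample_ids=ids,
                    scores=np.column_stack([1.0 - pos, pos]),
                    class_labels=labels, test_accuracy=accuracy,
                    cv_accuracy=accuracy)


def matrix_of(*pos_score_lists, families=None):
    families = families or [f"m{i}" for i in range(len(pos_score_lists))]
    sets = [scoreset(p, family=f) for p, f in zip(pos_score_lists, families)]
    return ScoreMatrix.from_scoresets(sets)


class TestWeightedSum:
    def test_equal_weights_are_arithmetic_mean(self):
        m = matrix_of([0.8], [0.6])
        fused = weighted_sum_fuse(m, FusionWeights((0.5, 0.5)))
        assert fused.scores[0, 1] == pytest.approx(0.7)

    def test_single_member_identity(self):
        m = matrix_of([0.3, 0.9])
        fused = weighted_sum_fuse(m, FusionWeights((1.0,)))
        assert np.allclose(fused.scores, m.scores[0])

    def test_two_sample_hand_table(self):
        # members' positive scores per sample: A=(0.9, 0.2), B=(0.2, 0.9);
        # weights (1.0, 0.1); all four fused class scores verified by hand
        m = matrix_of([0.9, 0.2], [0.2, 0.9])
        fused = weighted_sum_fuse(m, FusionWeights((1.0, 0.1)))
        # sample 0: class1 = 1.0*0.9 + 0.1*0.2 = 0.92; class0 = 0.1 + 0.08 = 0.18
        assert fused.scores[0, 1] == pytest.approx(0.92)
        assert fused.scores[0, 0] == pytest.approx(0.18)
        assert fused.predictions[0] == "b"
        # sample 1: class1 = 0.2 + 0.09 = 0.29; class0 = 0.8 + 0.01 = 0.81
        assert fused.scores[1, 1] == pytest.approx(0.29)
        assert fused.scores[1, 0] == pytest.approx(0.81)
        assert fused.predictions[1] == "a"

    def test_misaligned_ids_rejected(self):
        a = scoreset([0.5, 0.5])
        b = scoreset([0.5, 0.5], ids=np.array(["x0", "x1"]))
        with pytest.raises(AlignmentError):
            ScoreMatrix.from_scoresets([a, b])

    def test_weight_count_mismatch(self):
        with pytest.raises(ConfigurationError):
            weighted_sum_fuse(matrix_of([0.5], [0.5]), FusionWeights((1.0,)))

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=2),
           st.floats(0.01, 0.99))
    def test_convex_weights_stay_in_unit_interval(self, pos, w1):
        m = matrix_of([pos[0]], [pos[1]])
        fused = weighted_sum_fuse(m, FusionWeights((w1, 1.0 - w1)))
        assert np.all(fused.scores >= -1e-12)
        assert np.all(fused.scores <= 1.0 + 1e-12)


class TestWeightedProduct:
    def test_zero_annihilation(self):
        m = matrix_of([0.0, 0.5], [0.9, 0.5])
        fused = weighted_product_fuse(m, FusionWeights((1.0, 1.0)))
        assert fused.scores[0, 1] == 0.0

    def test_single_member_identity(self):
        m = matrix_of([0.4, 0.7])
        fused = weighted_product_fuse(m, FusionWeights((1.0,)))
        assert np.allclose(fused.scores, m.scores[0])

    def test_fractional_exponent(self):
        m = matrix_of([0.8], [0.5])
        fused = weighted_product_fuse(m, FusionWeights((1.0, 0.5)))
        assert fused.scores[0, 1] == pytest.approx(0.8 * 0.5 ** 0.5)
        assert fused.scores[0, 1] == pytest.approx(0.5657, abs=1e-4)

    def test_negative_scores_rejected(self):
        m = matrix_of([0.5], [0.5])
        m.scores[0, 0, 0] = -0.1
        with pytest.raises(DataError):
            weighted_product_fuse(m, FusionWeights((1.0, 1.0)))

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=2),
           st.floats(0.1, 1.0), st.floats(0.1, 1.0))
    def test_range_preserved(self, pos, w1, w2):
        m = matrix_of([pos[0]], [pos[1]])
        fused = weighted_product_fuse(m, FusionWeights((w1, w2)))
        assert np.all(fused.scores >= 0)
        assert np.all(fused.scores <= 1.0 + 1e-12)


class TestBayesFuse:
    def test_indifference_point(self):
        assert bayes_pair_scores(0.5, 0.5) == pytest.approx(0.5)

    def test_confident_agreement(self):
        # 0.64 / (0.04 + 0.64)
        assert bayes_pair_scores(0.8, 0.8) == pytest.approx(0.9412, abs=1e-4)

    def test_certain_member_dominates(self):
        for t_b in (0.1, 0.5, 0.9):
            assert bayes_pair_scores(1.0, t_b) == pytest.approx(1.0)

    def test_singular_pair_maps_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="singular"):
            assert bayes_pair_scores(1.0, 0.0) == pytest.approx(0.5)

    def test_symmetry_at_weight_one(self):
        m1 = matrix_of([0.8, 0.3], [0.6, 0.9], families=["x", "y"])
        m2 = matrix_of([0.6, 0.9], [0.8, 0.3], families=["y", "x"])
        f1 = bayes_fuse(m1)
        f2 = bayes_fuse(m2)
        assert np.allclose(f1.scores, f2.scores)

    def test_weight_applies_to_named_member(self):
        m = matrix_of([0.8], [0.6], families=["x", "y"])
        fused = bayes_fuse(m, weight_on=m.members[1], weight=0.5)
        expected = bayes_pair_scores(0.8, 0.3)
        assert fused.scores[0, 1] == pytest.approx(expected)

    def test_threshold_decision(self):
        m = matrix_of([0.9], [0.9])
        assert bayes_fuse(m).predictions[0] == "b"
        m2 = matrix_of([0.2], [0.3])
        assert bayes_fuse(m2).predictions[0] == "a"

    def test_pair_only(self):
        with pytest.raises(DataError):
            bayes_fuse(matrix_of([0.5], [0.5], [0.5]))

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 0.2))
    @settings(max_examples=200)
    def test_monotone_in_each_argument(self, t_a, t_b, eps):
        if (t_a, t_b) in ((1.0, 0.0), (0.0, 1.0)):
            return
        base = bayes_pair_scores(t_a, t_b)
        bumped = bayes_pair_scores(min(t_a + eps, 1.0), t_b)
        if not (min(t_a + eps, 1.0) == 1.0 and t_b == 0.0):
            assert bumped >= base - 1e-12
        assert 0.0 <= base <= 1.0


def make_candidates(n_members=3, n_samples=30, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array(["a", "b"])[rng.integers(0, 2, n_samples)]
    sets = []
    for i in range(n_members):
        noise = rng.normal(0, 0.35, n_samples)
        pos = np.clip((labels == "b") * 0.7 + 0.15 + noise, 0.0, 1.0)
        ss = scoreset(pos, family=f"m{i}")
        ss.test_accuracy = float(np.mean((pos >= 0.5) == (labels == "b")))
        sets.append(ss)
    return sets, labels


def oracle_search(candidates, rule, size, labels, grid=WEIGHT_GRID):
    """Plain nested-loop enumeration, independent of the library path."""
    best_acc, best_cfg, n_evals = -1.0, None, 0
    pos = np.stack([ss.scores[:, 1] for ss in candidates])
    neg = 1.0 - pos
    truth = labels == "b"
    for combo in itertools.combinations(range(len(candidates)), size):
        if rule == "bayes":
            for which in range(2):
                for w in grid:
                    t = pos[list(combo)].copy()
                    t[which] *= w
                    num = t[0] * t[1]
                    den = (1 - t[0]) * (1 - t[1]) + num
                    s = np.where(den == 0, 0.5, num / np.where(den == 0, 1, den))
                    acc = np.mean((s >= 0.5) == truth)
                    n_evals += 1
                    if acc > best_acc:
                        best_acc, best_cfg = acc, (combo, which, w)
        else:
            for weights in itertools.product(grid, repeat=size):
                w = np.asarray(weights)
                if rule == "sum":
                    s1 = np.tensordot(w, pos[list(combo)], axes=(0, 0))
                    s0 = np.tensordot(w, neg[list(combo)], axes=(0, 0))
                else:
                    s1 = np.prod(pos[list(combo)] ** w[:, None], axis=0)
                    s0 = np.prod(neg[list(combo)] ** w[:, None], axis=0)
                acc = np.mean((s1 > s0) == truth)
                n_evals += 1
                if acc > best_acc:
                    best_acc, best_cfg = acc, (combo, weights)
    return best_acc, best_cfg, n_evals


class TestSearch:
    def test_pairwise_sum_grid_size(self):
        sets, labels = make_candidates(2)
        result = search_weights_and_combinations(sets, "sum", [2], labels)
        assert result.n_evaluations == 100  # C(2,2) * 10^2

    def test_matches_bruteforce_oracle(self):
        sets, labels = make_candidates(3)
        for rule in ("sum", "product", "bayes"):
            sizes = [2] if rule == "bayes" else [2, 3]
            result = search_weights_and_combinations(sets, rule, sizes, labels)
            for size in sizes:
                acc, _, n = oracle_search(sets, rule, size, labels)
                assert result.best_by_size[size].accuracy == pytest.approx(acc)

    def test_evaluation_counts_match_oracle(self):
        sets, labels = make_candidates(3)
        result = search_weights_and_combinations(sets, "sum", [2, 3], labels)
        expected = oracle_search(sets, "sum", 2, labels)[2] + \
            oracle_search(sets, "sum", 3, labels)[2]
        assert result.n_evaluations == expected

    def test_dominant_member_keeps_perfect_accuracy(self):
        labels = np.array(["a", "b"] * 10)
        perfect = scoreset((labels == "b").astype(float) * 0.998 + 0.001,
                           family="m0", accuracy=1.0)
        noisy = scoreset(np.full(20, 0.5), family="m1", accuracy=0.5)
        result = search_weights_and_combinations([perfect, noisy], "sum", [2],
                                                 labels)
        assert result.best_by_size[2].accuracy == 1.0

    def test_beats_any_manual_configuration(self):
        sets, labels = make_candidates(3, seed=4)
        result = search_weights_and_combinations(sets, "sum", [2], labels)
        manual = weighted_sum_fuse(ScoreMatrix.from_scoresets(sets[:2]),
                                   FusionWeights((0.7, 0.3)), labels)
        assert result.best_by_size[2].accuracy >= manual.accuracy

    def test_improvement_flag(self):
        sets, labels = make_candidates(3, seed=1)
        result = search_weights_and_combinations(sets, "sum", [2], labels)
        best = result.best_by_size[2]
        assert best.improves_single == (best.accuracy >
                                        result.best_single_accuracy)

    def test_size_larger_than_pool_rejected(self):
        sets, labels = make_candidates(2)
        with pytest.raises(ConfigurationError):
            search_weights_and_combinations(sets, "sum", [3], labels)

    def test_bayes_restricted_to_pairs(self):
        sets, labels = make_candidates(3)
        with pytest.raises(ConfigurationError):
            search_weights_and_combinations(sets, "bayes", [2, 3], labels)


class TestClassifierScoreFusion:
    def specs(self):
        from gazefusion.classification import default_specs
        return default_specs(small=True, k_range=(2,))

    def test_separable_scores_reach_one(self):
        labels = np.array(["a"] * 20 + ["b"] * 20)
        a = scoreset(np.where(labels == "b", 0.9, 0.1), family="svm")
        b = scoreset(np.where(labels == "b", 0.8, 0.2), family="knn")
        out = classifier_score_fusion([a, b], labels, self.specs(), split_seed=0)
        for family, fused in out.items():
            assert fused.accuracy == 1.0, family

    def test_uninformative_scores_near_prevalence(self):
        labels = np.array(["a", "b"] * 20)
        a = scoreset(np.full(40, 0.5), family="svm")
        b = scoreset(np.full(40, 0.5), family="knn")
        out = classifier_score_fusion([a, b], labels, self.specs(), split_seed=0)
        for fused in out.values():
            assert fused.accuracy == pytest.approx(0.5, abs=0.1)

    def test_derived_width_is_four(self):
        labels = np.array(["a", "b"] * 10)
        a = scoreset(np.linspace(0, 1, 20), family="svm")
        b = scoreset(np.linspace(1, 0, 20), family="knn")
        out = classifier_score_fusion([a, b], labels,
                                      self.specs()[:1], split_seed=0)
        fused = next(iter(out.values()))
        assert fused.extra["params"] is not None
        # the derived problem concatenates both members' two-class vectors
        from gazefusion import score_fusion as sf
        X = np.hstack([a.scores, b.scores])
        assert X.shape == (20, 4)

    def test_requires_two_members(self):
        labels = np.array(["a", "b"])
        with pytest.raises(DataError):
            classifier_score_fusion([scoreset([0.5, 0.5])], labels,
                                    self.specs(), split_seed=0)
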