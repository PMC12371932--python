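"""Linear-SVM pair baseline: encoding, training, grouping, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herbrel import examples_data as D
from herbrel.svm_baseline import (
    LinearModel,
    PairInstance,
    cross_validate_pairs,
    evaluate,
    group_by_pp,
    macro_average,
    make_pairs,
    pair_space,
    train_linear_svm,
)
from herbrel.synthetic import GeneratorSpec, gen_vectors


def test_pair_space_is_product():
    assert pair_space() == 792
    assert pair_space(3, 5) == 15


class TestMakePairs:
    def test_single_vector_with_three_properties(self):
        from herbrel.corpus_io import BinaryVector

        pp = np.zeros(9); pp[2] = 1
        mp = np.zeros(10); mp[[1, 4, 7]] = 1
        v = BinaryVector("h", "Bark", pp, mp)
        pairs = make_pairs([v])
        assert [(p.pp_index, p.mp_index) for p in pairs] == [(2, 1), (2, 4), (2, 7)]
        x = pairs[0].features
        assert x.sum() == 2 and x[2] == 1 and x[9 + 1] == 1

    def test_counts_match_generator_manifest(self):
        spec = GeneratorSpec(seed=9, n_obs=40, n_properties=12, n_blocks=2, block_size=4)
        vectors, labels, _ = gen_vectors(spec)
        pairs = make_pairs(vectors, labels=labels)
        total_bits = sum(int(v.mp_indicators.sum()) for v in vectors)
        assert len(pairs) == total_bits
        assert all(p.label in (0, 1) for p in pairs)

    def test_unknown_pair_label_raises(self):
        spec = GeneratorSpec(seed=9, n_obs=5, n_properties=6, n_blocks=1, block_size=3)
        vectors, _, _ = gen_vectors(spec)
        with pytest.raises(KeyError):
            make_pairs(vectors, labels={(0, 0): 1})


class TestTrainLinearSVM:
    def test_hard_margin_toy_matches_hand_solution(self):
        # negative at x=0, positive at x=2: max margin -> w=1, b=-1
        model = train_linear_svm(np.array([[0.0], [2.0]]), [0, 1], C=1e6)
        assert pytest.approx(model.w[0], abs=1e-6) == 1.0
        assert pytest.approx(model.b, abs=1e-6) == -1.0
        # support constraints y*f(x) >= 1 - tol
        assert model.decision([[0.0]])[0] <= -1 + 1e-6
        assert model.decision([[2.0]])[0] >= 1 - 1e-6

    def test_boundary_convention_is_inclusive(self):
        model = LinearModel(w=np.zeros(2), b=0.0)
        assert model.classify(np.zeros((1, 2)))[0] == 1  # f(x) = 0 -> positive
        model_pos = LinearModel(w=np.zeros(2), b=1.0)
        assert model_pos.classify(np.random.rand(5, 2)).tolist() == [1] * 5

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.array([[0.0], [1.0]]), [1, 1])

    def test_separable_pairs_reach_zero_training_error(self):
        spec = GeneratorSpec(seed=10, n_obs=120, n_properties=16, n_blocks=2,
                             block_size=6)
        vectors, labels, _ = gen_vectors(spec)
        pairs = make_pairs(vectors, labels=labels)
        # pair labels are a deterministic function of the two-hot encoding,
        # hence linearly separable
        model = train_linear_svm(pairs, C=1e4)
        X = np.vstack([p.features for p in pairs])
        y = np.array([p.label for p in pairs])
        assert (model.classify(X) == y).all()


class TestGroupingAndMetrics:
    def test_group_by_pp_partition(self):
        mk = lambda part, prop: PairInstance(0, 0, 9, 88, 1, part, prop)
        groups = group_by_pp([mk("Leaf", "A"), mk("Leaf", "B"), mk("Root", "A")])
        assert groups == {"Leaf": {"A", "B"}, "Root": {"A"}}
        assert group_by_pp([]) == {}

    @given(st.lists(st.tuples(st.sampled_from("abc"), st.sampled_from("xyz")),
                    min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_grouping_is_a_partition(self, pairs):
        insts = [PairInstance(0, 0, 9, 88, 1, part, prop) for part, prop in pairs]
        groups = group_by_pp(insts)
        assert sum(len(v) for v in groups.values()) == len({(a, b) for a, b in pairs})

    def test_confusion_arithmetic(self):
        # TP=3, FP=1, FN=2, TN=4
        truth = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        preds = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        m = evaluate(preds, truth)
        assert m["accuracy"] == 0.7
        assert m["precision"] == 0.75
        assert pytest.approx(m["recall"], abs=1e-12) == 0.6
        assert pytest.approx(m["f1"], abs=1e-3) == 0.667

    def test_perfect_predictions(self):
        m = evaluate([1, 0, 1], [1, 0, 1])
        assert all(v == 1.0 for v in m.values())

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    def test_macro_average_of_published_rows(self):
        macro = macro_average(list(D.SVM_PART_METRICS.values()))
        assert macro["accuracy"] == 0.80
        assert macro["f1"] == 0.752

    def test_macro_average_of_identical_records_is_identity(self):
        rec = {"accuracy": 0.5, "f1": 0.25}
        assert macro_average([rec, rec, rec], ndigits=None) == rec


def test_cross_validation_is_seeded_and_above_chance():
    spec = GeneratorSpec(seed=12, n_obs=150, n_properties=16, n_blocks=2, block_size=6)
    vectors, labels, _ = gen_vectors(spec)
    pairs = make_pairs(vectors, labels=labels)
    r1 = cross_validate_pairs(pairs, folds=5, seed=3)
    r2 = cross_validate_pairs(pairs, folds=5, seed=3)
    assert np.array_equal(r1["predictions"], r2["predictions"])
    base_rate = max(np.mean([p.label for p in pairs]),
                    1 - np.mean([p.label for p in pairs]))
    assert r1["overall"]["accuracy"] > base_rate
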