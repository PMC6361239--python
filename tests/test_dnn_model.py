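"""Network training, ROC/AUC machinery, grid enumeration, thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from akid import fixtures
from akid.dnn_model import (
    DNNConfig,
    ThresholdSet,
    auc_by_group,
    cross_validate,
    enumerate_grid,
    grid_search,
    load_model,
    predict,
    roc_auc,
    save_model,
    select_thresholds,
    train,
)
from akid.encoding import N_BITS

from oracles import pairwise_auc


def _separable_toy(n=20, seed=0):
    """Balanced pairs differing at a single DoS slot decide the label."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, N_BITS))
    # one-hot blocks: fill every position with slot 0, then flip block 5
    X[:, np.arange(78) * 21] = 1
    y = np.tile([0, 1], n // 2 + 1)[:n]
    y = y[rng.permutation(n)]
    X[y == 1, 5 * 21] = 0
    X[y == 1, 5 * 21 + 3] = 1
    return X, y


class TestTrainPredict:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X, y = _separable_toy()
        model = train(X, y, DNNConfig(layer1=16, layer2=4, batch_size=20, epochs=10, seed=0))
        scores = predict(model, X)
        assert np.all((scores > 0.5) == (y == 1))
        assert np.all((scores >= 0) & (scores <= 1))

    def test_training_is_deterministic_under_a_seed(self):
        X, y = _separable_toy(seed=3)
        cfg = DNNConfig(layer1=8, layer2=2, batch_size=10, epochs=5, seed=11)
        s1 = predict(train(X, y, cfg), X)
        s2 = predict(train(X, y, cfg), X)
        assert np.array_equal(s1, s2)

    def test_duplicate_rows_get_identical_scores(self):
        X, y = _separable_toy(seed=1)
        model = train(X, y, DNNConfig(layer1=8, layer2=2, batch_size=10, epochs=3, seed=0))
        X2 = np.vstack([X[:1], X[:1]])
        s = predict(model, X2)
        assert s[0] == s[1]

    def test_single_class_input_raises(self):
        X, _ = _separable_toy()
        with pytest.raises(ValueError, match="class"):
            train(X, np.zeros(len(X), dtype=int), DNNConfig(layer1=4, layer2=2, batch_size=5))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="1638"):
            train(np.zeros((4, 10)), [0, 1, 0, 1], DNNConfig(layer1=4, layer2=2, batch_size=2))

    def test_shuffled_labels_give_chance_level_auc(self):
        rules = fixtures.make_rules(3, 3, seed=2)
        ds = fixtures.gen_ksp(rules, 40, 40, 0.0, seed=2)
        rng = np.random.default_rng(0)
        y = rng.permutation(ds.labels)
        cfg = DNNConfig(layer1=16, layer2=4, batch_size=80, epochs=5, seed=0)
        _, auc, _ = cross_validate(ds.encoded(), y, cfg, k=5, seed=0)
        assert 0.4 <= auc <= 0.6

    def test_model_round_trips_through_the_archive(self, tmp_path):
        X, y = _separable_toy(seed=5)
        cfg = DNNConfig(layer1=8, layer2=2, batch_size=10, epochs=3, seed=1)
        model = train(X, y, cfg)
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        assert np.array_equal(predict(loaded, X), predict(model, X))
        with pytest.raises(ValueError, match="block order"):
            load_model(tmp_path / "m.npz", expect_block_order="peptide-then-dos")


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_ties_is_chance(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_worked_example(self):
        # pairs: .9>.8, .9>.1, .4<.8, .4>.1 -> 3 of 4 favorable, no ties
        assert roc_auc([0.9, 0.4, 0.8, 0.1], [1, 1, 0, 0]).auc == pytest.approx(3 / 4)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_roc_points_are_monotone(self):
        rng = np.random.default_rng(0)
        r = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert np.all(np.diff(r.points[:, 0]) >= 0)
        assert np.all(np.diff(r.points[:, 1]) >= 0)

    @settings(derandomize=True, max_examples=100)
    @given(
        scores=st.lists(st.integers(0, 5).map(lambda v: v / 5), min_size=2, max_size=12),
        data=st.data(),
    )
    def test_agrees_with_pairwise_oracle(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < n
            )
        )
        assert roc_auc(scores, labels).auc == pytest.approx(pairwise_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        base = roc_auc(scores, labels).auc
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: s**3):
            assert roc_auc(f(scores), labels).auc == pytest.approx(base)


class TestCrossValidate:
    def test_leave_one_out_on_a_toy_set(self):
        X, y = _separable_toy(n=10, seed=7)
        cfg = DNNConfig(layer1=4, layer2=1, batch_size=9, epochs=2, seed=0)
        with pytest.raises(ValueError):
            cross_validate(X, y, cfg, k=11)
        # k = n gives n folds of size 1 (per-fold ROC needs 2 classes, so pool)
        folds, _, pooled = cross_validate(X, y, cfg, k=5, seed=0)
        assert len(folds) == 5
        assert len(pooled) == 10

    def test_fold_scores_reproducible_under_seed(self):
        X, y = _separable_toy(n=30, seed=2)
        cfg = DNNConfig(layer1=4, layer2=1, batch_size=10, epochs=2, seed=0)
        _, auc1, p1 = cross_validate(X, y, cfg, k=3, seed=5)
        _, auc2, p2 = cross_validate(X, y, cfg, k=3, seed=5)
        assert auc1 == auc2
        assert np.array_equal(p1, p2)


class TestGrid:
    def test_full_grid_has_90_combinations(self):
        combos = enumerate_grid()
        assert len(combos) == 90
        assert len(set(combos)) == 90

    def test_layer2_is_the_ceiling_fraction_of_layer1(self):
        combos = enumerate_grid(layer1_sizes=(210,), batch_sizes=(400,))
        assert (210, 53, 400) in combos  # ceil(210/4) = 53

    def test_reduced_grid_search_returns_best_with_tie_break(self):
        rules = fixtures.make_rules(2, 2, seed=1)
        ds = fixtures.gen_ksp(rules, 30, 30, 0.0, seed=1)
        best, table = grid_search(
            ds.encoded(),
            ds.labels,
            seed=0,
            k=2,
            epochs=3,
            batch_sizes=(40,),
            layer1_sizes=(8, 16),
            layer2_fractions=(0.5,),
        )
        assert len(table) == 2
        aucs = {cfg.layer1: auc for cfg, auc in table}
        if aucs[8] == aucs[16]:
            assert best.layer1 == 8
        else:
            assert aucs[best.layer1] == max(aucs.values())


class TestThresholds:
    def test_gaussian_classes_cross_at_the_mean_midpoint(self):
        rng = np.random.default_rng(7)
        pos = {a: np.clip(rng.normal(0.7, 0.1, 5000), 0, 1) for a in "STY"}
        neg = {a: np.clip(rng.normal(0.3, 0.1, 5000), 0, 1) for a in "STY"}
        ts = select_thresholds(pos, neg)
        for t in (ts.t_S, ts.t_T, ts.t_Y):
            assert t == pytest.approx(0.5, abs=0.02)

    def test_swapping_classes_keeps_the_crossing(self):
        rng = np.random.default_rng(3)
        a = {x: np.clip(rng.normal(0.65, 0.08, 2000), 0, 1) for x in "STY"}
        b = {x: np.clip(rng.normal(0.35, 0.08, 2000), 0, 1) for x in "STY"}
        assert select_thresholds(a, b).t_S == pytest.approx(select_thresholds(b, a).t_S, abs=1e-6)

    def test_small_class_suggests_pooling(self):
        rng = np.random.default_rng(0)
        pos = {a: rng.random(5) for a in "STY"}
        neg = {a: rng.random(100) for a in "STY"}
        with pytest.raises(ValueError, match="pool"):
            select_thresholds(pos, neg)

    def test_reference_defaults_match_the_published_values(self):
        ts = ThresholdSet()
        assert (ts.t_S, ts.t_T, ts.t_Y) == (0.545, 0.517, 0.34)


def test_auc_by_group_is_a_groupby_over_roc_auc():
    scores = np.array([0.9, 0.1, 0.8, 0.7, 0.2, 0.6])
    labels = np.array([1, 0, 1, 1, 0, 0])
    groups = np.array(["TK", "TK", "TK", "CMGC", "CMGC", "CMGC"])
    out = auc_by_group(scores, labels, groups)
    assert out["TK"] == pytest.approx(pairwise_auc([0.9, 0.1, 0.8], [1, 0, 1]))
    assert out["CMGC"] == pytest.approx(pairwise_auc([0.7, 0.2, 0.6], [1, 0, 0]))
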