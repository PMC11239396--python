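import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neurofuse as nf
from neurofuse import lrp
from neurofuse.selectors import (
    CNNHyperparams,
    apply_selection,
    devectorize_lower_triangle,
    rank_features,
    select_features,
    train_modality_cnn,
    vectorize_fnc_stack,
    vectorize_lower_triangle,
)


def _sym(n, seed=0):
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


class TestVectorize:
    def test_53x53_gives_1378(self):
        flat, index_map = vectorize_lower_triangle(_sym(53))
        assert len(flat) == 1378
        assert index_map.n_connections == 1378

    def test_row_major_enumeration_order(self):
        m = np.eye(3)
        m[1, 0] = m[0, 1] = 0.2
        m[2, 0] = m[0, 2] = 0.3
        m[2, 1] = m[1, 2] = 0.4
        flat, index_map = vectorize_lower_triangle(m)
        assert np.allclose(flat, [0.2, 0.3, 0.4])
        assert index_map.components(0) == (1, 0)
        assert index_map.components(2) == (2, 1)

    def test_2x2_has_single_connection(self):
        flat, _ = vectorize_lower_triangle(_sym(2))
        assert len(flat) == 1

    def test_asymmetry_rejected(self):
        m = _sym(4)
        m[0, 1] += 1e-3
        with pytest.raises(ValueError, match="asymmetric"):
            vectorize_lower_triangle(m)

    def test_round_trip_reconstruction(self):
        m = _sym(8, seed=3)
        flat, _ = vectorize_lower_triangle(m)
        assert np.allclose(devectorize_lower_triangle(flat, 8), m)


class TestTrainCNN:
    def test_separable_data_reaches_full_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 200))
        y = (rng.random(80) < 0.5).astype(int)
        X[:, 37] = y * 2 - 1.0  # one feature fully determines the label
        net = train_modality_cnn(X, y, seed=0)
        assert net.meta["train_accuracy"] == 1.0

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 60))
        y = (rng.random(40) < 0.5).astype(int)
        a = train_modality_cnn(X, y, seed=5)
        b = train_modality_cnn(X, y, seed=5)
        for la, lb in zip(a.layers, b.layers):
            for name in la.params:
                assert np.array_equal(la.params[name], lb.params[name])

    def test_shuffled_labels_do_not_generalize(self):
        # null-label control: with labels shuffled, held-out accuracy sits
        # near the class prior
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 100))
        y = rng.integers(0, 2, 300)
        net = train_modality_cnn(X[:200], y[:200], seed=0)
        mu, sd = net.meta["standardize_mu"], net.meta["standardize_sd"]
        logits = net.forward(((X[200:] - mu) / sd)[:, None, :], record=False)
        acc = (logits.argmax(axis=1) == y[200:]).mean()
        assert abs(acc - 0.5) < 0.15

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(3).normal(size=(20, 30))
        with pytest.raises(ValueError, match="class"):
            train_modality_cnn(X, np.zeros(20, dtype=int))


class TestRankFeatures:
    def test_scores_sum_to_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 40))
        y = (rng.random(30) < 0.5).astype(int)
        net = train_modality_cnn(X, y, seed=1)
        rv = rank_features(net, X)
        assert rv.normalized
        assert np.isclose(rv.scores.sum(), 1.0, atol=1e-9)

    def test_constant_feature_receives_zero_relevance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 40))
        X[:, 13] = 2.5  # constant: standardizes to exactly zero activation
        y = (rng.random(30) < 0.5).astype(int)
        net = train_modality_cnn(X, y, seed=1)
        rv = rank_features(net, X)
        assert rv.scores[13] == 0.0

    def test_planted_connections_recovered_in_top_ranks(self):
        cfg = nf.CohortConfig(
            n_subjects=200, n_components=20, n_snps=5, volume_shape=(8, 8, 8),
            fnc_effect=[(int(i), 0.8) for i in (4, 40, 77, 120, 185)], seed=8,
        )
        _, labels, _ = nf.simulate_snps(cfg)
        fnc, _ = nf.simulate_fnc(cfg, labels)
        F, _ = vectorize_fnc_stack(fnc)
        net = train_modality_cnn(F, labels.astype(int), seed=8)
        rv = rank_features(net, F)
        sel = select_features(rv, ("top_k", 35))
        hits = {4, 40, 77, 120, 185} & set(sel.selected_indices.tolist())
        assert len(hits) >= 4


class TestSelect:
    def _rv(self, scores):
        v = np.asarray(scores, dtype=float)
        return lrp.RelevanceVector(v / v.sum(), 0, normalized=True)

    def test_threshold_keeps_strictly_above(self):
        rv = self._rv([0.9985, 0.001, 0.0005])
        sel = select_features(rv, ("threshold", 0.002))
        assert sel.n_selected == 1
        assert sel.selected_indices[0] == 0

    def test_top_k_100_of_4943(self):
        rng = np.random.default_rng(9)
        rv = self._rv(rng.random(4943))
        sel = select_features(rv, ("top_k", 100))
        assert sel.n_selected == 100
        scores = rv.scores[sel.selected_indices]
        assert (np.diff(scores) <= 0).all()  # rank order

    def test_top_k_saturates_at_feature_count(self):
        sel = select_features(self._rv([1, 2, 3]), ("top_k", 10))
        assert sel.n_selected == 3
        assert list(sel.selected_indices) == [2, 1, 0]

    def test_ties_break_toward_lower_index(self):
        sel = select_features(self._rv([1.0, 2.0, 2.0, 1.0]), ("top_k", 2))
        assert list(sel.selected_indices) == [1, 2]

    def test_invalid_rules_rejected(self):
        rv = self._rv([1, 1])
        with pytest.raises(ValueError):
            select_features(rv, ("threshold", 1.0))
        with pytest.raises(ValueError):
            select_features(rv, ("top_k", 0))
        with pytest.raises(ValueError):
            select_features(rv, ("magic", 1))

    def test_unnormalized_relevance_rejected(self):
        rv = lrp.RelevanceVector(np.array([1.0, 2.0]), 0)
        with pytest.raises(ValueError, match="normalized"):
            select_features(rv, ("top_k", 1))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_threshold_selection_bounded_by_pigeonhole(self, seed):
        # scores sum to 1, so at most 1/tau - 1 < 500 can strictly exceed
        # tau = 0.002
        rng = np.random.default_rng(seed)
        rv = self._rv(rng.random(1378) ** 4)
        sel = select_features(rv, ("threshold", 0.002))
        assert sel.n_selected <= 499


class TestApplySelection:
    def _selection(self, scores, rule):
        v = np.asarray(scores, dtype=float)
        rv = lrp.RelevanceVector(v / v.sum(), 0, normalized=True)
        return select_features(rv, rule)

    def test_select_all_reorders_columns_by_rank(self):
        X = np.arange(12, dtype=float).reshape(3, 4)
        sel = self._selection([0.1, 0.4, 0.2, 0.3], ("top_k", 4))
        out = apply_selection(X, sel)
        assert np.array_equal(out, X[:, [1, 3, 2, 0]])

    def test_empty_selection_warns_and_returns_zero_width(self):
        with pytest.warns(UserWarning):
            sel = self._selection([0.25] * 4, ("threshold", 0.5))
        X = np.ones((5, 4))
        with pytest.warns(UserWarning):
            out = apply_selection(X, sel)
        assert out.shape == (5, 0)

    def test_duplicate_rows_preserved(self):
        X = np.tile(np.arange(4, dtype=float), (2, 1))
        sel = self._selection([0.4, 0.3, 0.2, 0.1], ("top_k", 2))
        out = apply_selection(X, sel)
        assert np.array_equal(out[0], out[1])

    def test_width_mismatch_rejected(self):
        sel = self._selection([0.5, 0.5], ("top_k", 1))
        with pytest.raises(ValueError, match="features"):
            apply_selection(np.ones((2, 5)), sel)
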