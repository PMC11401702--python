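"""Splits, MLP / baseline training, PCA ablation path, metric identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octma.classify import (
    MLPSpec,
    SplitSpec,
    evaluate,
    hidden_neuron_sweep,
    make_splits,
    metrics_from_confusion,
    pca_feature_path,
    train_baseline,
    train_mlp,
)


def _toy_separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n // 2, 2)), rng.normal(3, 0.3, (n // 2, 2))])
    y = np.array(["MA"] * (n // 2) + ["normal"] * (n // 2))
    return X, y


class TestMakeSplits:
    def test_study_sizes_and_stratification(self):
        ids = [f"s{i}" for i in range(202)]
        labels = ["MA"] * 92 + ["normal"] * 110
        spec = make_splits(ids, labels, SplitSpec(seed=0))
        sizes = {name: len(spec.ids(name)) for name in ("train", "validation", "test")}
        assert sorted(sizes.values()) == [30, 30, 142]
        for name, frac in zip(("train", "validation", "test"), (0.70, 0.15, 0.15)):
            n_ma = sum(labels[int(i[1:])] == "MA" for i in spec.ids(name))
            assert abs(n_ma - 92 * frac) <= 1

    def test_seed_determinism(self):
        ids = [f"s{i}" for i in range(50)]
        labels = (["MA", "normal"] * 25)[:50]
        a = make_splits(ids, labels, SplitSpec(seed=5))
        b = make_splits(ids, labels, SplitSpec(seed=5))
        assert a.assignment == b.assignment

    def test_all_train_fractions(self):
        ids = ["a", "b", "c"]
        spec = make_splits(ids, ["MA", "normal", "MA"], SplitSpec(fractions=(1.0, 0.0, 0.0)))
        assert set(spec.assignment.values()) == {"train"}

    def test_disjoint_and_exhaustive(self):
        ids = [f"s{i}" for i in range(37)]
        labels = ["MA" if i % 3 else "normal" for i in range(37)]
        spec = make_splits(ids, labels, SplitSpec(seed=2))
        assert sorted(spec.assignment) == sorted(ids)


class TestMetrics:
    def test_perfect_confusion_all_hundred(self):
        m = metrics_from_confusion(30, 0, 30, 0)
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision) == (100.0,) * 4

    def test_hand_computed_case(self):
        # (TP, FP, TN, FN) = (73, 5, 105, 19), totals 202
        m = metrics_from_confusion(73, 5, 105, 19)
        assert round(m.accuracy, 2) == 88.12
        assert round(m.sensitivity, 2) == 79.35
        assert round(m.specificity, 2) == 95.45
        assert round(m.precision, 2) == 93.59

    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        tn=st.integers(0, 500), fn=st.integers(0, 500),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identities_on_random_confusions(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics_from_confusion(tp, fp, tn, fn)
        assert m.accuracy == 100.0 * (tp + tn) / (tp + fp + tn + fn)
        for value, num, den in (
            (m.sensitivity, tp, tp + fn),
            (m.specificity, tn, tn + fp),
            (m.precision, tp, tp + fp),
        ):
            if den == 0:
                assert np.isnan(value)
            else:
                assert value == 100.0 * num / den
                assert 0.0 <= value <= 100.0

    def test_zero_denominator_warns_not_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = metrics_from_confusion(0, 0, 10, 0)
        assert np.isnan(m.sensitivity)

    def test_all_positive_predictor(self):
        m = metrics_from_confusion(15, 15, 0, 0)
        assert m.sensitivity == 100.0 and m.specificity == 0.0


class TestTrainMlp:
    def test_fits_linearly_separable_toy(self):
        X, y = _toy_separable()
        model = train_mlp(X, y, X, y, MLPSpec(seed=0))
        assert evaluate(model, X, y).accuracy == 100.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError, match="single-class"):
            train_mlp(X, ["MA"] * 10, X, ["MA"] * 10)

    def test_label_shuffle_gives_chance_accuracy(self):
        """Null check: shuffled labels must not be learnable."""
        rng = np.random.default_rng(1)
        X = rng.random((80, 5))
        accs = []
        for seed in range(20):
            y = np.array(["MA", "normal"] * 40)
            np.random.default_rng(seed).shuffle(y)
            tr, te = slice(0, 60), slice(60, 80)
            model = train_mlp(X[tr], y[tr], X[te], y[te], MLPSpec(seed=seed, max_epochs=100))
            accs.append(evaluate(model, X[te], y[te]).accuracy)
        assert 35.0 <= np.mean(accs) <= 65.0

    def test_seed_determinism(self):
        X, y = _toy_separable()
        a = train_mlp(X, y, X, y, MLPSpec(seed=4))
        b = train_mlp(X, y, X, y, MLPSpec(seed=4))
        assert np.array_equal(a.predict_proba_positive(X), b.predict_proba_positive(X))


class TestBaselines:
    def test_knn_k1_memorizes_training_set(self):
        X, y = _toy_separable()
        model = train_baseline("knn", X, y, k=1)
        assert evaluate(model, X, y).accuracy == 100.0

    def test_linear_svm_separates_toy(self):
        X, y = _toy_separable()
        model = train_baseline("linear_svm", X, y)
        assert evaluate(model, X, y).accuracy == 100.0

    def test_unknown_kind_rejected(self):
        X, y = _toy_separable()
        with pytest.raises(ValueError, match="unknown baseline"):
            train_baseline("random_forest", X, y)


class DescriptorSetStub:
    def __init__(self, matrix):
        self.matrix = matrix


class TestPcaFeaturePath:
    def _sets(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return [DescriptorSetStub(rng.random((4, 6))) for _ in range(n)]

    def test_components_orthonormal(self):
        vecs, pca = pca_feature_path(self._sets(), n_components=5)
        G = pca.components_ @ pca.components_.T
        assert np.allclose(G, np.eye(5), atol=1e-8)

    def test_explained_variance_non_increasing(self):
        _, pca = pca_feature_path(self._sets(), n_components=6)
        ev = pca.explained_variance_ratio_
        assert np.all(np.diff(ev) <= 1e-12)

    def test_full_rank_projection_reconstructs(self):
        sets = self._sets(n=30)
        vecs, pca = pca_feature_path(sets, n_components=24)
        flat = np.stack([s.matrix.ravel() for s in sets])
        assert np.allclose(pca.inverse_transform(vecs), flat, atol=1e-8)

    def test_components_exceeding_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            pca_feature_path(self._sets(n=5), n_components=30)

    def test_fitted_on_training_strips_only(self):
        sets = self._sets(n=20, seed=1)
        mask = np.zeros(20, dtype=bool)
        mask[:10] = True
        _, pca_a = pca_feature_path(sets, n_components=3, train_mask=mask)
        _, pca_b = pca_feature_path(sets[:10], n_components=3)
        assert np.allclose(pca_a.components_, pca_b.components_)


class TestHiddenNeuronSweep:
    def test_single_entry_matches_direct_run(self):
        X, y = _toy_separable()
        rows = hidden_neuron_sweep(X, y, X, y, X, y, neuron_range=[10], seeds=[0])
        direct = evaluate(train_mlp(X, y, X, y, MLPSpec(hidden_neurons=10, seed=0)), X, y)
        assert rows[0]["mean_accuracy"] == direct.accuracy

    def test_range_completes_with_valid_accuracies(self):
        X, y = _toy_separable(n=40)
        rows = hidden_neuron_sweep(X, y, X, y, X, y, neuron_range=[1, 3, 5], seeds=[0, 1])
        assert len(rows) == 3
        assert all(0.0 <= r["mean_accuracy"] <= 100.0 for r in rows)

    def test_empty_range_rejected(self):
        X, y = _toy_separable(n=20)
        with pytest.raises(ValueError):
            hidden_neuron_sweep(X, y, X, y, X, y, neuron_range=[], seeds=[0])
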