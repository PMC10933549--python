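"""Rankers, the frequency baseline, Shapley attribution, method predictor."""

import itertools
import math
import pickle

import numpy as np
import pytest

from nextgene import (
    METHOD_CATEGORIES,
    CategoricalSource,
    MethodPredictor,
    PairFeaturizer,
    PairRanker,
    attribute,
    frequency_baseline,
    rank_genes,
    train_ranker,
)


def separable_data(n=80, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    X[y == 1] += 2.0
    return X, y


class TestPairRanker:
    def test_separable_logistic_is_perfect(self):
        X, y = separable_data()
        model = train_ranker(X, y, algorithm="logistic_regression")
        assert (model.predict(X) == y).mean() == 1.0

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="single class"):
            train_ranker(X, np.ones(5))

    def test_permuted_labels_give_chance_auroc(self):
        from nextgene import auroc

        rng = np.random.default_rng(1)
        X = rng.normal(size=(600, 5))
        y = rng.integers(0, 2, size=600)  # labels independent of features
        model = train_ranker(X[:400], y[:400], algorithm="logistic_regression")
        held = auroc(model.score_pairs(X[400:]), y[400:])
        assert abs(held - 0.5) < 0.12

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_ranker(*separable_data(), algorithm="perceptron")

    @pytest.mark.parametrize("algorithm", ["gradient_boosting", "naive_bayes", "knn"])
    def test_probabilities_in_unit_interval(self, algorithm):
        X, y = separable_data()
        model = train_ranker(X, y, algorithm=algorithm)
        p = model.score_pairs(X)
        assert ((p >= 0) & (p <= 1)).all()

    def test_pickle_round_trip_bit_identical(self):
        X, y = separable_data()
        model = train_ranker(X, y, algorithm="gradient_boosting")
        clone = pickle.loads(pickle.dumps(model))
        np.testing.assert_array_equal(model.score_pairs(X), clone.score_pairs(X))


def shared_term_featurizer():
    ann = {"Q": {"t"}, "A": {"t"}, "B": {"t"}, "C": set(), "D": set()}
    return PairFeaturizer([CategoricalSource("go", ann)], min_genes=1).fit()


class TestRankGenes:
    def fitted(self, fz):
        # label = "both annotated with t" so the model learns the single slot
        pairs = [("Q", "A"), ("Q", "B"), ("Q", "C"), ("Q", "D"), ("A", "B"), ("C", "D")]
        X = fz.transform(pairs)
        y = X[:, 0].astype(int)
        return train_ranker(X, y, algorithm="logistic_regression")

    def test_sort_contract_and_permutation(self):
        fz = shared_term_featurizer()
        model = self.fitted(fz)
        r = rank_genes(model, "Q", ["A", "B", "C"], fz)
        assert sorted(r.genes) == ["A", "B", "C"]
        assert [e[2] for e in r.entries] == [1, 2, 3]
        assert all(a >= b for a, b in zip(r.scores, r.scores[1:]))

    def test_term_sharing_genes_rank_first(self):
        fz = shared_term_featurizer()
        model = self.fitted(fz)
        r = rank_genes(model, "Q", ["A", "B", "C", "D"], fz)
        assert set(r.genes[:2]) == {"A", "B"}

    def test_scores_invariant_to_universe_order(self):
        fz = shared_term_featurizer()
        model = self.fitted(fz)
        a = rank_genes(model, "Q", ["A", "B", "C", "D"], fz)
        b = rank_genes(model, "Q", ["D", "C", "B", "A"], fz)
        assert dict(zip(a.genes, a.scores)) == dict(zip(b.genes, b.scores))

    def test_query_excluded_and_unknown_query_rejected(self):
        fz = shared_term_featurizer()
        model = self.fitted(fz)
        r = rank_genes(model, "Q", ["Q", "A", "B"], fz)
        assert "Q" not in r.genes
        with pytest.raises(KeyError, match="NOPE"):
            rank_genes(model, "NOPE", ["A"], fz)

    def test_top_view_truncates(self, small_world):
        from nextgene.pipeline import run_experiment

        # cheap synthetic check of the display contract on a real ranking
        fz = shared_term_featurizer()
        model = self.fitted(fz)
        universe = ["A", "B", "C", "D"]
        assert len(rank_genes(model, "Q", universe, fz).top(2)) == 2


class TestFrequencyBaseline:
    def test_orders_by_count(self):
        r = frequency_baseline({"A": 5, "B": 2, "C": 9})
        assert r.genes == ["C", "A", "B"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            frequency_baseline({"A": -1})


def exact_shapley(f, x, background):
    """Brute-force Shapley values by subset enumeration (oracle)."""
    m = len(x)
    phis = np.zeros(m)
    idx = list(range(m))
    for i in idx:
        others = [j for j in idx if j != i]
        for size in range(m):
            for S in itertools.combinations(others, size):
                weight = math.factorial(size) * math.factorial(m - size - 1) / math.factorial(m)
                with_i = value_of(f, x, background, set(S) | {i})
                without_i = value_of(f, x, background, set(S))
                phis[i] += weight * (with_i - without_i)
    return phis


def value_of(f, x, background, subset):
    rows = background.copy()
    for j in subset:
        rows[:, j] = x[j]
    return float(np.mean(f(rows)))


class TestAttribution:
    def linear(self, w):
        return lambda X: X @ np.asarray(w)

    def test_ignored_feature_gets_zero(self):
        f = self.linear([1.0, 0.0, 2.0])
        bg = np.random.default_rng(0).normal(size=(20, 3))
        att = attribute(f, np.array([1.0, 5.0, -1.0]), bg, n_permutations=50, seed=0)
        assert att.contributions["f1"] == pytest.approx(0.0, abs=1e-12)

    def test_additive_model_closed_form(self):
        w = np.array([2.0, -1.0, 0.5, 3.0])
        f = self.linear(w)
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(200, 4))
        x = np.array([1.0, 2.0, -1.0, 0.5])
        att = attribute(f, x, bg, n_permutations=400, seed=0)
        got = np.array([att.contributions[f"f{i}"] for i in range(4)])
        expected = w * (x - bg.mean(axis=0))
        np.testing.assert_allclose(got, expected, atol=0.15)

    def test_matches_exact_enumeration_on_small_model(self):
        """Sampled permutations converge to the subset-enumeration oracle."""
        rng = np.random.default_rng(2)
        W = rng.normal(size=(5, 5))

        def f(X):
            return np.tanh(X @ W).sum(axis=1)  # non-additive

        bg = rng.normal(size=(8, 5))
        x = rng.normal(size=5)
        att = attribute(f, x, bg, n_permutations=3000, seed=3)
        got = np.array([att.contributions[f"f{i}"] for i in range(5)])
        oracle = exact_shapley(f, x, bg.copy())
        np.testing.assert_allclose(got, oracle, atol=0.05)

    def test_efficiency_property(self):
        rng = np.random.default_rng(4)
        f = lambda X: np.sin(X).prod(axis=1)
        bg = rng.normal(size=(30, 6))
        x = rng.normal(size=6)
        att = attribute(f, x, bg, n_permutations=200, seed=5)
        total = sum(att.contributions.values())
        assert total == pytest.approx(att.score - att.baseline_score, abs=1e-9)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            attribute(self.linear([1.0]), np.ones(1), np.zeros((2, 1)), n_permutations=0)

    def test_grouped_by_source(self):
        f = self.linear([1.0, 1.0])
        from nextgene import build_schema, NumericalSource, EmbeddingSource

        schema = build_schema(
            numerical=[NumericalSource("expr", {"A": np.zeros(3)})],
            embedding=[EmbeddingSource("w2v", {"A": np.ones(2)})],
        )
        att = attribute(f, np.ones(2), np.zeros((5, 2)), n_permutations=10, seed=0,
                        schema=schema)
        grouped = att.grouped_by_source()
        assert set(grouped) == {"expr", "w2v"}
        assert sum(grouped.values()) == pytest.approx(att.score - att.baseline_score)


class TestMethodPredictor:
    def test_single_category_training(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        model = MethodPredictor().fit(X, ["GWAS"] * 10)
        probs = model.predict_proba(X)
        assert probs.shape == (10, 20)
        assert (probs[:, list(METHOD_CATEGORIES).index("GWAS")] == 1.0).all()

    def test_rows_are_simplex(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = [METHOD_CATEGORIES[i % 4] for i in range(60)]
        probs = MethodPredictor().fit(X, y).predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_unseen_category_rejected(self):
        with pytest.raises(ValueError, match="closed category set"):
            MethodPredictor().fit(np.zeros((2, 1)), ["patch clamp", "GWAS"])

    def test_planted_signal_beats_chance(self):
        rng = np.random.default_rng(2)
        n = 400
        X = rng.normal(size=(n, 3))
        idx = rng.integers(0, 5, size=n)
        X[:, 0] = idx + 0.1 * rng.normal(size=n)  # category determined by one feature
        y = [METHOD_CATEGORIES[i] for i in idx]
        model = MethodPredictor().fit(X[:300], y[:300])
        acc = (model.predict(X[300:]) == np.asarray(y[300:], dtype=object)).mean()
        assert acc > 0.5  # well above the 1/20 chance level
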