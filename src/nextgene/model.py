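"""Ranking models, the frequency baseline, Shapley attribution, and
next-method category prediction.

The core estimator is :class:`PairRanker`, a binary classifier over
featurized gene pairs trained with negative sampling; ranking the genome
for a query gene means scoring every (query, candidate) tuple and sorting
by predicted probability.  Scores are raw classifier probabilities — no
calibration is applied.

Per-suggestion explanations use a model-agnostic sampled-permutation
Shapley estimator: for each sampled permutation, features are switched one
at a time from a background draw to the instance value and the marginal
score changes are accumulated.  The estimator satisfies the Shapley
efficiency property (contributions sum to the score minus the mean
background score) and converges to the exact subset-enumeration values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y
from xgboost import XGBClassifier

from .corpus import METHOD_CATEGORIES
from .features import FeatureSchema, PairFeaturizer

ALGORITHMS = (
    "gradient_boosting",
    "logistic_regression",
    "svm",
    "random_forest",
    "mlp",
    "naive_bayes",
    "knn",
)


def _make_estimator(algorithm: str, seed: int, hyperparams: dict | None):
    hp = dict(hyperparams or {})
    if algorithm == "gradient_boosting":
        hp.setdefault("n_estimators", 200)
        hp.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=seed, n_jobs=1, **hp)
    if algorithm == "logistic_regression":
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=seed, **hp)
    if algorithm == "svm":
        hp.setdefault("probability", True)
        return SVC(random_state=seed, **hp)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if algorithm == "mlp":
        hp.setdefault("max_iter", 500)
        return MLPClassifier(random_state=seed, **hp)
    if algorithm == "naive_bayes":
        return GaussianNB(**hp)
    if algorithm == "knn":
        return KNeighborsClassifier(**hp)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


class PairRanker(ClassifierMixin, BaseEstimator):
    """Binary classifier over featurized gene pairs.

    Parameters
    ----------
    algorithm
        One of ``gradient_boosting`` (XGBoost), ``logistic_regression``,
        ``svm``, ``random_forest``, ``mlp``, ``naive_bayes``, ``knn``.
    seed
        Random seed threaded into the underlying estimator.
    hyperparams
        Optional overrides of the underlying library defaults; everything
        used is recorded on the fitted artifact.
    """

    def __init__(self, algorithm: str = "gradient_boosting", seed: int = 0,
                 hyperparams: dict | None = None):
        self.algorithm = algorithm
        self.seed = seed
        self.hyperparams = hyperparams

    def fit(self, X, y) -> "PairRanker":
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        self.estimator_ = _make_estimator(self.algorithm, self.seed, self.hyperparams)
        self.estimator_.fit(X, y)
        self.classes_ = np.asarray(self.estimator_.classes_)
        self.n_features_in_ = X.shape[1]
        self.hyperparams_ = self.estimator_.get_params()
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator_.predict_proba(np.asarray(X))

    def predict(self, X) -> np.ndarray:
        return self.estimator_.predict(np.asarray(X))

    def score_pairs(self, X) -> np.ndarray:
        """Probability of the positive (consecutive-pair) class."""
        pos = int(np.flatnonzero(self.classes_ == 1)[0])
        return self.predict_proba(X)[:, pos]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PairRanker":
        return joblib.load(path)


def train_ranker(features, labels, algorithm: str = "gradient_boosting",
                 hyperparams: dict | None = None, seed: int = 0) -> PairRanker:
    """Thin functional wrapper over :class:`PairRanker`."""
    return PairRanker(algorithm=algorithm, seed=seed, hyperparams=hyperparams).fit(
        features, labels
    )


@dataclass
class RankedSuggestion:
    """Descending-score ranking of a candidate universe for one query."""

    query_gene: str
    entries: list[tuple[str, float, int]]  # (gene, score, 1-based rank)
    universe_size: int

    def __post_init__(self) -> None:
        scores = [s for _, s, _ in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing with rank")
        if [r for _, _, r in self.entries] != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be 1..n without gaps")

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.asarray([s for _, s, _ in self.entries])

    def top(self, k: int) -> list[tuple[str, float, int]]:
        return self.entries[:k]


def ranking_from_scores(query: str, genes: Sequence[str], scores: np.ndarray) -> RankedSuggestion:
    order = np.argsort(-scores, kind="stable")
    entries = [(genes[i], float(scores[i]), rank + 1) for rank, i in enumerate(order)]
    return RankedSuggestion(query_gene=query, entries=entries, universe_size=len(genes))


def rank_genes(
    model: PairRanker,
    query_gene: str,
    universe: Sequence[str],
    featurizer: PairFeaturizer,
) -> RankedSuggestion:
    """Score (query, candidate) for every candidate and sort descending.

    The universe must exclude the query gene itself (it is removed here if
    present).  The query must be known to the featurizer's gene table.
    """
    if query_gene not in featurizer.gene_index_:
        raise KeyError(f"unknown query gene {query_gene!r}")
    cands = [g for g in universe if g != query_gene]
    X = featurizer.transform([(query_gene, g) for g in cands])
    return ranking_from_scores(query_gene, cands, model.score_pairs(X))


def frequency_baseline(experiment_counts: Mapping[str, int]) -> RankedSuggestion:
    """Query-independent ranking by historical experiment count.

    Ranks genes by the number of experiments that targeted them in the
    training-period literature; downstream tie handling (jitter) is the
    evaluator's job.
    """
    genes = list(experiment_counts)
    counts = np.asarray([experiment_counts[g] for g in genes], dtype=float)
    if (counts < 0).any():
        raise ValueError("experiment counts must be nonnegative")
    return ranking_from_scores("", genes, counts)


@dataclass
class Attribution:
    """Per-feature Shapley contributions for one suggestion."""

    pair: tuple[str, str]
    contributions: dict[str, float]
    top_k: list[tuple[str, float]]
    baseline_score: float
    score: float

    def grouped_by_source(self) -> dict[str, float]:
        """Sum of contributions per source (column name prefix)."""
        out: dict[str, float] = {}
        for col, v in self.contributions.items():
            src = col.split(":", 1)[0]
            out[src] = out.get(src, 0.0) + v
        return out


def attribute(
    predict: Callable[[np.ndarray], np.ndarray] | PairRanker,
    feature_vector: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 64,
    seed: int = 0,
    top_k: int = 10,
    schema: FeatureSchema | None = None,
    pair: tuple[str, str] = ("", ""),
) -> Attribution:
    """Sampled-permutation Shapley attribution of one prediction.

    For each of ``n_permutations`` sampled feature orderings, a background
    row is drawn and features are switched to the instance values in
    permutation order; the marginal score changes telescope, so the summed
    contributions equal score(instance) − mean score(sampled backgrounds)
    exactly, and each feature's average converges to its Shapley value
    under the background distribution.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must be nonempty")
    x = np.asarray(feature_vector, dtype=float).ravel()
    m = x.shape[0]
    f = predict.score_pairs if isinstance(predict, PairRanker) else predict

    rng = np.random.default_rng(seed)
    contrib = np.zeros(m)
    base_scores = []
    for _ in range(n_permutations):
        perm = rng.permutation(m)
        bg = background[int(rng.integers(background.shape[0]))]
        # rows[j] has the first j features (in perm order) set to x
        rows = np.tile(bg, (m + 1, 1))
        for j, feat in enumerate(perm):
            rows[j + 1 :, feat] = x[feat]
        scores = np.asarray(f(rows), dtype=float)
        contrib[perm] += np.diff(scores)
        base_scores.append(scores[0])
    contrib /= n_permutations
    names = schema.column_names() if schema is not None else [f"f{i}" for i in range(m)]
    contributions = dict(zip(names, contrib.tolist()))
    order = np.argsort(-np.abs(contrib), kind="stable")[:top_k]
    return Attribution(
        pair=pair,
        contributions=contributions,
        top_k=[(names[i], float(contrib[i])) for i in order],
        baseline_score=float(np.mean(base_scores)),
        score=float(f(x[None, :])[0]),
    )


class MethodPredictor(ClassifierMixin, BaseEstimator):
    """Multiclass logistic regression over the 20 method categories.

    ``predict_proba`` always returns a probability simplex over the full
    closed category set (unobserved categories get probability 0); ties in
    the argmax are broken by fixed category order.
    """

    categories: tuple[str, ...] = METHOD_CATEGORIES

    def __init__(self, seed: int = 0, max_iter: int = 2000):
        self.seed = seed
        self.max_iter = max_iter

    def fit(self, X, y: Sequence[str]) -> "MethodPredictor":
        y = list(y)
        unseen = set(y) - set(self.categories)
        if unseen:
            raise ValueError(f"labels outside the closed category set: {sorted(unseen)}")
        X = np.asarray(X, dtype=float)
        self._single_class = len(set(y)) == 1
        if self._single_class:
            self._only = y[0]
        else:
            self.estimator_ = LogisticRegression(max_iter=self.max_iter, random_state=self.seed)
            self.estimator_.fit(X, y)
        self.classes_ = np.asarray(self.categories, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros((X.shape[0], len(self.categories)))
        if self._single_class:
            out[:, self.categories.index(self._only)] = 1.0
            return out
        probs = self.estimator_.predict_proba(X)
        for j, cat in enumerate(self.estimator_.classes_):
            out[:, self.categories.index(cat)] = probs[:, j]
        return out

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]


def train_method_predictor(features, method_categories: Sequence[str],
                           seed: int = 0) -> MethodPredictor:
    """Thin functional wrapper over :class:`MethodPredictor`."""
    return MethodPredictor(seed=seed).fit(features, method_categories)


def predict_method(predictor: MethodPredictor, features) -> np.ndarray:
    """Category probability simplex for each featurized query pair."""
    return predictor.predict_proba(np.atleast_2d(features))
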