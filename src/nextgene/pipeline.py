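"""End-to-end driver: corpus → pairs → features → model → evaluation.

Composes the individual modules into the full recommendation experiment
on any world (real files or the synthetic generator): extract the ordered
experiment list, build consecutive different-gene pairs, split them
temporally, train a ranker on sampled negatives, and score whole-genome
rankings per query with AUROC@k against the held-out partners, alongside
the literature-frequency baseline and a network RWR comparator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import AllPositiveClassifier, ExperimentMention, build_term_index
from .evaluation import (
    EvalConfig,
    QueryEval,
    evaluate_ranking,
    evaluation_report,
    filter_ambiguous,
    rwr_ranking,
)
from .features import PairFeaturizer
from .model import MethodPredictor, PairRanker, ranking_from_scores, rank_genes
from .pairs import SplitDataset, build_pairs, sample_negatives, temporal_split
from .simulate import SimConfig, SimWorld, generate_world


def partner_map(pairs) -> dict[str, set[str]]:
    """query gene → set of genes analyzed right after it."""
    out: dict[str, set[str]] = {}
    for p in pairs:
        if p.label == 1:
            out.setdefault(p.gene_prev, set()).add(p.gene_next)
    return out


@dataclass
class ExperimentResult:
    """Everything the end-to-end run produces."""

    world: SimWorld
    mentions: list[ExperimentMention]
    split: SplitDataset
    featurizer: PairFeaturizer
    ranker: PairRanker
    evals: dict[str, list[QueryEval]]  # model name → per-query evaluations
    method_accuracy: float
    n_queries: int
    skipped_queries: int
    config: EvalConfig = field(default_factory=EvalConfig)

    def mean_auroc_at_k(self, model: str, k: int) -> float:
        return float(np.mean([e.auroc_at_k[k] for e in self.evals[model]]))

    def report(self, model: str) -> pd.DataFrame:
        return evaluation_report(self.evals[model], self.config)


def run_experiment(
    sim_config: SimConfig = SimConfig(),
    algorithm: str = "gradient_boosting",
    neg_ratio: int = 3,
    eval_config: EvalConfig | None = None,
    eval_split: str = "test",
    with_rwr: bool = True,
    seed: int = 0,
    world: SimWorld | None = None,
) -> ExperimentResult:
    """Run the full pipeline on a (synthetic by default) world.

    ``seed`` drives negative sampling, model training and evaluation
    jitter; the world itself is governed by ``sim_config.seed``.
    """
    if world is None:
        world = generate_world(sim_config)
    eval_config = eval_config or EvalConfig(k_values=(100,), seed=seed)

    index = build_term_index(world.gene_records, world.method_terms, min_length=3)
    mentions = extract_mentions(world, index)
    positives = build_pairs(mentions)
    split = temporal_split(positives)
    universe = world.coding_genes

    negatives = sample_negatives(split.train, universe, ratio=neg_ratio, seed=seed)
    featurizer = PairFeaturizer(
        world.categorical_sources, world.numerical_sources, world.embedding_sources
    ).fit()
    X_train = featurizer.transform(split.train + negatives)
    y_train = np.array([1] * len(split.train) + [0] * len(negatives))
    ranker = PairRanker(algorithm=algorithm, seed=seed).fit(X_train, y_train)

    eval_pairs = split.test if eval_split == "test" else split.validation
    train_partners = partner_map(split.train)
    eval_partners = partner_map(eval_pairs)

    counts = Counter(
        m.gene_symbol for m in mentions if m.year <= split.boundaries[0]
    )

    evals: dict[str, list[QueryEval]] = {"ranker": [], "frequency": []}
    if with_rwr:
        evals["rwr"] = []
    skipped = 0
    for query in sorted(eval_partners):
        if query not in featurizer.gene_index_:
            skipped += 1
            continue
        pos = eval_partners[query]
        tp = train_partners.get(query, set())

        def scored(ranking) -> QueryEval | None:
            return evaluate_ranking(filter_ambiguous(ranking, tp, pos), pos, eval_config)

        r_model = scored(rank_genes(ranker, query, universe, featurizer))
        if r_model is None:
            skipped += 1
            continue
        evals["ranker"].append(r_model)

        cands = [g for g in universe if g != query]
        cscores = np.asarray([counts.get(g, 0) for g in cands], dtype=float)
        evals["frequency"].append(scored(ranking_from_scores(query, cands, cscores)))

        if with_rwr:
            if query in world.network.graph:
                rr = rwr_ranking(world.network, query, universe=universe)
            else:
                rr = ranking_from_scores(query, cands, np.zeros(len(cands)))
            evals["rwr"].append(scored(rr))

    # drop any None from comparators where the model eval was defined
    for name in list(evals):
        evals[name] = [e for e in evals[name] if e is not None]

    method_accuracy = _method_prediction_accuracy(world, mentions, split, featurizer, seed)
    return ExperimentResult(
        world=world,
        mentions=mentions,
        split=split,
        featurizer=featurizer,
        ranker=ranker,
        evals=evals,
        method_accuracy=method_accuracy,
        n_queries=len(evals["ranker"]),
        skipped_queries=skipped,
        config=eval_config,
    )


def extract_mentions(world: SimWorld, index=None) -> list[ExperimentMention]:
    """Dictionary-match + all-positive relation extraction over the corpus."""
    from .corpus import extract_experiments

    if index is None:
        index = build_term_index(world.gene_records, world.method_terms, min_length=3)
    return extract_experiments(world.corpus, index, AllPositiveClassifier(), threshold=0.5)


def _method_prediction_accuracy(
    world: SimWorld, mentions, split: SplitDataset, featurizer: PairFeaturizer, seed: int
) -> float:
    """Train the next-method category predictor; held-out accuracy."""
    cat_of = {t.name: t.category for t in world.method_terms}
    rows_train, y_train, rows_test, y_test = [], [], [], []
    by_article: dict[str, list] = {}
    for m in mentions:
        by_article.setdefault(m.article_id, []).append(m)
    train_end, _, test_start = split.boundaries
    for ms in by_article.values():
        for prev, nxt in zip(ms, ms[1:]):
            if prev.gene_symbol == nxt.gene_symbol:
                continue
            pair = (prev.gene_symbol, nxt.gene_symbol)
            cat = cat_of[nxt.method_name]
            if prev.year <= train_end:
                rows_train.append(pair)
                y_train.append(cat)
            elif prev.year >= test_start:
                rows_test.append(pair)
                y_test.append(cat)
    if not rows_train or not rows_test:
        return float("nan")
    predictor = MethodPredictor(seed=seed).fit(featurizer.transform(rows_train), y_train)
    pred = predictor.predict(featurizer.transform(rows_test))
    return float(np.mean(pred == np.asarray(y_test, dtype=object)))
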