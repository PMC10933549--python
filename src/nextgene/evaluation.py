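"""Ranking evaluation: AUROC / AUROC@k, network comparators, statistics.

A ranking of the gene universe for one query is scored against the genes
actually analyzed after that query in held-out articles.  AUROC@k zeroes
the scores of every candidate ranked below *k* before computing the AUROC,
so it measures whether true partners surface among the top-k suggestions.
Ties are broken reproducibly by adding uniform jitter bounded by 1e-10 to
every score once per ranking, before zeroing.

Network comparators rank candidates either by a stored pairwise link score
(raw STRING/FunCoup-style tables) or by random-walk-with-restart (RWR)
proximity on a weighted undirected gene network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.metrics import roc_auc_score

from .model import RankedSuggestion, ranking_from_scores


@dataclass
class EvalConfig:
    """Knobs of the ranking evaluation."""

    k_values: tuple[int, ...] = (100, 1000)
    jitter_bound: float = 1e-10
    seed: int = 0
    bootstrap_n: int = 10_000

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.k_values):
            raise ValueError("k must be >= 1")
        if self.jitter_bound <= 0:
            raise ValueError("jitter_bound must be positive")


@dataclass
class QueryEval:
    """Per-query ranking quality."""

    query_gene: str
    auroc: float
    auroc_at_k: dict[int, float]
    n_positives: int
    n_candidates: int


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outscores a random negative.

    Ties count one half (the Mann–Whitney convention).  Both classes must
    be present.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both label classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auroc_at_k(
    ranking: RankedSuggestion,
    positive_set: Iterable[str],
    k: int,
    jitter_bound: float = 1e-10,
    seed: int = 0,
) -> float:
    """AUROC after zeroing the scores of candidates ranked below k.

    Uniform jitter in (0, ``jitter_bound``) is added to every score to
    break ties, candidates are re-ranked on the jittered scores, scores at
    rank > k are set to 0, and the plain AUROC of the modified scores
    against the positive labels is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    positives = set(positive_set)
    genes = ranking.genes
    labels = np.fromiter((g in positives for g in genes), dtype=int, count=len(genes))
    rng = np.random.default_rng(seed)
    scores = ranking.scores + rng.uniform(0.0, jitter_bound, size=len(genes))
    order = np.argsort(-scores, kind="stable")
    modified = scores.copy()
    modified[order[k:]] = 0.0
    return auroc(modified, labels)


def filter_ambiguous(
    ranking: RankedSuggestion,
    train_partners: Iterable[str],
    eval_partners: Iterable[str],
) -> RankedSuggestion:
    """Drop candidates that are neither positive nor negative examples.

    Genes analyzed after the query during the training period but not in
    the evaluation period cannot be labeled either way, so they are
    removed from the ranking before scoring; ranks are recomputed.
    """
    remove = set(train_partners) - set(eval_partners)
    if not remove:
        return ranking
    kept = [(g, s) for g, s, _ in ranking.entries if g not in remove]
    entries = [(g, s, i + 1) for i, (g, s) in enumerate(kept)]
    return RankedSuggestion(ranking.query_gene, entries, len(entries))


# ---------------------------------------------------------------------------
# network comparators


@dataclass
class GeneNetwork:
    """Weighted undirected gene network (STRING-like / FunCoup-like)."""

    graph: nx.Graph
    name: str = "network"

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("network must not contain self-loops")
        weights = [d.get("weight", 1.0) for _, _, d in self.graph.edges(data=True)]
        if weights and not np.all(np.isfinite(weights)):
            raise ValueError("edge weights must be finite")
        if any(w < 0 for w in weights):
            raise ValueError("edge weights must be nonnegative")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], name: str = "network"
    ) -> "GeneNetwork":
        g = nx.Graph()
        for a, b, w in edges:
            g.add_edge(a, b, weight=float(w))
        return cls(g, name)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass
class RWRResult:
    """Seed-relative proximity of every network node."""

    seed_gene: str
    proximity: dict[str, float]
    restart_prob: float
    iterations: int
    residual: float
    unreachable: frozenset[str] = field(default_factory=frozenset)


def rwr(
    network: GeneNetwork,
    seed_gene: str,
    restart_prob: float = 0.15,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> RWRResult:
    """Random walk with restart from one seed node.

    Iterates r ← (1−c)·P·r + c·e with P the column-stochastic transition
    matrix (weighted adjacency with columns normalized by node strength),
    e the seed indicator and c the restart probability, until the L1
    change falls to ``tol``.  The stationary vector is a probability
    distribution over nodes; nodes in components not containing the seed
    get proximity 0 and are flagged.
    """
    nodes = network.nodes
    if seed_gene not in network.graph:
        raise KeyError(f"seed gene {seed_gene!r} not in network")
    if network.graph.number_of_edges() == 0:
        raise ValueError("network has no edges")
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    W = nx.to_scipy_sparse_array(network.graph, nodelist=nodes, weight="weight", format="csc")
    strength = np.asarray(W.sum(axis=0)).ravel()
    inv = np.divide(1.0, strength, out=np.zeros_like(strength), where=strength > 0)
    P = W @ sp.diags(inv)

    e = np.zeros(n)
    e[idx[seed_gene]] = 1.0
    if strength[idx[seed_gene]] == 0:
        import warnings

        warnings.warn(f"seed gene {seed_gene!r} is isolated; proximity degenerates to the seed")
        return RWRResult(seed_gene, dict(zip(nodes, e)), restart_prob, 0, 0.0,
                         frozenset(g for g in nodes if g != seed_gene))
    r = e.copy()
    c = restart_prob
    residual = np.inf
    for it in range(1, max_iter + 1):
        r_new = (1.0 - c) * (P @ r) + c * e
        residual = float(np.abs(r_new - r).sum())
        r = r_new
        if residual <= tol:
            break
    else:
        raise RuntimeError(f"RWR did not converge in {max_iter} iterations (residual {residual:.3g})")
    reachable = set(nx.node_connected_component(network.graph, seed_gene))
    unreachable = frozenset(g for g in nodes if g not in reachable)
    return RWRResult(seed_gene, dict(zip(nodes, r.tolist())), c, it, residual, unreachable)


def rwr_ranking(
    network: GeneNetwork,
    query: str,
    restart_prob: float = 0.15,
    cutoff: float = 0.0,
    universe: Sequence[str] | None = None,
) -> RankedSuggestion:
    """Rank candidates by RWR proximity to the query.

    ``cutoff`` implements the integration rule used when proximities feed
    a downstream model as a feature: proximities below the cutoff export
    as 0.  Candidates outside the network score 0.
    """
    result = rwr(network, query, restart_prob=restart_prob)
    prox = {g: (p if p >= cutoff else 0.0) for g, p in result.proximity.items()}
    cands = [g for g in (universe if universe is not None else network.nodes) if g != query]
    scores = np.asarray([prox.get(g, 0.0) for g in cands])
    return ranking_from_scores(query, cands, scores)


def raw_score_ranking(
    pair_scores: Mapping[tuple[str, str], float],
    query: str,
    universe: Sequence[str],
) -> RankedSuggestion:
    """Rank candidates by a stored symmetric pairwise link score.

    Lookups try (query, gene) then (gene, query); missing pairs score 0.
    """
    cands = [g for g in universe if g != query]
    scores = np.asarray(
        [pair_scores.get((query, g), pair_scores.get((g, query), 0.0)) for g in cands],
        dtype=float,
    )
    return ranking_from_scores(query, cands, scores)


# ---------------------------------------------------------------------------
# whole-evaluation drivers and model comparison


def evaluate_ranking(
    ranking: RankedSuggestion,
    positive_set: set[str],
    config: EvalConfig = EvalConfig(),
) -> QueryEval | None:
    """Score one query's ranking; None when AUROC is undefined."""
    genes = ranking.genes
    n_pos = sum(g in positive_set for g in genes)
    if n_pos == 0 or n_pos == len(genes):
        return None
    labels = [int(g in positive_set) for g in genes]
    return QueryEval(
        query_gene=ranking.query_gene,
        auroc=auroc(ranking.scores, labels),
        auroc_at_k={
            k: auroc_at_k(ranking, positive_set, k, config.jitter_bound, config.seed)
            for k in config.k_values
        },
        n_positives=n_pos,
        n_candidates=len(genes),
    )


def evaluation_report(evals: Sequence[QueryEval], config: EvalConfig = EvalConfig()) -> pd.DataFrame:
    """Tidy per-query table: query, n_pos, auroc, auroc@k columns."""
    rows = []
    for e in evals:
        row = {"query": e.query_gene, "n_pos": e.n_positives,
               "n_candidates": e.n_candidates, "auroc": e.auroc}
        for k in config.k_values:
            row[f"auroc@{k}"] = e.auroc_at_k[k]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ModelComparison:
    """Pairwise Mann–Whitney tests and bootstrap summaries."""

    means: dict[str, float]
    mean_ci: dict[str, tuple[float, float]]
    pairwise: pd.DataFrame  # model_a, model_b, u_stat, p_raw, p_bonferroni,
    #                         mean_diff, diff_ci_low, diff_ci_high


def compare_models(
    per_query_aurocs: Mapping[str, Sequence[float]],
    n_boot: int = 10_000,
    seed: int = 0,
) -> ModelComparison:
    """Compare models on matched per-query AUROC vectors.

    Two-sided Mann–Whitney U per model pair, Bonferroni-corrected across
    all reported pairs; per-model percentile-bootstrap 95% CI of the mean
    and bootstrap CIs of pairwise mean differences (paired resampling of
    queries, ``n_boot`` resamples).
    """
    models = sorted(per_query_aurocs)
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    arrays = {m: np.asarray(per_query_aurocs[m], dtype=float) for m in models}
    n = len(arrays[models[0]])
    if any(len(a) != n for a in arrays.values()):
        raise ValueError("models must be evaluated on the same query set")

    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    means, mean_ci = {}, {}
    boot_means = {}
    for m in models:
        a = arrays[m]
        means[m] = float(a.mean())
        bm = a[boot_idx].mean(axis=1)
        boot_means[m] = bm
        lo, hi = np.percentile(bm, [2.5, 97.5])
        mean_ci[m] = (float(lo), float(hi))

    pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1 :]]
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        if np.array_equal(arrays[a], arrays[b]):
            u, p = float(len(arrays[a]) ** 2 / 2), 1.0
        else:
            u, p = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
        diff_boot = boot_means[a] - boot_means[b]
        lo, hi = np.percentile(diff_boot, [2.5, 97.5])
        rows.append(
            {
                "model_a": a,
                "model_b": b,
                "u_stat": float(u),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * n_comp)),
                "mean_diff": means[a] - means[b],
                "diff_ci_low": float(lo),
                "diff_ci_high": float(hi),
            }
        )
    return ModelComparison(means=means, mean_ci=mean_ci, pairwise=pd.DataFrame(rows))
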