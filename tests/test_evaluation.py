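"""AUROC/AUROC@k, removal rule, RWR against dense-solve oracle, statistics."""

import numpy as np
import pytest

from nextgene import (
    GeneNetwork,
    auroc,
    auroc_at_k,
    compare_models,
    filter_ambiguous,
    raw_score_ranking,
    rwr,
    rwr_ranking,
)
from nextgene.model import ranking_from_scores


def brute_force_auroc(scores, labels):
    """Pairwise positive-vs-negative comparison count (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_four_item_example_matches_enumeration(self):
        scores, labels = [0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]
        assert auroc(scores, labels) == brute_force_auroc(scores, labels)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        assert auroc(scores, labels) == pytest.approx(auroc(np.exp(3 * scores), labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


def zeroed_auroc_oracle(genes, scores, positives, k, jitter):
    """Independent re-implementation of the zero-below-k rule."""
    s = np.asarray(scores) + jitter
    order = np.argsort(-s, kind="stable")
    mod = s.copy()
    mod[order[k:]] = 0.0
    labels = [int(g in positives) for g in genes]
    return brute_force_auroc(mod, labels)


class TestAurocAtK:
    def ranking(self, genes, scores):
        return ranking_from_scores("Q", genes, np.asarray(scores, dtype=float))

    def test_k_at_least_universe_equals_plain_auroc(self):
        genes = list("ABCDEF")
        scores = [0.9, 0.7, 0.6, 0.5, 0.3, 0.1]
        pos = {"A", "D"}
        r = self.ranking(genes, scores)
        labels = [int(g in pos) for g in genes]
        assert auroc_at_k(r, pos, k=6, seed=0) == pytest.approx(auroc(scores, labels), abs=1e-6)

    def test_positives_inside_top_k_give_one(self):
        genes = list("ABCDEF")
        r = self.ranking(genes, [0.9, 0.8, 0.4, 0.3, 0.2, 0.1])
        assert auroc_at_k(r, {"A", "B"}, k=2, seed=0) == 1.0

    def test_matches_hand_enumerated_zeroed_computation(self):
        """Positives at ranks 2 and 5 of 6, k=3, against the oracle."""
        genes = list("ABCDEF")
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        pos = {"B", "E"}
        rng = np.random.default_rng(0)
        jitter = rng.uniform(0, 1e-10, size=6)
        expected = zeroed_auroc_oracle(genes, scores, pos, 3, jitter)
        got = auroc_at_k(self.ranking(genes, scores), pos, k=3, jitter_bound=1e-10, seed=0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_oracle_agreement_on_random_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            n = int(rng.integers(6, 21))
            genes = [f"g{i}" for i in range(n)]
            scores = np.round(rng.random(n), 2)
            pos = set(rng.choice(genes, size=int(rng.integers(1, n - 1)), replace=False))
            k = int(rng.integers(1, n + 1))
            seed = 100 + trial
            r = self.ranking(genes, scores)
            jitter = np.random.default_rng(seed).uniform(0, 1e-10, size=n)
            expected = zeroed_auroc_oracle(r.genes, r.scores, pos, k, jitter)
            got = auroc_at_k(r, pos, k=k, seed=seed)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_jitter_breaks_ties_reproducibly(self):
        genes = list("ABCD")
        r = self.ranking(genes, [0.5, 0.5, 0.5, 0.5])
        a = auroc_at_k(r, {"A"}, k=2, seed=3)
        assert a == auroc_at_k(r, {"A"}, k=2, seed=3)


class TestFilterAmbiguous:
    def ranking(self):
        return ranking_from_scores("Q", ["B", "C", "D"], np.array([0.9, 0.5, 0.1]))

    def test_train_only_partner_removed(self):
        filtered = filter_ambiguous(self.ranking(), {"B"}, {"C"})
        assert filtered.genes == ["C", "D"]
        assert [e[2] for e in filtered.entries] == [1, 2]

    def test_subset_partners_leave_ranking_unchanged(self):
        r = self.ranking()
        assert filter_ambiguous(r, {"C"}, {"B", "C"}) is r

    def test_removal_can_change_auroc_at_k(self):
        # B (top-ranked, train-only) pushes positive C out of top-1
        r = self.ranking()
        before = auroc_at_k(r, {"C"}, k=1, seed=0)
        after = auroc_at_k(filter_ambiguous(r, {"B"}, {"C"}), {"C"}, k=1, seed=0)
        assert after > before


def dense_rwr_oracle(network, seed_gene, c):
    nodes = network.nodes
    import networkx as nx

    W = nx.to_numpy_array(network.graph, nodelist=nodes, weight="weight")
    P = W / W.sum(axis=0, keepdims=True)
    e = np.zeros(len(nodes))
    e[nodes.index(seed_gene)] = 1.0
    r = c * np.linalg.solve(np.eye(len(nodes)) - (1 - c) * P, e)
    return dict(zip(nodes, r))


class TestRWR:
    def test_single_edge_closed_form(self):
        net = GeneNetwork.from_edges([("A", "B", 1.0)])
        res = rwr(net, "A", restart_prob=0.15)
        oracle = dense_rwr_oracle(net, "A", 0.15)
        for g in net.nodes:
            assert res.proximity[g] == pytest.approx(oracle[g], abs=1e-8)

    def test_full_restart_returns_seed_indicator(self):
        net = GeneNetwork.from_edges([("A", "B", 1.0), ("B", "C", 2.0)])
        res = rwr(net, "B", restart_prob=1.0)
        assert res.proximity["B"] == pytest.approx(1.0)
        assert res.proximity["A"] == res.proximity["C"] == pytest.approx(0.0)

    def test_matches_dense_solve_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = int(rng.integers(10, 51))
            edges = [
                (f"n{i}", f"n{j}", float(rng.uniform(0.1, 1)))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.2
            ]
            if not edges:
                continue
            net = GeneNetwork.from_edges(edges)
            seed_gene = net.nodes[0]
            tol = 1e-9
            res = rwr(net, seed_gene, tol=tol)
            oracle = dense_rwr_oracle(net, seed_gene, 0.15)
            l1 = sum(abs(res.proximity[g] - oracle[g]) for g in net.nodes)
            assert l1 <= 10 * tol
            assert sum(res.proximity.values()) == pytest.approx(1.0, abs=1e-6)

    def test_unreachable_component_flagged_with_zero_mass(self):
        net = GeneNetwork.from_edges([("A", "B", 1.0), ("C", "D", 1.0)])
        res = rwr(net, "A")
        assert res.unreachable == {"C", "D"}
        assert res.proximity["C"] == res.proximity["D"] == 0.0

    def test_nonconvergence_raises(self):
        net = GeneNetwork.from_edges([("A", "B", 1.0), ("B", "C", 1.0)])
        with pytest.raises(RuntimeError, match="converge"):
            rwr(net, "A", tol=1e-15, max_iter=2)

    def test_missing_seed_and_self_loop_rejected(self):
        net = GeneNetwork.from_edges([("A", "B", 1.0)])
        with pytest.raises(KeyError):
            rwr(net, "Z")
        with pytest.raises(ValueError, match="self-loops"):
            GeneNetwork.from_edges([("A", "A", 1.0)])


class TestRWRRanking:
    def test_cutoff_zeroes_small_proximities(self):
        net = GeneNetwork.from_edges([("Q", "A", 1.0), ("A", "B", 0.01), ("B", "C", 0.01)])
        res = rwr(net, "Q")
        cut = max(p for g, p in res.proximity.items() if g != "Q") + 1e-6
        ranking = rwr_ranking(net, "Q", cutoff=cut)
        assert (ranking.scores == 0).all()

    def test_star_graph_leaves_tie(self):
        net = GeneNetwork.from_edges([("HUB", f"L{i}", 1.0) for i in range(5)])
        ranking = rwr_ranking(net, "HUB")
        assert len(set(ranking.scores)) == 1


class TestRawScoreRanking:
    def test_missing_pairs_score_zero(self):
        r = raw_score_ranking({("Q", "A"): 0.9, ("Q", "B"): 0.2}, "Q", ["A", "B", "C"])
        assert r.genes == ["A", "B", "C"]
        assert r.scores[2] == 0.0

    def test_symmetric_lookup(self):
        table = {("A", "Q"): 0.9, ("Q", "B"): 0.2}
        a = raw_score_ranking(table, "Q", ["A", "B"])
        assert a.genes == ["A", "B"]

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(15)]
        table = {("Q", g): float(rng.random()) for g in universe}
        r = raw_score_ranking(table, "Q", universe)
        resorted = sorted(universe, key=lambda g: -table[("Q", g)])
        assert r.genes == resorted


class TestCompareModels:
    def test_self_comparison_never_significant(self):
        v = list(np.random.default_rng(0).random(50))
        rep = compare_models({"a": v, "b": v}, n_boot=500, seed=0)
        row = rep.pairwise.iloc[0]
        assert row.p_bonferroni == 1.0
        assert row.diff_ci_low <= 0.0 <= row.diff_ci_high

    def test_separated_distributions_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.8, 0.02, size=200)
        b = rng.normal(0.5, 0.02, size=200)
        rep = compare_models({"good": a, "bad": b}, n_boot=1000, seed=0)
        assert rep.pairwise.iloc[0].p_bonferroni < 0.001

    def test_constant_vector_zero_width_ci(self):
        rep = compare_models({"a": [0.7] * 30, "b": list(range(30))}, n_boot=200, seed=0)
        lo, hi = rep.mean_ci["a"]
        assert lo == hi == pytest.approx(0.7)

    def test_invariant_to_model_labeling_order(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(40), rng.random(40)
        r1 = compare_models({"x": a, "y": b}, n_boot=300, seed=0)
        r2 = compare_models({"y": b, "x": a}, n_boot=300, seed=0)
        assert r1.pairwise.iloc[0].p_raw == r2.pairwise.iloc[0].p_raw

    def test_mismatched_query_sets_rejected(self):
        with pytest.raises(ValueError, match="same query set"):
            compare_models({"a": [0.1, 0.2], "b": [0.3]})
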