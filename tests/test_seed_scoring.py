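"""Score vectors, the rank-based AUC, and the threshold sweep.

The AUC implementation is checked two independent ways: against the
exhaustive positive x negative pairwise-comparison oracle (ties = 1/2) and
against scikit-learn's trapezoidal ROC AUC.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from netgi import (
    FunctionalNetwork,
    SeedSet,
    auc_sweep,
    evaluate_seed_set,
    label_vector,
    roc_auc,
    score_vector,
)

from conftest import make_random_network, pairwise_auc_oracle


class TestScoreVector:
    def test_additive_definition_missing_edges_zero(self):
        net = FunctionalNetwork.from_edges([("g", "A", 1.0), ("g", "C", 2.0)])
        for x in ("D",):
            net.add_gene(x)
        scores = score_vector(net, {"A", "C", "D"})
        assert scores["g"] == 3.0
        assert scores["D"] == 0.0

    def test_partners_without_edges_give_all_zero(self):
        net = FunctionalNetwork()
        for g in "ABCD":
            net.add_gene(g)
        assert set(score_vector(net, {"A", "B"}).values()) == {0.0}

    def test_partner_self_term_excluded_by_no_self_edges(self):
        # a partner's own score counts only edges to the *other* partners:
        # the implicit leave-one-out
        net = FunctionalNetwork.from_edges([("A", "B", 2.0), ("A", "C", 3.0), ("B", "C", 4.0)])
        scores = score_vector(net, {"A", "B"})
        assert scores["A"] == 2.0  # only A-B
        assert scores["B"] == 2.0
        assert scores["C"] == 7.0

    def test_partner_not_in_network_is_hard_error(self):
        net = FunctionalNetwork.from_edges([("A", "B", 1.0)])
        with pytest.raises(ValueError, match="not in network"):
            score_vector(net, {"A", "Q"})

    def test_matches_double_loop_oracle(self, rng):
        net, genes = make_random_network(rng, n_genes=60, n_edges=150)
        partners = set(rng.choice(genes, size=5, replace=False).tolist())
        scores = score_vector(net, partners)
        for g in genes:
            expected = sum(net.weight(g, p) for p in partners)
            assert scores[g] == pytest.approx(expected, abs=1e-12)


class TestLabelVector:
    def test_labels_and_exclusion(self):
        net = FunctionalNetwork()
        for g in "ABCDE":
            net.add_gene(g)
        labels = label_vector(net, {"A", "B"}, exclude={"E"})
        assert labels == {"A": 1, "B": 1, "C": 0, "D": 0}

    def test_positive_count(self, rng):
        net, genes = make_random_network(rng, n_genes=30, n_edges=40)
        partners = set(rng.choice(genes, size=6, replace=False).tolist())
        exclude = {sorted(partners)[0]}
        labels = label_vector(net, partners, exclude=exclude)
        assert sum(labels.values()) == len(partners - exclude)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5}
        labels = {"a": 1, "b": 1, "c": 0, "d": 0}
        assert roc_auc(scores, labels) == 1.0

    def test_pure_ties_give_half(self):
        scores = dict.fromkeys("abcd", 1.0)
        labels = {"a": 1, "b": 0, "c": 0, "d": 1}
        assert roc_auc(scores, labels) == 0.5

    def test_degenerate_labels_raise(self):
        with pytest.raises(ValueError):
            roc_auc({"a": 1.0, "b": 2.0}, {"a": 1, "b": 1})

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_pairwise_oracle_and_sklearn(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(10, 200))
        scores_arr = np.round(rng.uniform(0, 4, size=n), 1)  # forces ties
        labels_arr = (rng.random(n) < 0.2).astype(int)
        if labels_arr.sum() in (0, n):
            labels_arr[0], labels_arr[1] = 1, 0
        genes = [f"g{i}" for i in range(n)]
        scores = dict(zip(genes, scores_arr))
        labels = dict(zip(genes, labels_arr.tolist()))
        got = roc_auc(scores, labels)
        assert got == pytest.approx(pairwise_auc_oracle(scores, labels), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(labels_arr, scores_arr), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.data())
    def test_monotone_transform_invariance_and_label_flip(self, data):
        n = data.draw(st.integers(5, 40))
        scores_arr = data.draw(
            st.lists(st.integers(0, 10), min_size=n, max_size=n))
        labels_arr = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)
            .filter(lambda ls: 0 < sum(ls) < n))
        genes = [f"g{i}" for i in range(n)]
        scores = {g: float(s) for g, s in zip(genes, scores_arr)}
        labels = dict(zip(genes, labels_arr))
        base = roc_auc(scores, labels)
        squashed = {g: np.expm1(0.3 * s) for g, s in scores.items()}  # strictly increasing
        assert roc_auc(squashed, labels) == pytest.approx(base, abs=1e-12)
        flipped = {g: 1 - v for g, v in labels.items()}
        assert roc_auc(scores, flipped) == pytest.approx(1 - base, abs=1e-12)


class TestEvaluateSeedSet:
    def test_planted_clique_is_highly_predictive(self, rng):
        # 5 partners in a tight 5.0-weight clique over a sparse 0.1 background
        genes = [f"g{i:02d}" for i in range(40)]
        net = FunctionalNetwork()
        for g in genes:
            net.add_gene(g)
        clique = genes[:5]
        for i in range(5):
            for j in range(i + 1, 5):
                net.add_edge(clique[i], clique[j], 5.0)
        for _ in range(30):
            i, j = rng.integers(5, 40, size=2)
            if i != j and not net.has_edge(genes[i], genes[j]):
                net.add_edge(genes[i], genes[j], 0.1)
        result = evaluate_seed_set(net, SeedSet("X", frozenset(clique), "SL"))
        assert result.auc >= 0.9
        assert result.auc == pytest.approx(
            pairwise_auc_oracle(result.scores, result.labels), abs=1e-12)

    def test_random_partner_sets_score_near_half(self):
        aucs = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            net, genes = make_random_network(rng, n_genes=100, n_edges=150)
            partners = frozenset(rng.choice(genes, size=4, replace=False).tolist())
            result = evaluate_seed_set(net, SeedSet("X", partners, "SL"))
            aucs.append(result.auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_seed_gene_in_network_is_excluded_from_vectors(self):
        net = FunctionalNetwork.from_edges(
            [("X", "A", 9.0), ("A", "B", 1.0), ("A", "C", 1.0), ("B", "C", 1.0)])
        result = evaluate_seed_set(net, SeedSet("X", frozenset({"A", "B"}), "SL"))
        assert "X" not in result.labels and "X" not in result.scores
        kept = evaluate_seed_set(net, SeedSet("X", frozenset({"A", "B"}), "SL"),
                                 exclude_seed=False)
        assert "X" in kept.labels

    def test_two_partner_minimum_runs(self):
        net = FunctionalNetwork.from_edges([("A", "B", 1.0), ("B", "C", 2.0)])
        result = evaluate_seed_set(net, SeedSet("X", frozenset({"A", "B"}), "SL"))
        assert 0.0 <= result.auc <= 1.0
        assert result.n_positives == 2


class TestAucSweep:
    def _mk_results(self, aucs):
        class R:  # minimal stand-in carrying only .auc
            def __init__(self, a):
                self.auc = a
        return [R(a) for a in aucs]

    def test_boundary_thresholds(self):
        res = self._mk_results([1.0, 1.0])
        sweep = auc_sweep(res, [0.0, 0.9])
        assert sweep[0.0] == 1.0 and sweep[0.9] == 1.0

    def test_empty_results_error(self):
        with pytest.raises(ValueError):
            auc_sweep([], [0.5])

    def test_matches_counting_oracle_and_is_monotone(self, rng):
        aucs = rng.uniform(0, 1, size=50).tolist()
        res = self._mk_results(aucs)
        ts = [round(0.1 * i, 1) for i in range(1, 10)]
        sweep = auc_sweep(res, ts)
        props = [sweep[t] for t in ts]
        for t in ts:
            assert sweep[t] == pytest.approx(
                sum(a >= t for a in aucs) / len(aucs), abs=1e-12)
        assert all(a >= b for a, b in zip(props, props[1:]))
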