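"""Binomial enrichment model: background rate, exact tails, BH-FDR.

binomial_tail is verified against exact rational-arithmetic enumeration of
the probability mass function; bh_fdr against a literal step-up scan and
against statsmodels' implementation.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from netgi import (
    InteractionRecord,
    ProteinComplex,
    background_rate,
    bh_fdr,
    binomial_tail,
    complex_enrichment,
    enrich,
)

from conftest import make_random_records


def exact_tail(k: int, n: int, p: Fraction) -> Fraction:
    """P(X >= k) by exact rational pmf summation."""
    return sum(
        Fraction(math.comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    ) if k <= n else Fraction(0)


class TestBackgroundRate:
    def test_direct_count(self):
        recs = [InteractionRecord("A", "B"), InteractionRecord("C", "D")]
        params = background_rate(recs, {"A", "B", "C", "D"})
        assert params.p == pytest.approx(2 / 6)

    def test_no_interactions_gives_zero(self):
        assert background_rate([], {"A", "B", "C"}).p == 0.0

    def test_pairs_outside_universe_ignored(self):
        recs = [InteractionRecord("A", "B"), InteractionRecord("A", "Z")]
        assert background_rate(recs, {"A", "B", "C"}).p == pytest.approx(1 / 3)

    def test_small_universe_errors(self):
        with pytest.raises(ValueError):
            background_rate([], {"A"})

    def test_matches_pair_enumeration(self, rng):
        genes = [f"g{i}" for i in range(12)]
        recs = make_random_records(rng, genes, n=40)
        uni = set(genes[:9])
        pairs = {(min(a, b), max(a, b))
                 for a, b in itertools.combinations(sorted(uni), 2)
                 if any({r.a, r.b} == {a, b} for r in recs)}
        params = background_rate(recs, uni)
        assert params.p == pytest.approx(len(pairs) / math.comb(9, 2), abs=1e-15)


class TestBinomialTail:
    def test_k_zero_is_full_mass(self):
        for n, p in [(0, 0.0), (5, 0.3), (100, 1.0)]:
            assert binomial_tail(0, n, p) == 1.0

    def test_closed_forms(self):
        assert binomial_tail(2, 2, 0.5) == pytest.approx(0.25, abs=1e-15)
        assert binomial_tail(3, 3, 0.01) == pytest.approx(1e-6, rel=1e-9)

    @pytest.mark.parametrize("bad", [(-1, 5, 0.5), (6, 5, 0.5), (1, 5, 1.5), (1, 5, -0.1)])
    def test_out_of_range_arguments(self, bad):
        with pytest.raises(ValueError):
            binomial_tail(*bad)

    @pytest.mark.parametrize("p", [0.001, 0.01, 0.1, 0.5])
    def test_matches_exact_rational_enumeration(self, p):
        pf = Fraction(p).limit_denominator(10**6)
        for n in range(0, 16):
            for k in range(0, n + 1):
                assert binomial_tail(k, n, float(pf)) == pytest.approx(
                    float(exact_tail(k, n, pf)), abs=1e-12)

    def test_monotonicity(self):
        # non-increasing in k; non-decreasing in p
        for k in range(1, 10):
            assert binomial_tail(k, 10, 0.3) <= binomial_tail(k - 1, 10, 0.3) + 1e-15
        for p1, p2 in [(0.1, 0.2), (0.2, 0.5), (0.5, 0.9)]:
            assert binomial_tail(4, 10, p1) <= binomial_tail(4, 10, p2) + 1e-15


class TestComplexEnrichment:
    def test_fully_interacting_triple(self):
        cpx = ProteinComplex("C1", frozenset({"A", "B", "C"}))
        recs = [InteractionRecord(*pq) for pq in (("A", "B"), ("A", "C"), ("B", "C"))]
        params = background_rate(recs, {"A", "B", "C", "D", "E", "F", "G"})
        (res,) = complex_enrichment([cpx], recs, params)
        assert (res.n, res.k) == (3, 3)
        assert res.pvalue == pytest.approx(params.p**3, rel=1e-9)

    def test_zero_internal_interactions_pvalue_one(self):
        cpx = ProteinComplex("C1", frozenset({"A", "B"}))
        recs = [InteractionRecord("C", "D")]
        params = background_rate(recs, {"A", "B", "C", "D"})
        (res,) = complex_enrichment([cpx], recs, params)
        assert res.k == 0 and res.pvalue == 1.0

    def test_ineligible_complex_reported_not_dropped(self):
        cpx = ProteinComplex("C1", frozenset({"A", "Z"}))  # Z outside universe
        params = background_rate([], {"A", "B", "C"})
        (res,) = complex_enrichment([cpx], [], params)
        assert not res.eligible and res.n == 0 and res.pvalue == 1.0

    def test_counts_match_pair_enumeration(self, rng):
        genes = [f"g{i}" for i in range(20)]
        recs = make_random_records(rng, genes, n=80)
        pairs = {r.pair for r in recs}
        complexes = []
        for i in range(6):
            members = rng.choice(genes, size=int(rng.integers(2, 7)), replace=False)
            complexes.append(ProteinComplex(f"C{i}", frozenset(members.tolist())))
        params = background_rate(recs, genes)
        for res, cpx in zip(complex_enrichment(complexes, recs, params), complexes):
            m = len(cpx.members)
            k = sum(1 for a, b in itertools.combinations(sorted(cpx.members), 2)
                    if (a, b) in pairs)
            assert (res.m, res.n, res.k) == (m, math.comb(m, 2), k)

    def test_overlapping_complexes_each_count_shared_pairs(self):
        recs = [InteractionRecord("A", "B")]
        c1 = ProteinComplex("C1", frozenset({"A", "B", "C"}))
        c2 = ProteinComplex("C2", frozenset({"A", "B", "D"}))
        params = background_rate(recs, {"A", "B", "C", "D"})
        results = complex_enrichment([c1, c2], recs, params)
        assert [r.k for r in results] == [1, 1]  # double-counted by design


def step_up_oracle(pvalues, q):
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    cut = 0
    for rank, i in enumerate(order, start=1):
        if pvalues[i] <= rank * q / m:
            cut = rank
    flags = [False] * m
    for i in order[:cut]:
        flags[i] = True
    return flags


class TestBhFdr:
    def test_single_small_p_flagged(self):
        assert bh_fdr([0.01], q=0.05) == [True]

    def test_all_ones_unflagged(self):
        assert bh_fdr([1.0] * 10) == [False] * 10

    def test_empty_input(self):
        assert bh_fdr([]) == []

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_step_up_scan_and_statsmodels(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(1, 80))
        # mixture of null and signal p-values with duplicates
        p = np.concatenate([rng.uniform(size=n), rng.uniform(0, 0.01, size=max(1, n // 4))])
        p = np.round(np.clip(p, 1e-9, 1.0), 3)
        p[p == 0] = 1e-9
        got = bh_fdr(p.tolist(), q=0.05)
        assert got == step_up_oracle(p.tolist(), 0.05)
        sm_flags, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert got == sm_flags.tolist()


class TestEnrichPipeline:
    def test_flags_only_eligible_complexes(self):
        recs = [InteractionRecord("A", "B")]
        complexes = [
            ProteinComplex("C1", frozenset({"A", "B"})),
            ProteinComplex("C2", frozenset({"Z"})),
        ]
        results, params = enrich(complexes, recs, {"A", "B", "C", "D", "E"})
        by_id = {r.complex_id: r for r in results}
        assert by_id["C2"].significant is False
        assert isinstance(by_id["C1"].significant, bool)
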