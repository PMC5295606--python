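"""Binomial enrichment of genetic interactions within protein complexes.

Model: each of the ``n = C(m, 2)`` member pairs of a complex with ``m``
genes in the universe interacts independently with background probability
``p``, the proportion of all possible gene pairs in the universe that are
known to interact.  With ``k`` observed interacting pairs inside the
complex, the enrichment p-value is the exact binomial upper tail
``P(X >= k)``; complexes are called significant under Benjamini-Hochberg
control of the FDR (5% by default).

The universe defining "all possible gene pairs" is a required, explicit
parameter: the choice (complex catalog + interaction genes, network genes,
or a user list) changes ``p`` and must be reported with any result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .graph_model import Gene, InteractionRecord, ProteinComplex, interacting_pairs

DEFAULT_FDR = 0.05


@dataclass(frozen=True)
class EnrichmentModelParams:
    """Background interaction probability and the universe that defines it."""

    p: float
    universe: frozenset

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"background probability must be in [0, 1], got {self.p}")
        if len(self.universe) < 2:
            raise ValueError("universe must contain at least 2 genes")


@dataclass
class ComplexEnrichment:
    """Per-complex pair counts and binomial tail p-value."""

    complex_id: str
    m: int  # members inside the universe
    n: int  # possible pairs, C(m, 2)
    k: int  # observed interacting pairs
    pvalue: float
    eligible: bool
    significant: Optional[bool] = None  # set by BH step


def background_rate(
    interactions: Iterable[InteractionRecord],
    universe: Iterable[Gene],
) -> EnrichmentModelParams:
    """p = interacting pairs with both genes in the universe / C(|universe|, 2)."""
    uni = frozenset(universe)
    if len(uni) < 2:
        raise ValueError("universe must contain at least 2 genes")
    pairs = {pq for pq in interacting_pairs(interactions) if pq[0] in uni and pq[1] in uni}
    total = math.comb(len(uni), 2)
    return EnrichmentModelParams(p=len(pairs) / total, universe=uni)


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact binomial upper tail P(X >= k) for X ~ Binomial(n, p).

    ``P(X >= 0) = 1`` identically.  Arguments outside ``0 <= k <= n`` or
    ``0 <= p <= 1`` are errors.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"need 0 <= p <= 1, got p={p}")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p))


def complex_enrichment(
    complexes: Iterable[ProteinComplex],
    interactions: Iterable[InteractionRecord],
    params: EnrichmentModelParams,
) -> list[ComplexEnrichment]:
    """Binomial tail p-value per complex.

    A complex with fewer than 2 members inside the universe is ineligible
    and reported with n=0, k=0, pvalue=1.  Overlapping complexes each count
    an interacting pair they share (totals can double-count across
    complexes by design).
    """
    pairs = interacting_pairs(interactions)
    out: list[ComplexEnrichment] = []
    for cpx in complexes:
        members = sorted(cpx.members & params.universe)
        m = len(members)
        if m < 2:
            out.append(ComplexEnrichment(cpx.id, m=m, n=0, k=0, pvalue=1.0, eligible=False))
            continue
        n = math.comb(m, 2)
        k = 0
        for i in range(m):
            for j in range(i + 1, m):
                if (members[i], members[j]) in pairs:
                    k += 1
        out.append(
            ComplexEnrichment(cpx.id, m=m, n=n, k=k, pvalue=binomial_tail(k, n, params.p), eligible=True)
        )
    return out


def bh_fdr(pvalues: Sequence[float], q: float = DEFAULT_FDR) -> list[bool]:
    """Benjamini-Hochberg step-up: flag hypotheses kept at FDR ``q``.

    Sort ascending, find the largest i with ``p(i) <= i * q / m`` and flag
    every hypothesis at rank <= i.  Flags are returned in input order; an
    empty input gives an empty output.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * np.arange(1, m + 1) / m
    passing = np.nonzero(p[order] <= thresh)[0]
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        flags[order[: passing[-1] + 1]] = True
    return flags.tolist()


def enrich(
    complexes: Iterable[ProteinComplex],
    interactions: Iterable[InteractionRecord],
    universe: Iterable[Gene],
    fdr: float = DEFAULT_FDR,
) -> tuple[list[ComplexEnrichment], EnrichmentModelParams]:
    """Convenience pipeline: background rate -> per-complex tails -> BH flags.

    Only eligible complexes enter the BH family; ineligible ones get
    ``significant = False``.
    """
    interactions = list(interactions)
    params = background_rate(interactions, universe)
    results = complex_enrichment(complexes, interactions, params)
    eligible = [r for r in results if r.eligible]
    flags = bh_fdr([r.pvalue for r in eligible], q=fdr)
    for r, f in zip(eligible, flags):
        r.significant = bool(f)
    for r in results:
        if not r.eligible:
            r.significant = False
    return results, params
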