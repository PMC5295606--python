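"""Candidate ranking and display-cluster extraction.

A seed set whose AUC clears the high-confidence threshold (0.9 by default)
is treated as predictive; the unlabelled genes it scores, ranked by summed
edge weight, are its novel candidate interaction partners.  For
visualization, the functional cluster around the partners is extracted with
the display conventions used for such networks: only edges above an LLS
cutoff (3.0) are kept, and a non-partner gene is shown only if it links to
at least two partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .graph_model import FunctionalNetwork, Gene
from .seed_scoring import SeedSetResult

HIGH_CONFIDENCE_AUC = 0.9
DISPLAY_LLS_CUTOFF = 3.0
DISPLAY_MIN_LINKS = 2


class Candidate(NamedTuple):
    gene: Gene
    score: float
    rank: int
    #: midrank percentile of the candidate's score among all scored genes of
    #: this seed set (derived column for cross-seed comparability)
    percentile: float


@dataclass
class CandidateList:
    seed: Gene
    interaction_type: str
    entries: list
    auc_of_seed_set: float


def rank_candidates(
    result: SeedSetResult,
    min_auc: float = HIGH_CONFIDENCE_AUC,
    top_k: Optional[int] = None,
) -> CandidateList:
    """Ranked novel partner candidates from one seed-set result.

    Empty when the seed set's AUC is below ``min_auc``.  Otherwise the
    label-0 genes with positive score, sorted by score descending with ties
    broken by gene id ascending (a deterministic, stable order), truncated
    to ``top_k``.  Zero-score genes carry no functional evidence and are
    never candidates.
    """
    entries: list[Candidate] = []
    if result.auc >= min_auc:
        all_scores = np.asarray(list(result.scores.values()), dtype=float)
        n = all_scores.size
        candidates = sorted(
            ((g, s) for g, s in result.scores.items() if result.labels[g] == 0 and s > 0),
            key=lambda item: (-item[1], item[0]),
        )
        if top_k is not None:
            candidates = candidates[:top_k]
        for rank, (g, s) in enumerate(candidates, start=1):
            below = np.count_nonzero(all_scores < s)
            ties = np.count_nonzero(all_scores == s)
            percentile = 100.0 * (below + 0.5 * ties) / n
            entries.append(Candidate(gene=g, score=s, rank=rank, percentile=percentile))
    return CandidateList(
        seed=result.seed_set.seed,
        interaction_type=result.seed_set.interaction_type,
        entries=entries,
        auc_of_seed_set=result.auc,
    )


@dataclass
class DisplayCluster:
    nodes: set
    edges: set  # {(a, b, weight)} with a < b
    partner_flags: dict

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def extract_display_cluster(
    network: FunctionalNetwork,
    partners: Iterable[Gene],
    lls_cutoff: float = DISPLAY_LLS_CUTOFF,
    min_links: int = DISPLAY_MIN_LINKS,
) -> DisplayCluster:
    """Subgraph of partners and well-connected neighbors for display.

    Keeps edges with weight strictly above ``lls_cutoff`` among partners and
    their neighbors; a non-partner node survives only if, after the edge
    cutoff, it retains edges to at least ``min_links`` distinct partners.
    Partners are always shown, even when isolated.
    """
    partners = set(partners)
    missing = [p for p in partners if p not in network]
    if missing:
        raise ValueError(f"partners not in network: {sorted(missing)[:5]}")

    neighbors: set[Gene] = set()
    for p in partners:
        for nbr, _w in network.neighbors(p):
            neighbors.add(nbr)
    candidates = partners | neighbors

    # supra-cutoff edges among candidate nodes
    strong: list[tuple[Gene, Gene, float]] = []
    links_to_partners: dict[Gene, set[Gene]] = {}
    for a in candidates:
        for b, w in network.neighbors(a):
            if b not in candidates or not a < b:
                continue
            if w > lls_cutoff:
                strong.append((a, b, w))
                for x, y in ((a, b), (b, a)):
                    if y in partners:
                        links_to_partners.setdefault(x, set()).add(y)

    kept = set(partners)
    for g in candidates - partners:
        if len(links_to_partners.get(g, ())) >= min_links:
            kept.add(g)
    edges = {(a, b, w) for a, b, w in strong if a in kept and b in kept}
    return DisplayCluster(
        nodes=kept,
        edges=edges,
        partner_flags={g: (g in partners) for g in kept},
    )
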