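"""Seed-set scoring and leave-one-out ROC/AUC evaluation.

The method scores every gene in the functional network by the sum of its
edge weights to the known interaction partners of a query gene.  Because
the network has no self-edges, each partner's own score omits its self-term,
which makes the evaluation an implicit leave-one-out cross-validation: every
partner is scored exactly as if it had been withheld and predicted back from
the remaining partners.  Ranking the score vector against the binary
partner-label vector yields an ROC curve; its area (AUC) measures how
tightly the partners cluster in the network and hence how predictive the
seed set is for novel interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.stats import rankdata

from .graph_model import FunctionalNetwork, Gene, SeedSet


@dataclass
class SeedSetResult:
    """Scores, labels and AUC for one evaluated seed set."""

    seed_set: SeedSet
    scores: dict
    labels: dict
    auc: float
    n_positives: int
    n_negatives: int


def score_vector(network: FunctionalNetwork, partners: Iterable[Gene]) -> dict:
    """Sum-of-edge-weights score for every gene in the network.

    ``score(g) = sum over partners p of LLS(g, p)``, counting 0 for absent
    edges.  Partners must be network genes (callers pre-intersect).
    """
    partners = set(partners)
    missing = [p for p in partners if p not in network]
    if missing:
        raise ValueError(f"partners not in network: {sorted(missing)[:5]}")
    scores = dict.fromkeys(network.genes, 0.0)
    for p in partners:
        for nbr, w in network.neighbors(p):
            scores[nbr] += w
    return scores


def label_vector(
    network: FunctionalNetwork,
    partners: Iterable[Gene],
    exclude: Iterable[Gene] = (),
) -> dict:
    """Binary labels over network genes: 1 for partners, 0 otherwise.

    Genes in ``exclude`` (typically the seed gene itself when it happens to
    be a network gene) are omitted entirely rather than labelled.
    """
    partners = set(partners)
    missing = [p for p in partners if p not in network]
    if missing:
        raise ValueError(f"partners not in network: {sorted(missing)[:5]}")
    excluded = set(exclude)
    return {g: int(g in partners) for g in network.genes if g not in excluded}


def roc_auc(scores: Mapping[Gene, float], labels: Mapping[Gene, int]) -> float:
    """Rank-based ROC AUC with midrank tie handling (Mann-Whitney form).

    ``AUC = (R+ - n+(n+ + 1)/2) / (n+ * n-)`` where ``R+`` is the sum of
    midranks of the positives; equivalently the probability that a random
    positive outscores a random negative, ties counting 1/2.  Only genes
    present in ``labels`` are used, so exclusions apply to both vectors.
    """
    genes = list(labels)
    y = np.fromiter((labels[g] for g in genes), dtype=np.int64, count=len(genes))
    s = np.fromiter((scores[g] for g in genes), dtype=np.float64, count=len(genes))
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires at least one positive and one negative label")
    ranks = rankdata(s, method="average")
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_seed_set(
    network: FunctionalNetwork,
    seed_set: SeedSet,
    exclude_seed: bool = True,
) -> SeedSetResult:
    """Score, label and compute the leave-one-out AUC for one seed set.

    With ``exclude_seed`` (default) the seed gene, when present in the
    network, is removed from both vectors rather than scored as a negative.
    Deterministic for a fixed network and seed set.
    """
    exclude = {seed_set.seed} if exclude_seed else set()
    scores = score_vector(network, seed_set.partners)
    labels = label_vector(network, seed_set.partners, exclude=exclude)
    scores = {g: scores[g] for g in labels}
    auc = roc_auc(scores, labels)
    n_pos = sum(labels.values())
    return SeedSetResult(
        seed_set=seed_set,
        scores=scores,
        labels=labels,
        auc=auc,
        n_positives=n_pos,
        n_negatives=len(labels) - n_pos,
    )


def auc_sweep(
    results: Iterable[SeedSetResult],
    thresholds: Iterable[float],
) -> dict[float, float]:
    """Proportion of seed sets with AUC >= t for each threshold t.

    The output is non-increasing in t; an empty result list is an error.
    """
    aucs = np.asarray([r.auc for r in results], dtype=float)
    if aucs.size == 0:
        raise ValueError("auc_sweep requires at least one result")
    out: dict[float, float] = {}
    for t in thresholds:
        t = float(t)
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold {t} outside [0, 1]")
        out[t] = float(np.mean(aucs >= t))
    return out
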