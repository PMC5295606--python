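"""Withholding simulations: how enrichment detectability degrades as known
genetic interactions are removed.

Three withholding modes emulate different discovery regimes:

* ``degree_above`` — remove every pair touching a gene whose interaction
  degree (number of distinct partners, computed on the FULL original set)
  exceeds a cutoff; mimics a world where hub genes had never been screened.
* ``degree_below`` — remove pairs whose both endpoints fall under a degree
  cutoff; mimics losing the sparsely-studied periphery.
* ``random_pairs`` — remove a uniform random fraction of pairs, averaged
  over seeded replicates.

At each point the complex-enrichment pipeline is re-run on the reduced set,
with the background rate recomputed from it (the simulation pretends the
withheld pairs are unknown), and the number of significantly enriched
complexes is recorded.  The gene universe stays fixed across points: the
hypothetical is fewer known interactions, not fewer genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .enrichment import DEFAULT_FDR, background_rate, bh_fdr, complex_enrichment, enrich
from .graph_model import Gene, InteractionRecord, ProteinComplex, degree

Mode = Literal["degree_above", "degree_below", "random_pairs"]


@dataclass
class WithholdingPlan:
    mode: Mode
    cutoffs: Sequence[float]  # integer degree cutoffs, or proportions in [0,1]
    rng_seed: int = 0
    replicates: int = 20  # random mode only

    def __post_init__(self) -> None:
        if self.mode not in ("degree_above", "degree_below", "random_pairs"):
            raise ValueError(f"unknown mode {self.mode!r}")
        cuts = list(self.cutoffs)
        if not cuts:
            raise ValueError("plan needs at least one cutoff/proportion")
        diffs = [b - a for a, b in zip(cuts, cuts[1:])]
        if diffs and not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
            raise ValueError("cutoffs must be strictly monotone")
        if self.mode == "random_pairs":
            if any(not 0.0 <= c <= 1.0 for c in cuts):
                raise ValueError("proportions must lie in [0, 1]")
            if self.replicates < 1:
                raise ValueError("replicates must be >= 1")

    def ordered_cutoffs(self) -> list[float]:
        """Cutoffs ordered from mild to severe withholding."""
        cuts = list(self.cutoffs)
        if self.mode == "degree_above":
            return sorted(cuts, reverse=True)  # lower cutoff removes more
        return sorted(cuts)


@dataclass
class WithholdingPoint:
    severity: float  # the degree cutoff or the random proportion
    withheld_fraction: float
    n_significant: float  # replicate mean in random mode, exact otherwise
    n_eligible: int
    frac_significant: float
    n_significant_min: Optional[int] = None
    n_significant_max: Optional[int] = None


@dataclass
class WithholdingCurve:
    mode: Mode
    points: list
    #: whether the background rate p was recomputed on each reduced set
    #: (the default) or held at the full-set value
    background_recomputed: bool = True


def withhold_by_degree(
    interactions: Iterable[InteractionRecord],
    cutoff: int,
    mode: Literal["above", "below"] = "above",
) -> tuple[set[InteractionRecord], float]:
    """Remove pairs by the interaction degree of their endpoints.

    Degrees are computed once on the full input set.  ``above`` removes a
    pair when either endpoint has degree > cutoff; ``below`` removes a pair
    when both endpoints have degree < cutoff.  Returns the surviving records
    and the withheld fraction of distinct pairs.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    records = set(interactions)
    genes = {g for r in records for g in (r.a, r.b)}
    deg = {g: degree(records, g) for g in genes}
    if mode == "above":
        kept = {r for r in records if deg[r.a] <= cutoff and deg[r.b] <= cutoff}
    elif mode == "below":
        kept = {r for r in records if not (deg[r.a] < cutoff and deg[r.b] < cutoff)}
    else:
        raise ValueError(f"unknown degree mode {mode!r}")
    frac = 0.0 if not records else (len(records) - len(kept)) / len(records)
    return kept, frac


def withhold_random(
    interactions: Iterable[InteractionRecord],
    proportion: float,
    rng_seed,
) -> tuple[set[InteractionRecord], float]:
    """Remove ``floor(proportion * N)`` pairs uniformly without replacement.

    ``rng_seed`` may be an int or anything ``numpy.random.default_rng``
    accepts; the removal is reproducible for a fixed seed.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    records = sorted(set(interactions), key=lambda r: (r.a, r.b, r.interaction_type))
    n_remove = int(proportion * len(records))
    if n_remove == 0:
        return set(records), 0.0
    rng = np.random.default_rng(rng_seed)
    drop = set(rng.choice(len(records), size=n_remove, replace=False).tolist())
    kept = {r for i, r in enumerate(records) if i not in drop}
    frac = 0.0 if not records else n_remove / len(records)
    return kept, frac


def enrichment_curve(
    interactions: Iterable[InteractionRecord],
    complexes: Iterable[ProteinComplex],
    universe: Iterable[Gene],
    plan: WithholdingPlan,
    fdr: float = DEFAULT_FDR,
    recompute_background: bool = True,
) -> WithholdingCurve:
    """Number of significantly enriched complexes at each withholding level.

    By default the background rate is recomputed on each reduced
    interaction set (the withheld pairs are treated as never observed);
    with ``recompute_background=False`` the full-set rate is reused, which
    asks a different question and is recorded on the returned curve.  In
    random mode results are averaged over ``plan.replicates`` independent
    draws per point (seeded deterministically from ``plan.rng_seed``, the
    point index and the replicate index).
    """
    records = set(interactions)
    complexes = list(complexes)
    universe = frozenset(universe)
    fixed_params = None
    if not recompute_background:
        fixed_params = background_rate(records, universe)

    def run_once(reduced: set[InteractionRecord]) -> tuple[int, int]:
        if fixed_params is None:
            results, _params = enrich(complexes, reduced, universe, fdr=fdr)
        else:
            results = complex_enrichment(complexes, reduced, fixed_params)
            eligible_res = [r for r in results if r.eligible]
            flags = bh_fdr([r.pvalue for r in eligible_res], q=fdr)
            for r, f in zip(eligible_res, flags):
                r.significant = bool(f)
        eligible = [r for r in results if r.eligible]
        n_sig = sum(1 for r in eligible if r.significant)
        return n_sig, len(eligible)

    points: list[WithholdingPoint] = []
    for idx, cut in enumerate(plan.ordered_cutoffs()):
        if plan.mode == "random_pairs":
            sigs = []
            frac = 0.0
            n_eligible = 0
            for rep in range(plan.replicates):
                reduced, frac = withhold_random(records, cut, [plan.rng_seed, idx, rep])
                n_sig, n_eligible = run_once(reduced)
                sigs.append(n_sig)
            mean_sig = float(np.mean(sigs))
            points.append(
                WithholdingPoint(
                    severity=float(cut),
                    withheld_fraction=frac,
                    n_significant=mean_sig,
                    n_eligible=n_eligible,
                    frac_significant=mean_sig / n_eligible if n_eligible else 0.0,
                    n_significant_min=int(min(sigs)),
                    n_significant_max=int(max(sigs)),
                )
            )
        else:
            mode = "above" if plan.mode == "degree_above" else "below"
            reduced, frac = withhold_by_degree(records, int(cut), mode=mode)
            n_sig, n_eligible = run_once(reduced)
            points.append(
                WithholdingPoint(
                    severity=float(cut),
                    withheld_fraction=frac,
                    n_significant=float(n_sig),
                    n_eligible=n_eligible,
                    frac_significant=n_sig / n_eligible if n_eligible else 0.0,
                )
            )
    return WithholdingCurve(mode=plan.mode, points=points,
                            background_recomputed=recompute_background)
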