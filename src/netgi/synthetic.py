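"""Synthetic worlds with known ground truth.

The generator embodies the working hypothesis of guilt-by-association
prediction — functionally related genes share genetic interaction partners —
as a generative model.  A world contains:

* a modular functional network: disjoint gene modules wired as cliques with
  a high within-module LLS, plus sparse random background edges at a low
  LLS (two-point weights deliberately straddle the 3.0 display cutoff);
* genetic interactions of two classes: a phenotypic class linking dedicated
  seed genes to partners drawn from a single module (coherent seeds, with a
  controlled fraction of out-of-module noise partners) or drawn uniformly
  (control seeds), and a growth-score class planted densely inside
  "enriched" complexes plus a uniform background;
* protein complexes that either coincide with interaction-dense module
  subsets (enriched) or are uniform random gene sets (null).

Seed genes use identifiers outside the network gene pool: only partners are
scored, and a query gene need not itself be part of the functional network.
Everything is reproducible from ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .graph_model import FunctionalNetwork, InteractionRecord, ProteinComplex, SeedSet
from .io_formats import write_complexes, write_interactions, write_network

SEED_INTERACTION_TYPE = "Phenotypic Enhancement"
COMPLEX_INTERACTION_TYPE = "Negative Genetic"
ORGANISM = "synthetic"


@dataclass
class WorldSpec:
    """Generation parameters; the defaults define the standard test world."""

    n_genes: int = 500
    n_modules: int = 10
    module_size: int = 15
    within_module_lls: float = 4.0
    within_module_edge_prob: float = 1.0  # 1.0: modules are cliques
    background_edge_prob: float = 0.01
    background_lls: float = 0.5
    n_coherent_seeds: int = 20
    partners_per_seed: int = 6
    partner_noise: float = 0.1
    n_random_seeds: int = 20
    n_enriched_complexes: int = 10
    n_null_complexes: int = 10
    complex_size: int = 8
    within_complex_interaction_prob: float = 0.9
    background_interaction_prob: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_module_edge_prob", "background_edge_prob", "partner_noise",
                     "within_complex_interaction_prob", "background_interaction_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.module_size < 3:
            raise ValueError("module_size must be >= 3")
        if self.partners_per_seed < 2:
            raise ValueError("partners_per_seed must be >= 2")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"module demand {self.n_modules}x{self.module_size} exceeds n_genes={self.n_genes}"
            )
        if self.complex_size > self.module_size:
            raise ValueError("complex_size cannot exceed module_size")
        if self.partners_per_seed > self.module_size:
            raise ValueError("partners_per_seed cannot exceed module_size")


@dataclass
class SyntheticWorld:
    spec: WorldSpec
    network: FunctionalNetwork
    interactions: set
    complexes: list
    seed_sets: list
    truth: dict


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_world(spec: WorldSpec) -> SyntheticWorld:
    """Build a reproducible synthetic world from a WorldSpec."""
    rng = np.random.default_rng(spec.rng_seed)
    genes = _gene_ids(spec.n_genes)
    modules = [
        genes[i * spec.module_size : (i + 1) * spec.module_size]
        for i in range(spec.n_modules)
    ]
    module_of = {g: mi for mi, mod in enumerate(modules) for g in mod}

    # --- functional network ------------------------------------------------
    network = FunctionalNetwork()
    for g in genes:
        network.add_gene(g)
    for mod in modules:
        for i in range(len(mod)):
            for j in range(i + 1, len(mod)):
                if spec.within_module_edge_prob >= 1.0 or rng.random() < spec.within_module_edge_prob:
                    network.add_edge(mod[i], mod[j], spec.within_module_lls)
    if spec.background_edge_prob > 0:
        ii, jj = np.triu_indices(spec.n_genes, k=1)
        mod_idx = np.fromiter((module_of.get(g, -1) for g in genes), dtype=np.int64, count=spec.n_genes)
        same_module = (mod_idx[ii] == mod_idx[jj]) & (mod_idx[ii] >= 0)
        hit = (rng.random(ii.size) < spec.background_edge_prob) & ~same_module
        for a, b in zip(ii[hit], jj[hit]):
            network.add_edge(genes[a], genes[b], spec.background_lls)

    interactions: set[InteractionRecord] = set()
    seed_sets: list[SeedSet] = []
    truth_seeds: dict[str, str] = {}

    # --- coherent seeds: partners concentrated in one module ---------------
    # floor: noise below 1/partners_per_seed leaves seed sets fully coherent
    n_noise = int(spec.partner_noise * spec.partners_per_seed)
    n_core = spec.partners_per_seed - n_noise
    for i in range(spec.n_coherent_seeds):
        seed_id = f"SEED_C{i:03d}"
        mod = modules[int(rng.integers(spec.n_modules))]
        core = [mod[j] for j in rng.choice(len(mod), size=n_core, replace=False)]
        outside = sorted(set(genes) - set(mod))
        noise = [outside[j] for j in rng.choice(len(outside), size=n_noise, replace=False)]
        partners = core + noise
        for p in partners:
            interactions.add(
                InteractionRecord(seed_id, p, SEED_INTERACTION_TYPE, ORGANISM, 2015)
            )
        seed_sets.append(SeedSet(seed_id, frozenset(partners), SEED_INTERACTION_TYPE))
        truth_seeds[seed_id] = "coherent"

    # --- control seeds: partners uniform over the network -------------------
    for i in range(spec.n_random_seeds):
        seed_id = f"SEED_R{i:03d}"
        partners = [genes[j] for j in rng.choice(spec.n_genes, size=spec.partners_per_seed, replace=False)]
        for p in partners:
            interactions.add(
                InteractionRecord(seed_id, p, SEED_INTERACTION_TYPE, ORGANISM, 2015)
            )
        seed_sets.append(SeedSet(seed_id, frozenset(partners), SEED_INTERACTION_TYPE))
        truth_seeds[seed_id] = "control"

    # --- complexes and growth-score interactions ----------------------------
    complexes: list[ProteinComplex] = []
    truth_complexes: dict[str, str] = {}
    for i in range(spec.n_enriched_complexes):
        cid = f"CPX_E{i:03d}"
        mod = modules[i % spec.n_modules]
        members = sorted(mod[j] for j in rng.choice(len(mod), size=spec.complex_size, replace=False))
        complexes.append(ProteinComplex(cid, frozenset(members)))
        truth_complexes[cid] = "enriched"
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                if rng.random() < spec.within_complex_interaction_prob:
                    interactions.add(
                        InteractionRecord(members[a_i], members[b_i],
                                          COMPLEX_INTERACTION_TYPE, ORGANISM, 2015)
                    )
    for i in range(spec.n_null_complexes):
        cid = f"CPX_N{i:03d}"
        members = sorted(genes[j] for j in rng.choice(spec.n_genes, size=spec.complex_size, replace=False))
        complexes.append(ProteinComplex(cid, frozenset(members)))
        truth_complexes[cid] = "null"
    if spec.background_interaction_prob > 0:
        ii, jj = np.triu_indices(spec.n_genes, k=1)
        hit = rng.random(ii.size) < spec.background_interaction_prob
        for a, b in zip(ii[hit], jj[hit]):
            interactions.add(
                InteractionRecord(genes[a], genes[b], COMPLEX_INTERACTION_TYPE, ORGANISM, 2015)
            )

    truth = {
        "seeds": truth_seeds,
        "complexes": truth_complexes,
        "modules": {f"M{mi:02d}": mod for mi, mod in enumerate(modules)},
    }
    return SyntheticWorld(
        spec=spec,
        network=network,
        interactions=interactions,
        complexes=complexes,
        seed_sets=seed_sets,
        truth=truth,
    )


def write_world(world: SyntheticWorld, directory) -> dict[str, Path]:
    """Serialize a world to TSV/JSON files readable by io_formats.

    Deterministic: two worlds generated with the same seed produce
    byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": directory / "network.tsv",
        "interactions": directory / "interactions.tsv",
        "complexes": directory / "complexes.tsv",
        "truth": directory / "truth.json",
    }
    write_network(world.network, paths["network"])
    write_interactions(world.interactions, paths["interactions"])
    write_complexes(world.complexes, paths["complexes"])
    payload = {"spec": asdict(world.spec), "truth": world.truth}
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths
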