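"""End-to-end orchestration: simulate -> score -> sweep -> predict ->
enrich -> withhold, with a machine-readable run manifest.

All artifacts are plain TSV/JSON, re-readable by the package's own readers,
and byte-identical across reruns of the same configuration and seed.  All
randomness flows from one top-level seed; stage seeds are derived from it
deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import enrichment, io_formats, prediction, seed_scoring, synthetic, withholding
from .graph_model import FunctionalNetwork

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "score", "sweep", "predict", "enrich", "withhold")

#: the constants of the standard analysis
DEFAULT_MIN_AUC = 0.9
DEFAULT_FDR = 0.05
DEFAULT_LLS_CUTOFF = 3.0
DEFAULT_MIN_LINKS = 2
EXTENDED_AUC_FLOOR = 0.7  # raw-release band for moderately predictive seed sets


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run; defaults are the standard
    analysis constants (AUC >= 0.9 high-confidence, FDR 5%, display LLS
    cutoff 3.0, >= 2 links)."""

    out_dir: str = "netgi_run"
    network_path: Optional[str] = None
    interactions_path: Optional[str] = None
    complexes_path: Optional[str] = None
    mapping_path: Optional[str] = None
    # filter policy
    interaction_type: Optional[str] = None
    organism: Optional[str] = None
    min_partners: int = 2
    exclude_pairs_in_network: bool = True
    year_cutoff: Optional[int] = None
    # analysis constants
    min_auc: float = DEFAULT_MIN_AUC
    fdr: float = DEFAULT_FDR
    lls_cutoff: float = DEFAULT_LLS_CUTOFF
    min_links: int = DEFAULT_MIN_LINKS
    top_k: Optional[int] = 20
    sweep_thresholds: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(1, 10))
    universe: str = "catalog"  # catalog | network | file:PATH
    # withholding
    withhold_mode: str = "random_pairs"
    withhold_cutoffs: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0)
    withhold_replicates: int = 20
    # simulation
    world_spec: Optional[synthetic.WorldSpec] = None
    rng_seed: int = 0
    log_level: str = "INFO"


def _stage_seed(config: RunConfig, stage: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    idx = ALL_STAGES.index(stage)
    return int(np.random.SeedSequence([config.rng_seed, idx]).generate_state(1)[0] % (2**31))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _resolve_universe(config, interactions, complexes, network):
    if config.universe == "catalog":
        uni = {g for c in complexes for g in c.members}
        uni |= {g for r in interactions for g in (r.a, r.b)}
        return uni
    if config.universe == "network":
        return network.genes
    if config.universe.startswith("file:"):
        path = config.universe[5:]
        return {line.strip() for line in open(path) if line.strip()}
    raise ValueError(f"unknown universe policy {config.universe!r}")


def run_pipeline(config: RunConfig, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Execute the requested stages in order and write their artifacts.

    Returns the run manifest (also written to ``manifest.json``).  A stage
    failure removes the partially written output directory and re-raises.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in ALL_STAGES if s in stages]
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        manifest = _run_stages(config, stages, out)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
    return manifest


def _run_stages(config: RunConfig, stages: Sequence[str], out: Path) -> dict:
    manifest: dict = {
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": list(stages),
        "artifacts": {},
        "counts": {},
    }

    network_path = config.network_path
    interactions_path = config.interactions_path
    complexes_path = config.complexes_path

    if "simulate" in stages:
        spec = config.world_spec or synthetic.WorldSpec()
        spec = dataclasses.replace(spec, rng_seed=_stage_seed(config, "simulate"))
        world = synthetic.generate_world(spec)
        paths = synthetic.write_world(world, out / "world")
        network_path = str(paths["network"])
        interactions_path = str(paths["interactions"])
        complexes_path = str(paths["complexes"])
        manifest["artifacts"]["world"] = {k: str(v) for k, v in paths.items()}
        manifest["counts"]["world"] = {
            "genes": world.network.n_genes,
            "edges": world.network.n_edges,
            "interactions": len(world.interactions),
            "complexes": len(world.complexes),
        }
        if config.interaction_type is None:
            config = dataclasses.replace(config, interaction_type=synthetic.SEED_INTERACTION_TYPE)

    network: Optional[FunctionalNetwork] = None
    if network_path:
        network = io_formats.read_network(network_path)
        if config.mapping_path:
            network = io_formats.relabel_network(network, io_formats.read_mapping(config.mapping_path))
    interactions = io_formats.read_interactions(interactions_path) if interactions_path else None

    results = []
    if "score" in stages:
        if network is None or interactions is None:
            raise FileNotFoundError("score stage needs network and interactions inputs")
        policy = io_formats.FilterPolicy(
            min_partners=config.min_partners,
            exclude_pairs_in_network=config.exclude_pairs_in_network,
            year_cutoff=config.year_cutoff,
            interaction_type=config.interaction_type,
            organism=config.organism,
        )
        seed_sets, report = io_formats.build_seed_sets(interactions, network, policy, with_report=True)
        results = [seed_scoring.evaluate_seed_set(network, ss) for ss in seed_sets]
        rows = [
            {
                "seed": r.seed_set.seed,
                "interaction_type": r.seed_set.interaction_type,
                "n_partners_total": report[(r.seed_set.seed, r.seed_set.interaction_type)]["n_partners_total"],
                "n_partners_in_network": r.n_positives,
                "auc": r.auc,
            }
            for r in sorted(results, key=lambda r: (r.seed_set.seed, r.seed_set.interaction_type))
        ]
        df = pd.DataFrame(rows, columns=["seed", "interaction_type", "n_partners_total",
                                         "n_partners_in_network", "auc"])
        _write_tsv(df, out / "seed_results.tsv")
        _write_tsv(df[df["auc"] >= EXTENDED_AUC_FLOOR], out / "seed_results_extended.tsv")
        manifest["artifacts"]["seed_results"] = str(out / "seed_results.tsv")
        manifest["artifacts"]["seed_results_extended"] = str(out / "seed_results_extended.tsv")
        manifest["counts"]["seed_sets"] = len(results)
        manifest["counts"]["high_confidence_seed_sets"] = int(sum(r.auc >= config.min_auc for r in results))

    if "sweep" in stages:
        if not results:
            raise RuntimeError("sweep stage needs score results (run with the score stage)")
        sweep = seed_scoring.auc_sweep(results, config.sweep_thresholds)
        df = pd.DataFrame(
            {"threshold": list(sweep), "proportion": [sweep[t] for t in sweep]}
        )
        _write_tsv(df, out / "sweep.tsv")
        manifest["artifacts"]["sweep"] = str(out / "sweep.tsv")

    if "predict" in stages:
        if not results:
            raise RuntimeError("predict stage needs score results (run with the score stage)")
        rows = []
        for r in sorted(results, key=lambda r: (r.seed_set.seed, r.seed_set.interaction_type)):
            clist = prediction.rank_candidates(r, min_auc=config.min_auc, top_k=config.top_k)
            for c in clist.entries:
                rows.append(
                    {
                        "seed": clist.seed,
                        "candidate": c.gene,
                        "score": c.score,
                        "rank": c.rank,
                        "percentile": c.percentile,
                        "seed_auc": clist.auc_of_seed_set,
                    }
                )
        df = pd.DataFrame(rows, columns=["seed", "candidate", "score", "rank", "percentile", "seed_auc"])
        _write_tsv(df, out / "candidates.tsv")
        manifest["artifacts"]["candidates"] = str(out / "candidates.tsv")
        manifest["counts"]["candidates"] = len(df)

    if "enrich" in stages or "withhold" in stages:
        if interactions is None or not complexes_path:
            raise FileNotFoundError("enrichment stages need interactions and complexes inputs")
        complexes = io_formats.read_complexes(complexes_path)
        enrich_records = interactions
        if "simulate" in stages:
            # the growth-score class carries the planted complex signal
            enrich_records = {
                r for r in interactions
                if r.interaction_type == synthetic.COMPLEX_INTERACTION_TYPE
            }
        universe = _resolve_universe(config, enrich_records, complexes, network)
        manifest["counts"]["universe_genes"] = len(universe)
        manifest["config"]["universe_policy"] = config.universe

        if "enrich" in stages:
            enr, params = enrichment.enrich(complexes, enrich_records, universe, fdr=config.fdr)
            df = pd.DataFrame(
                [
                    {
                        "complex_id": e.complex_id, "m": e.m, "n": e.n, "k": e.k,
                        "p_background": params.p, "pvalue": e.pvalue,
                        "eligible": e.eligible, "significant": bool(e.significant),
                    }
                    for e in sorted(enr, key=lambda e: e.complex_id)
                ]
            )
            _write_tsv(df, out / "enrich.tsv")
            manifest["artifacts"]["enrich"] = str(out / "enrich.tsv")
            manifest["counts"]["significant_complexes"] = int(df["significant"].sum())

        if "withhold" in stages:
            plan = withholding.WithholdingPlan(
                mode=config.withhold_mode,
                cutoffs=tuple(config.withhold_cutoffs),
                rng_seed=_stage_seed(config, "withhold"),
                replicates=config.withhold_replicates,
            )
            curve = withholding.enrichment_curve(
                enrich_records, complexes, universe, plan, fdr=config.fdr
            )
            df = pd.DataFrame(
                [
                    {
                        "severity": p.severity,
                        "withheld_fraction": p.withheld_fraction,
                        "n_significant": p.n_significant,
                        "n_eligible": p.n_eligible,
                        "frac_significant": p.frac_significant,
                        "n_significant_min": p.n_significant_min,
                        "n_significant_max": p.n_significant_max,
                        "background_recomputed": curve.background_recomputed,
                    }
                    for p in curve.points
                ]
            )
            _write_tsv(df, out / "curve.tsv")
            manifest["artifacts"]["curve"] = str(out / "curve.tsv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
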