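"""Readers and writers for the three tabular inputs, plus seed-set assembly.

Formats (all tab-delimited plain text):

* network edge list: ``geneA<TAB>geneB<TAB>LLS``; ``#`` lines are comments;
* genetic interactions: a headered table; a built-in column map recognizes
  BioGRID TAB 2.0 header names, and a simple ``interactor_a``/``interactor_b``
  layout is the native dialect;
* protein complexes: ``complex_id<TAB>gene``; gene-id mapping: ``from<TAB>to``.

Seed-set assembly applies, in a fixed order, the filters that keep the
evaluation non-circular: restrict to one interaction class/organism, drop
records published before a cutoff year, intersect partners with network
genes, and optionally drop seed-partner pairs that are themselves edges of
the functional network.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .graph_model import (
    FunctionalNetwork,
    Gene,
    InteractionRecord,
    ProteinComplex,
    SeedSet,
    normalize_gene,
)

logger = logging.getLogger(__name__)

# Column-role -> header-name maps for interaction tables. Roles: a, b, type,
# organism, year (year optional). Native dialect first, then BioGRID TAB 2.0.
NATIVE_COLUMNS = {
    "a": "interactor_a",
    "b": "interactor_b",
    "type": "experimental_system",
    "organism": "organism",
    "year": "year",
}
BIOGRID_TAB2_COLUMNS = {
    "a": "Official Symbol Interactor A",
    "b": "Official Symbol Interactor B",
    "type": "Experimental System",
    "organism": "Organism Interactor A",
    "year": "Publication Year",
}


@dataclass
class FilterPolicy:
    """Filters applied while assembling seed sets.

    ``min_partners`` enforces the rule that seed sets with only a single
    interacting gene pair are uninformative and dropped.  ``year_cutoff``
    excludes records published before the given year (the circularity guard
    used when the functional network itself was built from pre-cutoff data).
    """

    min_partners: int = 2
    exclude_pairs_in_network: bool = True
    year_cutoff: Optional[int] = None
    interaction_type: Optional[str] = None
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        if self.min_partners < 2:
            raise ValueError("min_partners must be >= 2")


def _open_rows(path):
    with open(path, "r", newline="") as fh:
        yield from csv.reader(fh, delimiter="\t")


def read_network(path, weight_floor: Optional[float] = None) -> FunctionalNetwork:
    """Read a tab-delimited weighted edge list into a FunctionalNetwork.

    Self-edges are dropped with a warning; rows with weight below
    ``weight_floor`` are dropped; malformed rows raise with their line number.
    """
    net = FunctionalNetwork()
    n_rows = 0
    for lineno, row in enumerate(_open_rows(path), start=1):
        if row and row[0] == "#node" and len(row) > 1:
            # isolated-gene declaration: keeps zero-degree genes (scored as
            # zero-evidence negatives) across write/read round trips
            net.add_gene(row[1])
            continue
        if not row or (row[0].startswith("#")):
            continue
        if len(row) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns (geneA, geneB, LLS), got {len(row)}")
        a, b, raw_w = row[0], row[1], row[2]
        try:
            w = float(raw_w)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric weight {raw_w!r}") from None
        n_rows += 1
        if normalize_gene(a) == normalize_gene(b):
            logger.warning("%s:%d: dropping self-edge %s", path, lineno, a)
            continue
        if weight_floor is not None and w < weight_floor:
            continue
        try:
            net.add_edge(a, b, w)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    if n_rows == 0:
        raise ValueError(f"{path}: no edges found")
    return net


def write_network(net: FunctionalNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# geneA\tgeneB\tLLS\n")
        connected = set()
        for a, b, w in net.sorted_edges():
            fh.write(f"{a}\t{b}\t{w!r}\n")
            connected.add(a)
            connected.add(b)
        for g in sorted(net.genes - connected):
            fh.write(f"#node\t{g}\n")


def _resolve_columns(header: list[str], column_map: Optional[dict]) -> dict:
    if column_map is not None:
        maps = [column_map]
    else:
        maps = [NATIVE_COLUMNS, BIOGRID_TAB2_COLUMNS]
    for cmap in maps:
        required = [cmap["a"], cmap["b"], cmap["type"], cmap["organism"]]
        if all(c in header for c in required):
            return cmap
    raise ValueError(
        f"missing required interaction columns; header was {header!r} "
        f"(need interactor A/B, experimental system, organism)"
    )


def read_interactions(path, column_map: Optional[dict] = None) -> set[InteractionRecord]:
    """Read a headered interaction table into deduplicated unordered records.

    One record is kept per (unordered pair, interaction type); when
    duplicates carry different publication years the earliest is retained,
    since the year filter asks when a pair was first reported.  Rows pairing
    a gene with itself are dropped with a warning.
    """
    rows = _open_rows(path)
    try:
        header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty file") from None
    header = [h.strip() for h in header]
    cmap = _resolve_columns(header, column_map)
    idx = {role: header.index(col) for role, col in cmap.items() if col in header}

    best: dict[tuple, InteractionRecord] = {}
    for lineno, row in enumerate(rows, start=2):
        if not row or row[0].startswith("#"):
            continue
        try:
            a = row[idx["a"]]
            b = row[idx["b"]]
            itype = row[idx["type"]].strip()
            org = row[idx["organism"]].strip()
        except IndexError:
            raise ValueError(f"{path}:{lineno}: truncated row") from None
        year: Optional[int] = None
        if "year" in idx and idx["year"] < len(row):
            raw = row[idx["year"]].strip()
            if raw and raw != "-":
                try:
                    year = int(raw)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer year {raw!r}") from None
        if normalize_gene(a) == normalize_gene(b):
            logger.warning("%s:%d: dropping self-interaction %s", path, lineno, a)
            continue
        rec = InteractionRecord(a=a, b=b, interaction_type=itype, organism=org, year=year)
        key = (rec.a, rec.b, rec.interaction_type.lower())
        prev = best.get(key)
        if prev is None:
            best[key] = rec
        elif rec.year is not None and (prev.year is None or rec.year < prev.year):
            best[key] = rec
    return set(best.values())


def write_interactions(records: Iterable[InteractionRecord], path) -> None:
    """Write records in the native dialect (stable sorted order)."""
    cols = NATIVE_COLUMNS
    recs = sorted(records, key=lambda r: (r.a, r.b, r.interaction_type))
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(cols[r] for r in ("a", "b", "type", "organism", "year")) + "\n")
        for r in recs:
            fh.write(
                f"{r.a}\t{r.b}\t{r.interaction_type}\t{r.organism or ''}\t"
                f"{'' if r.year is None else r.year}\n"
            )


def build_seed_sets(
    interactions: Iterable[InteractionRecord],
    network: FunctionalNetwork,
    policy: FilterPolicy,
    with_report: bool = False,
):
    """Assemble one SeedSet per gene with enough usable partners.

    Pipeline order: (i) restrict to the requested interaction type/organism,
    (ii) drop records older than ``year_cutoff`` (records without a year are
    dropped too when a cutoff is set — their discovery date cannot be
    certified), (iii) intersect partners with network genes, (iv) with
    ``exclude_pairs_in_network``, drop seed-partner pairs that are edges of
    the network, then (v) keep seeds with >= ``min_partners`` partners.
    Every gene appearing in any record is a potential seed.

    With ``with_report`` a per-seed dict of dropped-partner counts is
    returned alongside the list.
    """
    recs = list(interactions)
    if policy.interaction_type is not None:
        want = policy.interaction_type.strip().lower()
        recs = [r for r in recs if r.interaction_type.strip().lower() == want]
    if policy.organism is not None:
        want_org = policy.organism.strip().lower()
        recs = [r for r in recs if (r.organism or "").strip().lower() == want_org]
    if policy.year_cutoff is not None:
        recs = [r for r in recs if r.year is not None and r.year >= policy.year_cutoff]

    partners: dict[Gene, dict[str, set[Gene]]] = {}
    for r in recs:
        partners.setdefault(r.a, {}).setdefault(r.interaction_type, set()).add(r.b)
        partners.setdefault(r.b, {}).setdefault(r.interaction_type, set()).add(r.a)

    seed_sets: list[SeedSet] = []
    report: dict[tuple[Gene, str], dict[str, int]] = {}
    for seed in sorted(partners):
        for itype in sorted(partners[seed]):
            raw = partners[seed][itype]
            in_net = {p for p in raw if p in network}
            if policy.exclude_pairs_in_network:
                usable = {p for p in in_net if not network.has_edge(seed, p)}
            else:
                usable = in_net
            report[(seed, itype)] = {
                "n_partners_total": len(raw),
                "n_dropped_not_in_network": len(raw) - len(in_net),
                "n_dropped_network_edge": len(in_net) - len(usable),
                "n_partners_usable": len(usable),
            }
            if len(usable) >= policy.min_partners:
                seed_sets.append(SeedSet(seed=seed, partners=frozenset(usable), interaction_type=itype))
    if with_report:
        return seed_sets, report
    return seed_sets


def read_complexes(path) -> list[ProteinComplex]:
    """Read a two-column (complex_id, gene) membership table.

    Complexes with <2 members are retained but ``eligible`` is False.
    """
    members: dict[str, set[Gene]] = {}
    order: list[str] = []
    n_rows = 0
    for lineno, row in enumerate(_open_rows(path), start=1):
        if not row or row[0].startswith("#"):
            continue
        if row == ["complex_id", "gene"]:  # optional header
            continue
        if len(row) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns (complex_id, gene)")
        cid = row[0].strip()
        gene = normalize_gene(row[1])
        if not cid:
            raise ValueError(f"{path}:{lineno}: empty complex id")
        if cid not in members:
            members[cid] = set()
            order.append(cid)
        members[cid].add(gene)
        n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: no complex memberships found")
    return [ProteinComplex(id=cid, members=frozenset(members[cid])) for cid in order]


def write_complexes(complexes: Iterable[ProteinComplex], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("complex_id\tgene\n")
        for cpx in sorted(complexes, key=lambda c: c.id):
            for g in sorted(cpx.members):
                fh.write(f"{cpx.id}\t{g}\n")


def read_mapping(path) -> dict[Gene, Gene]:
    """Read a two-column gene-id translation table.

    A source id mapped to two different targets is ambiguous and dropped
    entirely with a warning, so the surviving map is a function.
    """
    mapping: dict[Gene, Gene] = {}
    ambiguous: set[Gene] = set()
    n_rows = 0
    for lineno, row in enumerate(_open_rows(path), start=1):
        if not row or row[0].startswith("#"):
            continue
        if len(row) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns (from_id, to_id)")
        src = normalize_gene(row[0])
        dst = normalize_gene(row[1])
        n_rows += 1
        if src in mapping and mapping[src] != dst:
            ambiguous.add(src)
            continue
        mapping[src] = dst
    for src in ambiguous:
        logger.warning("%s: dropping ambiguous mapping for %s", path, src)
        del mapping[src]
    if n_rows == 0:
        raise ValueError(f"{path}: no mappings found")
    return mapping


def relabel_network(net: FunctionalNetwork, mapping: dict[Gene, Gene]) -> FunctionalNetwork:
    """Translate gene ids through a mapping; unmapped genes keep their id.
    Edges whose translated endpoints collide into a self-pair are dropped."""
    out = FunctionalNetwork()
    for g in net.genes:
        out.add_gene(mapping.get(g, g))
    for a, b, w in net.edges():
        ta, tb = mapping.get(a, a), mapping.get(b, b)
        if ta == tb:
            logger.warning("dropping edge %s-%s: both map to %s", a, b, ta)
            continue
        out.add_edge(ta, tb, w)
    return out
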