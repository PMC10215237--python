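"""Compound-target network assembly, filtering and export.

An herbal medicine is modeled as a bipartite graph of compound-protein
interactions (CPIs).  This module loads assembled CPI tables, computes
degree statistics, applies the key-target rule (keep proteins hit by at
least ``min_ingredients`` distinct compounds), and exports the bipartite
network for graph tooling.  Identifier matching is exact, case-sensitive
string equality; id normalization across source databases is the caller's
responsibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("compound_id", "compound_name", "target_id")


@dataclass
class CompoundTargetTable:
    """Unique compound->target interaction records."""

    records: list[tuple[str, str, str]]  # (compound_id, compound_name, target_id)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for cid, _name, tid in self.records:
            if not cid or not tid:
                raise ValidationError("compound and target ids must be nonempty")
            key = (cid, tid)
            if key in seen:
                raise ValidationError(f"duplicate CPI record {key}")
            seen.add(key)

    @property
    def compounds(self) -> list[str]:
        return sorted({cid for cid, _, _ in self.records})

    @property
    def targets(self) -> list[str]:
        return sorted({tid for _, _, tid in self.records})

    def targets_of(self, compound_id: str) -> set[str]:
        return {tid for cid, _, tid in self.records if cid == compound_id}

    def compound_names(self) -> dict[str, str]:
        names = {}
        for cid, name, _ in self.records:
            names.setdefault(cid, name)
        return names

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=list(REQUIRED_COLUMNS))


@dataclass
class DiseaseProteinSet:
    """Disease-associated protein identifiers plus provenance metadata."""

    ids: set[str]
    label: str = ""
    co_occurrence_threshold: float | None = None


@dataclass
class NetworkSummary:
    n_compounds: int
    n_targets: int
    n_cpis: int
    target_degree: dict[str, int] = field(default_factory=dict)


def load_compound_targets(path, provenance: str | None = None) -> CompoundTargetTable:
    """Load a CPI TSV, collapsing duplicate (compound, target) pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"CPI file {path} missing column(s): {', '.join(missing)}")
    if df.empty:
        raise ValidationError(f"CPI file {path} contains no records")
    before = len(df)
    df = df.drop_duplicates(subset=["compound_id", "target_id"], keep="first")
    dropped = before - len(df)
    if dropped:
        logger.info("collapsed %d duplicate CPI record(s) from %s", dropped, path)
    records = [tuple(r) for r in df[list(REQUIRED_COLUMNS)].itertuples(index=False, name=None)]
    return CompoundTargetTable(records=records, provenance=provenance or str(path))


def write_compound_targets(table: CompoundTargetTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REQUIRED_COLUMNS) + "\n")
        for cid, name, tid in sorted(table.records):
            fh.write(f"{cid}\t{name}\t{tid}\n")


def load_disease_proteins(path, label: str = "") -> DiseaseProteinSet:
    """Read one protein id per line; blank lines and '#' comments ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split("\t")[0])
    if not ids:
        raise ValidationError(f"disease protein file {path} is empty")
    return DiseaseProteinSet(ids=ids, label=label or str(path))


def write_disease_proteins(disease: DiseaseProteinSet, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(disease.ids):
            fh.write(pid + "\n")


def summarize(table: CompoundTargetTable) -> NetworkSummary:
    """Exact CPI counts and the per-target distinct-compound degree map."""
    degree: dict[str, set[str]] = {}
    for cid, _, tid in table.records:
        degree.setdefault(tid, set()).add(cid)
    target_degree = {tid: len(cids) for tid, cids in degree.items()}
    return NetworkSummary(
        n_compounds=len({cid for cid, _, _ in table.records}),
        n_targets=len(target_degree),
        n_cpis=len(table.records),
        target_degree=target_degree,
    )


def filter_key_targets(
    table: CompoundTargetTable, min_ingredients: int = 2
) -> CompoundTargetTable:
    """Keep records whose target is hit by >= min_ingredients distinct compounds.

    Compounds left with no surviving target drop out of the roster, so the
    ingredient count can shrink alongside the target count.
    """
    if min_ingredients < 1:
        raise ValidationError("min_ingredients must be >= 1")
    degree = summarize(table).target_degree
    kept = [r for r in table.records if degree[r[2]] >= min_ingredients]
    lost = set(c for c, _, _ in table.records) - set(c for c, _, _ in kept)
    if lost:
        logger.info(
            "key-target filter (min_ingredients=%d) dropped %d compound(s): %s",
            min_ingredients, len(lost), ", ".join(sorted(lost)),
        )
    return CompoundTargetTable(records=kept, provenance=table.provenance)


def export_network(
    table: CompoundTargetTable,
    graphml_path=None,
    sif_path=None,
    annotations: dict[str, dict] | None = None,
):
    """Write the bipartite CPI graph as GraphML and/or SIF.

    Nodes carry ``node_class`` in {compound, target}; ``annotations`` maps
    node id -> extra attributes (e.g. disease or pathway flags).  Returns
    the networkx graph for further use.
    """
    import networkx as nx

    g = nx.Graph()
    names = table.compound_names()
    for cid in table.compounds:
        g.add_node(cid, node_class="compound", name=names.get(cid, cid))
    for tid in table.targets:
        g.add_node(tid, node_class="target")
    for cid, _, tid in table.records:
        g.add_edge(cid, tid, interaction="cpi")
    if annotations:
        for node, attrs in annotations.items():
            if node in g:
                g.nodes[node].update(attrs)
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for cid, _, tid in sorted(table.records):
                fh.write(f"{cid}\tcpi\t{tid}\n")
    return g


def write_summary_json(summary: NetworkSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_compounds": summary.n_compounds,
                "n_targets": summary.n_targets,
                "n_cpis": summary.n_cpis,
                "target_degree": dict(sorted(summary.target_degree.items())),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
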