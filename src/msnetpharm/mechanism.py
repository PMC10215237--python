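"""Mechanism-of-action subgraphs from compound and disease diffusion profiles.

The proposed mechanism for a compound-disease pair is the subnetwork
induced by the most-visited nodes of their two diffusion profiles (top-k
each, default k=20) together with the compound's targets and the disease's
proteins as anchors.  Nodes on the compound side that cannot reach any
disease-side node inside the subgraph (and vice versa) are pruned
iteratively, with connectivity evaluated ignoring edge direction, so the
retained graph always links the two entities.  The highest-visited node is
read as the most relevant element of the mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .diffusion import DiffusionProfile, MultiscaleNetwork
from .errors import ValidationError

logger = logging.getLogger(__name__)


def top_k_nodes(profile: DiffusionProfile, k: int = 20) -> list[str]:
    """The k highest visit-frequency nodes, ties broken lexicographically."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    order = sorted(zip(profile.nodes, profile.frequencies), key=lambda nf: (-nf[1], nf[0]))
    return [n for n, _ in order[:k]]


def _profile_ranks(profile: DiffusionProfile) -> dict[str, int]:
    order = sorted(zip(profile.nodes, profile.frequencies), key=lambda nf: (-nf[1], nf[0]))
    return {n: i + 1 for i, (n, _) in enumerate(order)}


@dataclass
class MechanismSubgraph:
    """Pruned induced subnetwork linking a compound to a disease.

    ``nodes`` rows carry both profile ranks and visit frequencies plus
    anchor flags; ``edges`` is the induced directed edge list with classes.
    """

    nodes: list[dict]
    edges: list[tuple[str, str, str]]
    compound: str
    disease: str
    k: int

    @property
    def node_ids(self) -> set[str]:
        return {row["id"] for row in self.nodes}

    def is_empty(self) -> bool:
        return not self.nodes


def _connected_sides(nodes, edges, compound_side, disease_side):
    """Return the node subset whose component touches the *other* side."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for s, t, _ in edges:
        if s in adj and t in adj:
            adj[s].add(t)
            adj[t].add(s)
    unvisited = set(nodes)
    keep: set[str] = set()
    while unvisited:
        start = unvisited.pop()
        comp = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v in unvisited:
                    unvisited.discard(v)
                    comp.add(v)
                    stack.append(v)
        has_c = bool(comp & compound_side)
        has_d = bool(comp & disease_side)
        for n in comp:
            in_c = n in compound_side
            in_d = n in disease_side
            # a node needs a path to the opposite side; nodes on both sides
            # satisfy the rule trivially
            ok = True
            if in_c and not in_d:
                ok = has_d
            elif in_d and not in_c:
                ok = has_c
            elif not in_c and not in_d:
                ok = has_c and has_d
            if ok:
                keep.add(n)
    return keep


def extract_mechanism_subgraph(
    network: MultiscaleNetwork,
    compound_profile: DiffusionProfile,
    disease_profile: DiffusionProfile,
    compound_targets,
    disease_proteins,
    k: int = 20,
) -> MechanismSubgraph:
    """Top-k union subgraph with the cross-connectivity pruning rule.

    Node set: top-k of each profile plus compound-target and
    disease-protein anchors present in the network; edges are induced from
    the multiscale network.  Compound-side nodes without an undirected
    path to a disease-side node (and symmetrically) are removed, iterating
    to a fixed point since removals can disconnect further nodes.
    """
    net_nodes = set(network.node_class)
    anchors_c = set(compound_targets) & net_nodes
    anchors_d = set(disease_proteins) & net_nodes
    top_c = set(top_k_nodes(compound_profile, k))
    top_d = set(top_k_nodes(disease_profile, k))
    selected = top_c | top_d | anchors_c | anchors_d

    compound_side = anchors_c | top_c
    disease_side = anchors_d | top_d

    def _induced(nodeset):
        return [(s, t, ec) for s, t, ec in network.edges if s in nodeset and t in nodeset]

    current = set(selected)
    while True:
        edges = _induced(current)
        keep = _connected_sides(current, edges, compound_side & current, disease_side & current)
        if keep == current:
            break
        current = keep
    # a component may satisfy per-node rules yet lack any cross-side link
    # (e.g. all-compound-side components when the disease side vanished)
    if not (current & compound_side) or not (current & disease_side):
        current = set()
    edges = sorted(_induced(current))
    if not current:
        logger.warning(
            "mechanism subgraph for %r vs %r is empty after pruning: no mechanism link",
            compound_profile.entity, disease_profile.entity,
        )
    ranks_c = _profile_ranks(compound_profile)
    ranks_d = _profile_ranks(disease_profile)
    freq_c = compound_profile.visit_frequency
    freq_d = disease_profile.visit_frequency
    nodes = [
        {
            "id": n,
            "node_class": network.node_class[n],
            "rank_in_compound_profile": ranks_c[n],
            "rank_in_disease_profile": ranks_d[n],
            "visit_frequency_compound": freq_c[n],
            "visit_frequency_disease": freq_d[n],
            "is_compound_target": n in anchors_c,
            "is_disease_protein": n in anchors_d,
        }
        for n in sorted(current)
    ]
    return MechanismSubgraph(
        nodes=nodes,
        edges=edges,
        compound=compound_profile.entity,
        disease=disease_profile.entity,
        k=k,
    )


def rank_mechanism_nodes(subgraph: MechanismSubgraph) -> pd.DataFrame:
    """Nodes ordered by their best visit frequency across the two profiles."""
    if subgraph.is_empty():
        raise ValidationError("cannot rank an empty mechanism subgraph")
    df = pd.DataFrame(subgraph.nodes)
    df["max_visit_frequency"] = df[
        ["visit_frequency_compound", "visit_frequency_disease"]
    ].max(axis=1)
    df = df.sort_values(
        ["max_visit_frequency", "id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def write_subgraph(
    subgraph: MechanismSubgraph,
    graphml_path=None,
    sif_path=None,
    table_path=None,
) -> None:
    """Serialize the subgraph for Cytoscape-style rendering."""
    if graphml_path is not None:
        import networkx as nx

        g = nx.DiGraph(compound=subgraph.compound, disease=subgraph.disease, k=subgraph.k)
        for row in subgraph.nodes:
            g.add_node(row["id"], **{k: v for k, v in row.items() if k != "id"})
        for s, t, ec in subgraph.edges:
            g.add_edge(s, t, edge_class=ec)
        nx.write_graphml(g, graphml_path)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for s, t, ec in subgraph.edges:
                fh.write(f"{s}\t{ec}\t{t}\n")
    if table_path is not None:
        if subgraph.is_empty():
            pd.DataFrame(
                columns=[
                    "id", "node_class", "rank_in_compound_profile",
                    "rank_in_disease_profile", "visit_frequency_compound",
                    "visit_frequency_disease", "is_compound_target",
                    "is_disease_protein",
                ]
            ).to_csv(table_path, sep="\t", index=False)
        else:
            rank_mechanism_nodes(subgraph).to_csv(table_path, sep="\t", index=False)
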