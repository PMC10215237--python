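"""Synthetic multiscale-network scenarios with planted active compounds.

The generator builds miniature versions of the inputs the analysis expects:

* a multiscale network whose protein layer is a preferential-attachment
  (heavy-tailed) interaction graph, whose function layer is a random
  hierarchy (tree plus optional extra child->ancestor links), and whose
  annotation layer links proteins to functions at a configurable rate;
* a disease protein set sampled as a BFS ball around a seed protein, so
  the disease is network-localized (diffusion-profile correlation carries
  no signal for a scattered disease);
* a compound library in which *planted* compounds draw a configurable
  fraction of their targets from the disease set and its immediate
  interactors, while decoy compounds draw targets from the rest of the
  proteome where possible;
* a pathway library of protein sets, one of which is seeded to overlap
  the disease cluster.

All randomness flows from the scenario's single integer seed through one
numpy Generator, so a scenario reproduces byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .assembly import (
    CompoundTargetTable,
    DiseaseProteinSet,
    load_compound_targets,
    load_disease_proteins,
    write_compound_targets,
    write_disease_proteins,
)
from .diffusion import (
    PROTEIN,
    MultiscaleNetwork,
    load_multiscale_network,
    write_network_tsv,
)
from .enrich import GeneSetLibrary, read_gmt, write_gmt
from .errors import GenerationError, ParameterError


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults describe the standard test scenario: a 200-protein,
    50-function network with a mean protein degree of ~6, fourteen
    compounds with target-set sizes in the 7-64 range observed for herbal
    ingredient libraries, a 20-protein localized disease cluster, one
    planted active compound whose targets all fall in the disease
    neighborhood, and nine pathways of 10-35 proteins.
    """

    n_proteins: int = 200
    n_functions: int = 50
    ppi_edges: int = 600
    annotation_rate: float = 2.0
    hierarchy_branching: float = 2.0
    ff_edges: int | None = None
    n_compounds: int = 14
    targets_per_compound: tuple[int, int] = (7, 64)
    n_disease_proteins: int = 20
    planted_compounds: tuple[str, ...] = ("C01",)
    planted_overlap_fraction: float = 1.0
    n_pathways: int = 9
    pathway_size_range: tuple[int, int] = (10, 35)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_functions": self.n_functions,
            "ppi_edges": self.ppi_edges,
            "n_compounds": self.n_compounds,
            "n_pathways": self.n_pathways,
            "n_disease_proteins": self.n_disease_proteins,
        }
        for name, value in counts.items():
            if value < 1:
                raise ParameterError(f"{name} must be positive, got {value}")
        if not (0.0 <= self.planted_overlap_fraction <= 1.0):
            raise ParameterError("planted_overlap_fraction must be in [0, 1]")
        lo, hi = self.targets_per_compound
        if not (1 <= lo <= hi):
            raise ParameterError("targets_per_compound must be a valid integer range")
        if hi > self.n_proteins:
            raise ParameterError("targets_per_compound max cannot exceed n_proteins")
        if self.n_disease_proteins > self.n_proteins:
            raise ParameterError("n_disease_proteins cannot exceed n_proteins")
        plo, phi = self.pathway_size_range
        if not (1 <= plo <= phi) or phi > self.n_proteins:
            raise ParameterError("pathway_size_range must fit within n_proteins")
        cap = self.n_proteins * (self.n_proteins - 1) // 2
        if self.ppi_edges > cap:
            raise ParameterError(
                f"ppi_edges={self.ppi_edges} exceeds simple-graph capacity {cap}"
            )
        if self.ppi_edges < self.n_proteins - 1:
            raise ParameterError(
                "ppi_edges must be at least n_proteins - 1 to keep every protein connected"
            )
        if self.annotation_rate < 0:
            raise ParameterError("annotation_rate must be nonnegative")
        if self.ff_edges is not None and self.ff_edges < self.n_functions - 1:
            raise ParameterError("ff_edges cannot be below the spanning-tree minimum")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ScenarioBundle:
    """All inputs for one synthetic run, plus the planted-compound truth."""

    network: MultiscaleNetwork
    compounds: CompoundTargetTable
    disease: DiseaseProteinSet
    pathways: GeneSetLibrary
    truth: dict
    scenario: SyntheticScenario

    def __post_init__(self) -> None:
        proteins = {n for n, c in self.network.node_class.items() if c == PROTEIN}
        for tid in self.compounds.targets:
            if tid not in proteins:
                raise GenerationError(f"compound target {tid} is not a network protein")
        if not self.disease.ids <= proteins:
            raise GenerationError("disease proteins must be network protein nodes")
        for name, members in self.pathways.sets.items():
            if not members <= proteins:
                raise GenerationError(f"pathway {name} members outside network proteins")
        compound_ids = set(self.compounds.compounds)
        if not set(self.truth.get("planted", [])) <= compound_ids:
            raise GenerationError("truth labels reference unknown compounds")


def _protein_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def _function_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"F{i + 1:0{width}d}" for i in range(n)]


def _preferential_attachment_edges(
    n: int, n_edges: int, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Simple undirected scale-free-like graph with exactly ``n_edges`` edges."""
    m = max(1, round(n_edges / n))
    edges: set[tuple[int, int]] = set()
    repeated: list[int] = []  # degree-weighted sampling pool

    def _add(u: int, v: int) -> bool:
        if u == v:
            return False
        key = (min(u, v), max(u, v))
        if key in edges:
            return False
        edges.add(key)
        repeated.extend(key)
        return True

    start = min(m + 1, n)
    for u in range(start):
        for v in range(u + 1, start):
            _add(u, v)
    for new in range(start, n):
        attached = 0
        attempts = 0
        while attached < min(m, new) and attempts < 50 * m:
            pick = int(repeated[rng.integers(len(repeated))])
            attempts += 1
            if _add(new, pick):
                attached += 1
    # trim or grow to the exact requested count
    while len(edges) > n_edges:
        deg: dict[int, int] = {}
        for u, v in edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        removable = sorted(e for e in edges if deg[e[0]] > 1 and deg[e[1]] > 1)
        if not removable:
            break
        drop = removable[rng.integers(len(removable))]
        edges.remove(drop)
        repeated.remove(drop[0])
        repeated.remove(drop[1])
    guard = 0
    while len(edges) < n_edges and guard < 1000 * n_edges:
        guard += 1
        u = int(repeated[rng.integers(len(repeated))])
        v = int(rng.integers(n))
        _add(u, v)
    if len(edges) != n_edges:
        raise GenerationError(
            f"could not realize {n_edges} protein-protein edges (got {len(edges)})"
        )
    return edges


def generate_multiscale_network(scenario: SyntheticScenario, rng=None) -> MultiscaleNetwork:
    """Generate the three-layer network of one scenario.

    Protein-protein topology is preferential attachment with the exact
    requested edge count; the function layer is a random tree (mean
    children ~ hierarchy_branching) optionally densified with extra
    child->earlier-function links to reach ``ff_edges``; annotations are
    ``round(annotation_rate * n_proteins)`` distinct protein-function
    pairs.  Pure function of the scenario seed.
    """
    rng = rng if rng is not None else scenario.rng()
    prot = _protein_ids(scenario.n_proteins)
    func = _function_ids(scenario.n_functions)
    raw: list[tuple[str, str, str]] = []

    for u, v in sorted(_preferential_attachment_edges(scenario.n_proteins, scenario.ppi_edges, rng)):
        raw.append((prot[u], prot[v], "pp"))

    # function hierarchy: queue-based tree with Poisson(branching) capacities
    ff: set[tuple[int, int]] = set()
    if scenario.n_functions > 1:
        queue: list[list[int]] = [[0, max(1, int(rng.poisson(scenario.hierarchy_branching)))]]
        for child in range(1, scenario.n_functions):
            if not queue:
                queue.append([child - 1, 1])
            parent = queue[0][0]
            ff.add((child, parent))
            queue[0][1] -= 1
            if queue[0][1] <= 0:
                queue.pop(0)
            queue.append([child, max(1, int(rng.poisson(scenario.hierarchy_branching)))])
        target_ff = scenario.ff_edges if scenario.ff_edges is not None else len(ff)
        guard = 0
        while len(ff) < target_ff and guard < 1000 * target_ff:
            guard += 1
            child = int(rng.integers(1, scenario.n_functions))
            parent = int(rng.integers(0, child))
            ff.add((child, parent))
        if len(ff) < target_ff:
            raise GenerationError(f"could not realize {target_ff} hierarchy edges")
    for child, parent in sorted(ff):
        raw.append((func[child], func[parent], "ff"))

    n_pf = round(scenario.annotation_rate * scenario.n_proteins)
    cap = scenario.n_proteins * scenario.n_functions
    if n_pf > cap:
        raise ParameterError(f"annotation_rate implies {n_pf} pf edges > capacity {cap}")
    annotated_functions: set[int] = set()
    if n_pf:
        flat = rng.choice(cap, size=n_pf, replace=False)
        for code in sorted(int(x) for x in flat):
            p, f = divmod(code, scenario.n_functions)
            raw.append((prot[p], func[f], "pf"))
            annotated_functions.add(f)
    # an isolated function (possible when n_functions == 1) gets one annotation
    if scenario.n_functions == 1 and not annotated_functions:
        p = int(rng.integers(scenario.n_proteins))
        raw.append((prot[p], func[0], "pf"))

    node_class = {p: "protein" for p in prot}
    node_class.update({f: "function" for f in func})
    return MultiscaleNetwork.from_raw(raw, node_class=node_class)


def _pp_adjacency(network: MultiscaleNetwork) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {p: [] for p in network.proteins}
    for s, t, ec in network.edges:
        if ec == "pp":
            adj[s].append(t)
    return {k: sorted(v) for k, v in adj.items()}


def generate_disease(
    network: MultiscaleNetwork,
    scenario: SyntheticScenario,
    rng=None,
    oversample: float = 1.5,
) -> DiseaseProteinSet:
    """Sample a network-localized disease cluster.

    A random seed protein's BFS ball is grown to ~oversample times the
    requested size, then thinned uniformly back down (the seed protein is
    always kept).  Localization is what makes diffusion-profile
    correlation informative.
    """
    rng = rng if rng is not None else scenario.rng()
    n = scenario.n_disease_proteins
    adj = _pp_adjacency(network)
    proteins = sorted(adj)
    if n > len(proteins):
        raise ParameterError("n_disease_proteins exceeds available proteins")
    seed_node = proteins[int(rng.integers(len(proteins)))]
    ball = [seed_node]
    seen = {seed_node}
    frontier = [seed_node]
    want = max(n, int(np.ceil(oversample * n)))
    while frontier and len(ball) < want:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    ball.append(v)
                    nxt.append(v)
                    if len(ball) >= want:
                        break
            if len(ball) >= want:
                break
        frontier = nxt
    if len(ball) < n:  # tiny component fallback: pad with random proteins
        rest = [p for p in proteins if p not in seen]
        pad = rng.choice(len(rest), size=n - len(ball), replace=False)
        ball.extend(rest[int(i)] for i in pad)
    chosen = {seed_node}
    rest = ball[1:]
    if n > 1:
        pick = rng.choice(len(rest), size=n - 1, replace=False)
        chosen.update(rest[int(i)] for i in pick)
    return DiseaseProteinSet(
        ids=chosen, label="synthetic-disease", co_occurrence_threshold=1.0
    )


def generate_compound_library(
    network: MultiscaleNetwork,
    scenario: SyntheticScenario,
    disease: DiseaseProteinSet,
    rng=None,
) -> CompoundTargetTable:
    """Compound target sets with planted disease-proximal compounds.

    Planted compounds draw ``planted_overlap_fraction`` of their targets
    from the disease set and its one-hop protein neighbors; decoys draw
    from outside that pool where possible.
    """
    rng = rng if rng is not None else scenario.rng()
    proteins = sorted(network.proteins)
    if not disease.ids <= set(proteins):
        raise GenerationError("disease proteins must be network protein nodes")
    adj = _pp_adjacency(network)
    pool = set(disease.ids)
    for d in disease.ids:
        pool.update(adj[d])
    pool_sorted = sorted(pool)
    outside_sorted = sorted(set(proteins) - pool)
    if not pool_sorted:
        raise GenerationError("planted target pool is empty")

    neighbors_sorted = sorted(pool - disease.ids)
    disease_sorted = sorted(disease.ids)

    def _fill(targets: set[str], size: int, tiers) -> None:
        """Fill up to ``size`` targets, exhausting each tier before the next."""
        for tier in tiers:
            if len(targets) >= size:
                return
            avail = [p for p in tier if p not in targets]
            take = min(size - len(targets), len(avail))
            if take:
                pick = rng.choice(len(avail), size=take, replace=False)
                targets.update(avail[int(j)] for j in pick)

    lo, hi = scenario.targets_per_compound
    width = max(2, len(str(scenario.n_compounds)))
    records: list[tuple[str, str, str]] = []
    for i in range(scenario.n_compounds):
        cid = f"C{i + 1:0{width}d}"
        name = f"compound-{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        targets: set[str] = set()
        if cid in scenario.planted_compounds:
            n_in = min(round(scenario.planted_overlap_fraction * size), len(pool_sorted))
            _fill(targets, n_in, [pool_sorted])
            _fill(targets, size, [outside_sorted, pool_sorted])
        else:
            # decoys avoid the disease neighborhood where possible, and avoid
            # the disease set itself as long as any other protein remains
            _fill(targets, size, [outside_sorted, neighbors_sorted, disease_sorted])
        records.extend((cid, name, tid) for tid in sorted(targets))
    return CompoundTargetTable(records=records, provenance="synthetic")


def generate_pathway_library(
    network: MultiscaleNetwork,
    scenario: SyntheticScenario,
    disease: DiseaseProteinSet | None = None,
    rng=None,
) -> GeneSetLibrary:
    """Random protein sets in the requested size range.

    When a disease set is supplied, the first pathway draws half its
    members from the disease cluster so at least one set is genuinely
    disease-enriched.
    """
    rng = rng if rng is not None else scenario.rng()
    proteins = sorted(network.proteins)
    lo, hi = scenario.pathway_size_range
    width = max(2, len(str(scenario.n_pathways)))
    sets: dict[str, set[str]] = {}
    disease_sorted = sorted(disease.ids) if disease is not None else []
    for i in range(scenario.n_pathways):
        name = f"PW{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        members: set[str] = set()
        if i == 0 and disease_sorted:
            n_dis = min(size // 2 + size % 2, len(disease_sorted))
            pick = rng.choice(len(disease_sorted), size=n_dis, replace=False)
            members.update(disease_sorted[int(j)] for j in pick)
        remaining = [p for p in proteins if p not in members]
        pick = rng.choice(len(remaining), size=size - len(members), replace=False)
        members.update(remaining[int(j)] for j in pick)
        sets[name] = members
    return GeneSetLibrary(sets=sets, source="synthetic")


def generate_bundle(scenario: SyntheticScenario) -> ScenarioBundle:
    """Generate every input of a scenario from one seeded generator."""
    rng = scenario.rng()
    network = generate_multiscale_network(scenario, rng=rng)
    disease = generate_disease(network, scenario, rng=rng)
    compounds = generate_compound_library(network, scenario, disease, rng=rng)
    pathways = generate_pathway_library(network, scenario, disease=disease, rng=rng)
    truth = {
        "planted": sorted(set(scenario.planted_compounds) & set(compounds.compounds)),
        "decoys": sorted(set(compounds.compounds) - set(scenario.planted_compounds)),
        "planted_overlap_fraction": scenario.planted_overlap_fraction,
    }
    return ScenarioBundle(
        network=network,
        compounds=compounds,
        disease=disease,
        pathways=pathways,
        truth=truth,
        scenario=scenario,
    )


FIXTURE_FILES = {
    "network": "network.tsv",
    "compounds": "compounds.tsv",
    "disease": "disease.txt",
    "pathways": "pathways.gmt",
    "truth": "truth.json",
}


def write_fixture(bundle: ScenarioBundle, directory) -> dict:
    """Write all bundle inputs to ``directory`` and return a manifest.

    Files round-trip bit-identically through the package loaders; the
    manifest records paths, counts and the expanded edge-class census.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {key: directory / fname for key, fname in FIXTURE_FILES.items()}
        write_network_tsv(bundle.network, paths["network"])
        write_compound_targets(bundle.compounds, paths["compounds"])
        write_disease_proteins(bundle.disease, paths["disease"])
        write_gmt(bundle.pathways, paths["pathways"])
        with open(paths["truth"], "w") as fh:
            json.dump(bundle.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write fixture under {directory}: {exc}") from exc
    manifest = {
        "scenario": asdict(bundle.scenario),
        "files": {k: str(v) for k, v in paths.items()},
        "n_nodes": bundle.network.n_nodes,
        "n_proteins": len(bundle.network.proteins),
        "n_functions": len(bundle.network.functions),
        "edge_class_counts": bundle.network.edge_class_counts(),
        "n_cpis": len(bundle.compounds.records),
        "n_compounds": len(bundle.compounds.compounds),
        "n_disease_proteins": len(bundle.disease.ids),
        "n_pathways": len(bundle.pathways.sets),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_fixture(directory) -> ScenarioBundle:
    """Reload a written fixture through the standard loaders."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    scenario_kwargs = dict(manifest["scenario"])
    for key in ("targets_per_compound", "pathway_size_range", "planted_compounds"):
        scenario_kwargs[key] = tuple(scenario_kwargs[key])
    scenario = SyntheticScenario(**scenario_kwargs)
    network = load_multiscale_network(directory / FIXTURE_FILES["network"])
    compounds = load_compound_targets(directory / FIXTURE_FILES["compounds"])
    disease = load_disease_proteins(directory / FIXTURE_FILES["disease"])
    disease.label = "synthetic-disease"
    pathways = read_gmt(directory / FIXTURE_FILES["pathways"], source="synthetic")
    with open(directory / FIXTURE_FILES["truth"]) as fh:
        truth = json.load(fh)
    return ScenarioBundle(
        network=network,
        compounds=compounds,
        disease=disease,
        pathways=pathways,
        truth=truth,
        scenario=scenario,
    )
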