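"""Diffusion profiles on a multiscale protein/biological-function network.

The multiscale network mixes three kinds of biology in one directed graph:
physical protein-protein interactions, protein-to-function annotations, and
a hierarchy among biological functions.  A compound (anchored on its protein
targets) or a disease (anchored on its associated proteins) is propagated
over this graph by a random walk with restart: at each step the walker
either continues along an out-edge (probability ``c``) or teleports back to
the entity's restart distribution (probability ``1 - c``).  Out-edge choice
is biased by per-edge-class scalar weights, so e.g. annotation edges can be
made more or less attractive than physical interactions.

The stationary visit-frequency vector of this walk is the entity's
*diffusion profile*; Pearson correlation between a compound profile and the
disease profile scores how similarly the two entities perturb the network,
and is the compound-prioritization statistic.

The fixed point solves ``r = (1 - c) * s + c * W^T r`` where ``W`` is the
row-stochastic biased transition matrix and ``s`` the restart vector.  Both
a power iteration (the production path) and a direct sparse/dense linear
solve (the verification oracle) are provided, plus an explicit step-by-step
walker simulation for Monte Carlo cross-checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import NumericalError, ParameterError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

PROTEIN = "protein"
FUNCTION = "function"

#: directed edge classes after expansion
EXPANDED_EDGE_CLASSES = ("pp", "pf", "fp", "ff_up", "ff_down")
#: edge classes accepted in network TSV files (pre-expansion)
RAW_EDGE_CLASSES = ("pp", "pf", "ff")

_CLASS_ENDPOINTS = {
    "pp": (PROTEIN, PROTEIN),
    "pf": (PROTEIN, FUNCTION),
    "fp": (FUNCTION, PROTEIN),
    "ff_up": (FUNCTION, FUNCTION),
    "ff_down": (FUNCTION, FUNCTION),
}


@dataclass
class MultiscaleNetwork:
    """Directed graph over protein and biological-function nodes.

    ``edges`` holds the fully expanded directed edge list; ``raw_edges``
    (when the network came from a file or the generator) holds the compact
    one-row-per-undirected-link form used for serialization, with classes
    ``pp`` (undirected), ``pf`` (protein -> function) and ``ff``
    (child function -> parent function).
    """

    node_class: dict[str, str]
    edges: list[tuple[str, str, str]]
    raw_edges: list[tuple[str, str, str]] | None = None

    def __post_init__(self) -> None:
        offenders = []
        for s, t, ec in self.edges:
            if ec not in _CLASS_ENDPOINTS:
                offenders.append((s, t, ec, "unknown edge class"))
                continue
            if s == t:
                offenders.append((s, t, ec, "self-loop"))
                continue
            if s not in self.node_class or t not in self.node_class:
                offenders.append((s, t, ec, "endpoint not a node"))
                continue
            want = _CLASS_ENDPOINTS[ec]
            got = (self.node_class[s], self.node_class[t])
            if want != got:
                offenders.append((s, t, ec, f"endpoints {got} incompatible"))
        if offenders:
            shown = "; ".join(f"{s}->{t} [{ec}]: {why}" for s, t, ec, why in offenders[:10])
            raise ValidationError(
                f"{len(offenders)} invalid edge(s): {shown}"
            )
        self.node_order: tuple[str, ...] = tuple(sorted(self.node_class))
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.node_order)}

    # -- convenience -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_class)

    @property
    def proteins(self) -> list[str]:
        return [n for n in self.node_order if self.node_class[n] == PROTEIN]

    @property
    def functions(self) -> list[str]:
        return [n for n in self.node_order if self.node_class[n] == FUNCTION]

    def edge_class_counts(self) -> dict[str, int]:
        counts = {ec: 0 for ec in EXPANDED_EDGE_CLASSES}
        for _, _, ec in self.edges:
            counts[ec] += 1
        return counts

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for n, cls in self.node_class.items():
            g.add_node(n, node_class=cls)
        for s, t, ec in self.edges:
            g.add_edge(s, t, edge_class=ec)
        return g

    @classmethod
    def from_raw(
        cls,
        raw_edges: list[tuple[str, str, str]],
        node_class: dict[str, str] | None = None,
    ) -> "MultiscaleNetwork":
        """Build a network from compact rows, expanding reciprocal edges.

        ``pp`` rows become two directed pp edges; ``pf`` rows become a pf
        edge plus its fp reverse; ``ff`` rows (child -> parent) become an
        ff_up edge plus its ff_down reverse.  Node classes are inferred
        from edge classes when not supplied; inconsistencies raise.
        """
        inferred: dict[str, str] = dict(node_class or {})
        conflicts = []

        def _claim(node: str, cls: str, row) -> None:
            prev = inferred.setdefault(node, cls)
            if prev != cls:
                conflicts.append((node, prev, cls, row))

        for row in raw_edges:
            s, t, ec = row
            if ec == "pp":
                _claim(s, PROTEIN, row)
                _claim(t, PROTEIN, row)
            elif ec == "pf":
                _claim(s, PROTEIN, row)
                _claim(t, FUNCTION, row)
            elif ec == "ff":
                _claim(s, FUNCTION, row)
                _claim(t, FUNCTION, row)
            else:
                raise SchemaError(
                    f"unknown edge_class {ec!r} in row {row}; expected one of {RAW_EDGE_CLASSES}"
                )
        if conflicts:
            shown = "; ".join(
                f"{n}: {a} vs {b} (row {r})" for n, a, b, r in conflicts[:10]
            )
            raise ValidationError(f"node class conflicts: {shown}")

        expanded: set[tuple[str, str, str]] = set()
        for s, t, ec in raw_edges:
            if s == t:
                raise ValidationError(f"self-loop {s}->{t} [{ec}]")
            if ec == "pp":
                expanded.add((s, t, "pp"))
                expanded.add((t, s, "pp"))
            elif ec == "pf":
                expanded.add((s, t, "pf"))
                expanded.add((t, s, "fp"))
            else:  # ff, stored child -> parent
                expanded.add((s, t, "ff_up"))
                expanded.add((t, s, "ff_down"))
        return cls(
            node_class=inferred,
            edges=sorted(expanded),
            raw_edges=sorted(set(raw_edges)),
        )


def load_multiscale_network(path) -> MultiscaleNetwork:
    """Read a network TSV with columns source, target, edge_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["source", "target", "edge_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"network file {path} missing column(s): {', '.join(missing)}")
    bad = sorted(set(df["edge_class"]) - set(RAW_EDGE_CLASSES))
    if bad:
        raise SchemaError(
            f"network file {path} has unknown edge_class values {bad}; "
            f"expected {RAW_EDGE_CLASSES}"
        )
    rows = [tuple(r) for r in df[required].itertuples(index=False, name=None)]
    return MultiscaleNetwork.from_raw(rows)


def write_network_tsv(network: MultiscaleNetwork, path) -> None:
    """Write the compact (unexpanded) edge list, canonically sorted."""
    if network.raw_edges is None:
        raise ValidationError("network has no compact edge representation to write")
    with open(path, "w") as fh:
        fh.write("source\ttarget\tedge_class\n")
        for s, t, ec in sorted(network.raw_edges):
            fh.write(f"{s}\t{t}\t{ec}\n")


# ---------------------------------------------------------------------------
# configuration, restart vectors
# ---------------------------------------------------------------------------


def default_edge_class_weights() -> dict[str, float]:
    """Unbiased walk: all five edge classes equally likely per edge."""
    return {ec: 1.0 for ec in EXPANDED_EDGE_CLASSES}


@dataclass
class DiffusionConfig:
    """Random walk with restart settings.

    continue_prob
        Probability ``c`` that the walker follows an out-edge instead of
        restarting.  Default 0.85, a standard choice for personalized
        network propagation.
    edge_class_weights
        Positive scalar per directed edge class; step probability along an
        edge is its class weight normalized over the source node's
        out-edges.
    tolerance
        L1 convergence bound on the iterate change.
    k
        Top-k size used downstream for mechanism subgraphs (default 20).
    """

    continue_prob: float = 0.85
    edge_class_weights: dict[str, float] = field(default_factory=default_edge_class_weights)
    tolerance: float = 1e-6
    max_iterations: int = 1000
    k: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.continue_prob < 1.0):
            raise ParameterError(f"continue_prob must be in [0, 1), got {self.continue_prob}")
        for ec, w in self.edge_class_weights.items():
            if ec not in EXPANDED_EDGE_CLASSES:
                raise ParameterError(f"unknown edge class in weights: {ec!r}")
            if not w > 0:
                raise ParameterError(f"edge class weight must be positive: {ec}={w}")
        if not self.tolerance > 0:
            raise ParameterError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.k < 1:
            raise ParameterError("k must be >= 1")


@dataclass
class RestartVector:
    """Teleport distribution of one entity over network nodes."""

    entries: dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        total = sum(self.entries.values())
        if not self.entries or abs(total - 1.0) > 1e-9 or min(self.entries.values()) < 0:
            raise ValidationError(
                f"restart vector {self.label!r} must be a probability distribution "
                f"(sum={total:.6g})"
            )


def build_restart_vector(
    network: MultiscaleNetwork, ids, label: str = ""
) -> RestartVector:
    """Uniform restart mass over the given ids that exist in the network."""
    ids = set(ids)
    if not ids:
        raise ValidationError(f"entity {label!r}: empty id set")
    mapped = sorted(ids & set(network.node_class))
    unmapped = sorted(ids - set(network.node_class))
    if unmapped:
        logger.warning(
            "entity %r: %d id(s) not in network dropped from restart vector: %s",
            label, len(unmapped), ", ".join(unmapped[:8]),
        )
    if not mapped:
        raise ValidationError(f"entity {label!r} has no network anchor")
    p = 1.0 / len(mapped)
    return RestartVector(entries={n: p for n in mapped}, label=label)


# ---------------------------------------------------------------------------
# transition matrix and profiles
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrix:
    """Row-stochastic biased step matrix plus dangling-node bookkeeping."""

    matrix: sp.csr_matrix
    dangling: np.ndarray  # boolean mask over node_order
    node_order: tuple[str, ...]


def build_transition_matrix(
    network: MultiscaleNetwork, weights: dict[str, float] | None = None
) -> TransitionMatrix:
    """Edge u->v gets probability weight(class) / sum of weights over u's out-edges."""
    if weights is None:
        weights = default_edge_class_weights()
    present = {ec for _, _, ec in network.edges}
    missing = sorted(present - set(weights))
    if missing:
        raise ParameterError(f"edge_class_weights missing class(es): {missing}")
    for ec, w in weights.items():
        if not w > 0:
            raise ParameterError(f"edge class weight must be positive: {ec}={w}")

    n = network.n_nodes
    idx = network.index
    rows = np.fromiter((idx[s] for s, _, _ in network.edges), dtype=np.int64, count=len(network.edges))
    cols = np.fromiter((idx[t] for _, t, _ in network.edges), dtype=np.int64, count=len(network.edges))
    data = np.fromiter((weights[ec] for _, _, ec in network.edges), dtype=float, count=len(network.edges))
    w = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    out_mass = np.asarray(w.sum(axis=1)).ravel()
    dangling = out_mass == 0
    if dangling.any():
        logger.warning("%d dangling node(s) flagged (no out-edges)", int(dangling.sum()))
    inv = np.ones_like(out_mass)
    inv[~dangling] = 1.0 / out_mass[~dangling]
    w = sp.diags(inv) @ w
    return TransitionMatrix(matrix=w.tocsr(), dangling=dangling, node_order=network.node_order)


@dataclass
class DiffusionProfile:
    """Stationary visit-frequency vector of one entity's restarting walk."""

    nodes: tuple[str, ...]
    frequencies: np.ndarray
    entity: str = ""
    iterations_used: int = 0
    converged: bool = True
    delta_trace: list[float] = field(default_factory=list)

    @property
    def visit_frequency(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.frequencies.tolist()))

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies, index=list(self.nodes), name=self.entity)


def _restart_array(restart: RestartVector, node_order, index) -> np.ndarray:
    s = np.zeros(len(node_order))
    for node, p in restart.entries.items():
        if node not in index:
            raise ValidationError(f"restart node {node!r} not in network")
        s[index[node]] = p
    return s


def compute_diffusion_profile(
    network: MultiscaleNetwork,
    restart: RestartVector,
    config: DiffusionConfig | None = None,
    transition: TransitionMatrix | None = None,
) -> DiffusionProfile:
    """Power iteration of r <- (1-c) s + c W^T r starting from r0 = s.

    Mass sitting on dangling nodes is teleported back to the restart
    vector each step, preserving stochasticity.
    """
    config = config or DiffusionConfig()
    if transition is None:
        transition = build_transition_matrix(network, config.edge_class_weights)
    c = config.continue_prob
    s = _restart_array(restart, network.node_order, network.index)
    wt = transition.matrix.T.tocsr()
    dangling = transition.dangling

    r = s.copy()
    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        stepped = wt @ r
        if dangling.any():
            stepped = stepped + r[dangling].sum() * s
        r_new = (1.0 - c) * s + c * stepped
        delta = float(np.abs(r_new - r).sum())
        trace.append(delta)
        r = r_new
        if delta < config.tolerance:
            converged = True
            break
    if not converged:
        logger.warning(
            "power iteration for %r did not converge in %d iterations (last delta %.3g)",
            restart.label, config.max_iterations, trace[-1] if trace else float("nan"),
        )
    return DiffusionProfile(
        nodes=network.node_order,
        frequencies=r,
        entity=restart.label,
        iterations_used=iterations,
        converged=converged,
        delta_trace=trace,
    )


def solve_stationary_exact(
    network: MultiscaleNetwork,
    restart: RestartVector,
    config: DiffusionConfig | None = None,
    transition: TransitionMatrix | None = None,
) -> DiffusionProfile:
    """Direct linear solve of (I - c W_eff^T) r = (1-c) s.

    ``W_eff`` replaces dangling rows with the restart vector, matching the
    teleport convention of the power iteration.  Serves as the correctness
    oracle for :func:`compute_diffusion_profile` on networks of up to 2000
    nodes.
    """
    config = config or DiffusionConfig()
    if network.n_nodes > 2000:
        raise ParameterError("exact solve limited to networks of <= 2000 nodes")
    if transition is None:
        transition = build_transition_matrix(network, config.edge_class_weights)
    c = config.continue_prob
    s = _restart_array(restart, network.node_order, network.index)
    w = transition.matrix.toarray()
    if transition.dangling.any():
        w[transition.dangling, :] = s
    n = network.n_nodes
    a = np.eye(n) - c * w.T
    try:
        r = np.linalg.solve(a, (1.0 - c) * s)
    except np.linalg.LinAlgError as exc:  # c -> 1 pathologies
        raise NumericalError(f"stationary system is singular: {exc}") from exc
    return DiffusionProfile(
        nodes=network.node_order,
        frequencies=r,
        entity=restart.label,
        iterations_used=0,
        converged=True,
    )


def simulate_restarting_walk(
    network: MultiscaleNetwork,
    restart: RestartVector,
    config: DiffusionConfig | None = None,
    n_steps: int = 100_000,
    rng: np.random.Generator | None = None,
    transition: TransitionMatrix | None = None,
) -> np.ndarray:
    """Empirical visit frequencies of an explicitly simulated walker.

    The chain is the one whose stationary law the diffusion profile solves:
    with probability 1-c (or from a dangling node) the walker teleports to
    a restart-vector draw, otherwise it follows a weight-biased out-edge.
    Returns visit counts / n_steps aligned to ``network.node_order``.
    """
    config = config or DiffusionConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    if transition is None:
        transition = build_transition_matrix(network, config.edge_class_weights)
    c = config.continue_prob
    n = network.n_nodes
    w = transition.matrix
    # per-node cumulative out-neighbor tables for O(log deg) stepping
    indptr, indices, data = w.indptr, w.indices, w.data
    cum: list[np.ndarray] = []
    nbr: list[np.ndarray] = []
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        nbr.append(indices[lo:hi])
        cum.append(np.cumsum(data[lo:hi]))
    s = _restart_array(restart, network.node_order, network.index)
    s_cum = np.cumsum(s)
    dangling = transition.dangling

    counts = np.zeros(n, dtype=np.int64)
    u = rng.random(n_steps)  # restart-vs-step coin
    v = rng.random(n_steps)  # which edge / which restart node
    state = int(np.searchsorted(s_cum, rng.random()))
    for t in range(n_steps):
        if u[t] >= c or dangling[state]:
            state = int(np.searchsorted(s_cum, v[t] * s_cum[-1]))
        else:
            ci = cum[state]
            j = int(np.searchsorted(ci, v[t] * ci[-1]))
            state = int(nbr[state][j])
        counts[state] += 1
    return counts / n_steps


# ---------------------------------------------------------------------------
# profile comparison and compound ranking
# ---------------------------------------------------------------------------


def correlate_profiles(a: DiffusionProfile, b: DiffusionProfile) -> float:
    """Pearson correlation over the full, aligned node vectors."""
    if a.nodes != b.nodes:
        if set(a.nodes) != set(b.nodes):
            raise ValidationError("profiles live on different node universes")
        order = {n: i for i, n in enumerate(b.nodes)}
        bv = b.frequencies[[order[n] for n in a.nodes]]
    else:
        bv = b.frequencies
    av = a.frequencies
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        flat = a.entity if np.ptp(av) == 0 else b.entity
        raise ValidationError(
            f"profile {flat!r} has zero variance; correlation undefined"
        )
    return float(np.corrcoef(av, bv)[0, 1])


def rank_compounds(
    profiles: dict[str, DiffusionProfile],
    disease_profile: DiffusionProfile,
    overlaps: dict | None = None,
) -> pd.DataFrame:
    """Rank compounds by diffusion-profile correlation with the disease.

    Returns a table sorted by correlation (descending, ties broken by
    compound id) with one row per compound; when ``overlaps`` maps
    compound id -> EnrichmentResult, the overlap counts and p-value are
    included to mirror the published prioritization-table shape.
    """
    if not profiles:
        raise ValidationError("no compound profiles to rank")
    rows = []
    for cid in sorted(profiles):
        row = {
            "compound": cid,
            "correlation": correlate_profiles(profiles[cid], disease_profile),
        }
        if overlaps is not None and cid in overlaps:
            res = overlaps[cid]
            row["overlap_k"] = res.overlap_k
            row["overlap_n"] = res.query_n
            row["overlap_p"] = res.p_value
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["correlation", "compound"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def write_profile_tsv(profile: DiffusionProfile, network: MultiscaleNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tnode_class\tvisit_frequency\n")
        for node, freq in zip(profile.nodes, profile.frequencies):
            fh.write(f"{node}\t{network.node_class[node]}\t{freq:.12g}\n")
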