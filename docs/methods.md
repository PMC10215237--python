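# Methods

## The model

A *multiscale network* is a directed graph over two node classes, proteins
and biological functions, with five directed edge classes: `pp`
(protein–protein, stored as reciprocal directed pairs), `pf` / `fp`
(protein→function annotation and its reverse), and `ff_up` / `ff_down`
(child→parent function hierarchy and its reverse).  Serialized networks
store one compact row per link (`pp`, `pf`, `ff`); the loader expands the
reciprocal directions and infers node classes from edge classes, rejecting
inconsistencies.

An entity (a compound with target proteins, or a disease with associated
proteins) is represented by its *diffusion profile*: the stationary
visit-frequency vector `r` of a random walk with restart,

    r = (1 − c) s + c Wᵀ r

* `s` — restart vector: uniform over the entity's anchor nodes present in
  the network.  Compounds anchor on their target proteins; the disease
  anchors on its protein set only, not on function nodes (functions enter
  profiles through propagation, not through anchoring).
* `c` — continue probability, default **0.85** (the standard personalized
  network-propagation value); restart probability is 1 − c.
* `W` — row-stochastic transition matrix.  The step probability along an
  edge is its class weight divided by the summed weights of the source
  node's out-edges.  Default weights are **1.0 for all five classes** (the
  unbiased walk); optimized class weights are dataset-specific and are left
  to the user.
* Dangling nodes (no out-edges) teleport to the restart vector, which
  preserves stochasticity; profiles therefore always sum to 1.

The fixed point is computed by power iteration from `r₀ = s` until the L1
change falls below a tolerance (default **1e-6**, max 1000 iterations; the
iteration contracts with ratio ≤ c, so convergence takes roughly
log(tol)/log(c) steps).  Two independent routes verify it: a direct linear
solve of `(I − c Wᵀ_eff) r = (1 − c) s` (with dangling rows replaced by
`s`), used as the oracle on networks of up to 2000 nodes, and an explicit
step-by-step walker simulation whose empirical visit frequencies are
compared using block standard errors (visits are autocorrelated within
restart segments, so naïve binomial SEs would be too small).

Compounds are ranked by the Pearson correlation between their full
diffusion profile and the disease profile, over all nodes in a fixed
lexicographic order.  Full vectors, not top-k truncations, are used: the
correlation statistic is defined on profiles, and truncation would make it
depend on k.  A profile with zero variance (only possible in degenerate
graphs) makes the correlation undefined and is reported as an error rather
than silently coerced.

## Overlap and enrichment statistics

`hypergeom_overlap_test` computes the exact upper tail P(X ≥ k) with
N = |background|, K = |reference ∩ background|, n = |query|,
k = |overlap|, via the exact hypergeometric tail sum (no normal
approximation).  Query ids outside the background are dropped with a
warning (or rejected in strict mode).  The z-score is the overlap
standardized under the same hypergeometric null, z = (k − nK/N)/σ, and the
combined score is −ln(p)·z, signed so that enriched sets score positive.
This z differs from Enrichr's rank-based z, which depends on internal
backgrounds that cannot be reproduced locally; the divergence is
intentional and documented here.

`monte_carlo_fold_enrichment` mirrors the randomization procedure used in
network pharmacology studies literally: it repeatedly draws |query| ids
uniformly without replacement from the background, counts overlaps with
the reference, and reports fold = observed / mean(random) and
empirical p = (1 + #{random ≥ observed}) / (n_iter + 1).  The add-one
correction avoids zero p-values; the closed-form mean nK/N serves as an
independent oracle for the null mean.  If the mean random overlap is zero
the fold is reported as infinite with an explicit flag.

Pathway over-representation runs one hypergeometric test per GMT set and
adjusts p-values with Benjamini–Hochberg (default) or Bonferroni via
statsmodels; results sort by adjusted p, ties by name.  The default
background for compound–disease overlap is the union of all target
proteins in the loaded CPI table (plus the disease ids, so the reference
lives in the universe), switchable to the multiscale network's protein
set — overlap p-values are only comparable within one background choice.

## Key-target filter and mechanism subgraphs

`filter_key_targets` keeps CPI records whose target protein is hit by at
least `min_ingredients` (default 2) distinct compounds.  Compounds left
without any surviving target drop out of the roster, so the compound count
can shrink alongside the target count; the filter is idempotent and its
output CPI count is non-increasing in the threshold.

A mechanism subgraph for a compound–disease pair is induced by the top-k
nodes of each diffusion profile (default **k = 20**, ties broken
lexicographically) together with the compound-target and disease-protein
anchors.  Nodes on the compound side (anchor or top-k of the compound
profile) with no path to any disease-side node inside the subgraph are
removed, and symmetrically; removal iterates to a fixed point because
pruning can disconnect further nodes.  Connectivity is evaluated ignoring
edge direction: reciprocal storage makes direction irrelevant for `pp` and
`pf`/`fp`, and hierarchy edges should not block mechanism paths.  k is
read as *per profile*, so the subgraph has at most 2k + |anchors| nodes.
An empty result after pruning signals that no mechanism link exists and is
returned (with a warning) rather than raised.

## Synthetic scenarios

The generator produces complete miniature studies from a single integer
seed (one numpy Generator threads through all stages, so bundles reproduce
byte-identically):

* **Protein layer** — preferential-attachment graph with an exact
  requested edge count.  Interactomes are heavy-tailed, and hubs stress
  the walker more than an Erdős–Rényi graph would.  Default: 200 proteins,
  600 interactions (mean degree 6).
* **Function layer** — random tree built with Poisson(branching)
  capacities (default mean 2 children), optionally densified with extra
  child→earlier-node edges to reach a requested hierarchy edge count
  (`ff_edges`); the extra edges keep the hierarchy acyclic.  Default: 50
  functions.
* **Annotations** — exactly `round(annotation_rate × n_proteins)` distinct
  protein–function pairs (default rate 2.0).
* **Disease** — a BFS ball around a random seed protein, oversampled ~1.5×
  and thinned uniformly back to size.  Localization matters: diffusion
  profiles only discriminate when the disease occupies a coherent network
  neighborhood.  Default 20 proteins (10% of the default proteome; a
  realistic disease module is a small minority of the network, and a much
  larger set would leave no room for decoy compounds to avoid it).
* **Compounds** — 14 compounds with target-set sizes uniform in [7, 64],
  the range seen in assembled herbal-ingredient target sets.  One planted
  compound draws `planted_overlap_fraction` (default 1.0) of its targets
  from the disease set and its one-hop interactors; decoys draw from
  outside that pool, falling back first to non-disease neighbors and only
  then to disease proteins if the proteome runs out.
* **Pathways** — 9 random protein sets of 10–35 members; the first is
  seeded with disease proteins so at least one set is genuinely
  disease-enriched.

What the generator does **not** emulate: realistic degree correlations,
annotation semantics (functions are random, not ontology terms), compound
chemistry, or database noise (synonymous identifiers, species mixing).
Passing tests therefore demonstrate statistical and algorithmic
correctness — exact p-values, solver agreement, recovery of a planted
signal under the stated geometry — not performance on any real interactome.

## Numerical and design choices

* Node order for all vector algebra is lexicographic over ids, fixed at
  load time; all serializations sort canonically, making outputs
  byte-reproducible.
* Ranking ties (equal correlations, equal visit frequencies) break by id.
* Identifier matching is exact, case-sensitive string equality; mapping
  between identifier namespaces is a user responsibility upstream.
* Duplicate CPI rows collapse to one record with a logged count.
* p-value validation for the multiplicity procedures requires p ∈ (0, 1];
  an exact-zero tail (possible only through floating-point underflow) is
  floored at 1e-320.
* Exit codes of the CLI: 0 success, 2 validation/parameter/schema error,
  3 runtime error.

## Verification problem sizes

The test suite and `scripts/acceptance.py` run entirely on generated data:
oracle-equivalence checks use 20 networks of 38–250 nodes; the walker
cross-check uses 10⁶ steps in 50 blocks on a 48-node fixture;
hypergeometric exactness enumerates all universes N ≤ 12 (1819 cases);
null calibration uses 200 null runs of 200 draws plus one 10⁴-draw run;
planted-compound recovery runs the full scenario across 20 seeds.  These
sizes give each property enough resolution to fail visibly while keeping
the whole verification run in the order of seconds.

## Known limitations

* Edge-class weights default to the unbiased walk; no weight optimization
  is provided.
* The hypergeometric background must be chosen by the user; published
  overlap p-values are generally not reproducible without knowing the
  original background universe.
* The exact solver is quadratic in memory (dense) and capped at 2000
  nodes; it is a verification tool, not a production path.
* Mechanism subgraphs annotate pathway membership only through a
  user-supplied GMT; no automatic biological narrative is attempted.
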