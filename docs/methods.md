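# Methods

## Model

A probabilistic signaling network is a directed graph `G = (V, E, P)` with
independent per-edge existence probabilities `P : E → [0, 1]`, a source set
`S ⊆ V` (receptors) and a target set `T ⊆ V` (reporters). A *deterministic
instance* fixes the subset of present edges; its probability is the product
of present-edge probabilities and absent-edge complements, and the
`2^|E|` instance probabilities sum to 1. `P_reach(G, S, T)` is the total
mass of instances containing a directed path from some `s ∈ S` to some
`t ∈ T`; a node in `S ∩ T` counts as a zero-length path, so self-
reachability is 1 by convention throughout (including matrix diagonals).

Edges are strictly directed (signal flow); parallel duplicate edges and
self-loops are rejected at construction — the polynomial associates exactly
one binomial with each edge, and self-loops can affect no `S→T` path.
Undirected interaction data must be pre-expanded to edge pairs by the user.
Raw interaction confidences on the `[1, 1000]` database scale are mapped to
probabilities by division by 1000.

## Exact reachability computation

The engine maintains an xy-polynomial over the processed edge set Θ:
non-free terms `(Sᵢ ⊆ Θ, aᵢ)` encode undecided present/absent combinations,
and the free coefficients `b` (`x*`) and `c` (`y*`) hold the decided
reachable and unreachable mass. Multiplying edge `e`'s binomial splits each
term into a present branch (`aᵢ·p`) and an absent branch (`aᵢ·(1−p)`);
after **every** multiplication, terms whose present set contains an `S→T`
path collapse into `b` and terms whose absent set is an `S→T` cut collapse
into `c`. Coefficients are only ever moved, never rescaled, so
`b + c + Σ aᵢ = 1` holds exactly (asserted within 1e-12 in debug mode);
after the final edge no undecided term can survive and the result is `b`.

Numerical and algorithmic choices:

* **Edge order** — breadth-first from the source set, ties broken by input
  edge index, unreachable edges appended last. The product commutes, so the
  order never changes the result (a tested property, ≤ 1e-12 across random
  permutations); BFS merely decides path/cut status early to maximize
  collapsing.
* **Relevance pruning** (on by default) — an edge `(u, v)` with `u` not
  reachable from `S` or `v` unable to reach `T` lies on no `S→T` path and
  is skipped. This changes neither path nor cut verdicts and is validated
  against unpruned computation.
* **Term cap** — the worst case is `O(2^|E|)` live terms; a configurable cap
  (default 2^22) raises a clear resource error instead of exhausting
  memory. Set-to-set queries over many sources and targets on dense layered
  networks are the typical way to hit it; per-pair and per-target queries
  prune far better and are what the downstream characterizations use.
* **Floating point** — coefficients are doubles, not rationals; reported
  probabilities carry the stated 1e-10/1e-12 tolerances. An optional
  epsilon-prune flag drops terms below a threshold for large inputs and is
  documented as approximate (off by default; exactness first).
* **Path/cut memoization** — verdicts are cached per present/absent set
  within one query; semantics unchanged.

The enumeration oracle (`reachability_bruteforce`, |E| ≤ 20) sums instance
probabilities over all `2^|E|` masks with its own BFS, independent of the
polynomial code path; it uses an iterated outer product for the mask
probabilities and the elementary fact that supersets of a path-containing
edge set contain a path. The two routes agree within 1e-10 on hundreds of
random networks (max observed deviation ~4e-15).

## Node centrality

`C_v(G,s,t) = P_reach(G,s,t) − P_reach(G∖v,s,t)` is the probability that
`v` is essential for `(s,t)`; removal never increases reachability, so
values in `[−1e-9, 0)` are clamped to 0 as floating-point noise and larger
negatives raise an internal-consistency error. The centrality
`E[X_v] = Σ C_v(G,s,t)` is the Poisson-binomial mean of the per-pair
essentiality indicators — computed as the plain sum, by linearity.

Pairs with `v ∈ {s, t}` are **excluded** by default: essentiality
formalizes relay importance, and counting terminals as essential for their
own pairs would trivially inflate every receptor/reporter score. A config
switch (`include_terminal_pairs`) includes them, contributing
`P_reach(G,s,t)` per such pair (removing a terminal disconnects the pair
with certainty whenever it was connected).

The deterministic companion is classical shortest-path betweenness on the
underlying directed topology with all edges certain and unweighted,
normalized by `(|V|−1)(|V|−2)`. Rank disagreement for node `x` counts the
nodes whose order relative to `x` differs between the probabilistic and
deterministic rankings, divided by `|V|`; rankings are descending by value
with identifier tie-breaks, and score-tied pairs count as agreeing.

## Stability

Perturbation response is the mean per-pair reachability change
`1/(|S||T|) Σ [P_reach(G^δ,s,t) − P_reach(G,s,t)]`, negative values
indicating loss of responsiveness. Probability perturbation redraws each
edge probability uniformly on the truncated window
`[max(0, p−δ), min(1, p+δ)]` — uniform on the intersection, not
draw-then-clamp, which would place point mass at 0 and 1. Consequently a
network with edge probabilities above `1−δ` drifts down in expectation
(e.g. `p = 1, δ = 0.2` gives `E[p'] = 0.9`), reproducing the qualitative
monotone decrease of reachability with perturbation strength.

Topology perturbation performs `round(δ·|E|/2)` swaps, each replacing two
random edges `(u₁,v₁), (u₂,v₂)` by `(u₁,v₂), (u₂,v₁)` with the two old
probabilities reassigned in random order; in-/out-degree sequences and the
probability multiset are invariant. Proposals creating a self-loop or
duplicate edge are rejected and resampled within a budget of 100 draws per
swap (the swap-pair convention and budget are configurable). Replicate
count defaults to 30 (reported in all outputs) and every replicate draws
from a sub-stream spawned from the single user seed, so curves reproduce
bit-identically.

## Functional characterization

Targets are ranked by `P_reach(G, S, {t})` descending, identifier ties
ascending. For a term with `N` annotated targets, every prefix length
`d ∈ {1..|T|}` yields a tail `P(X ≥ n | |T|, d, N)` with `n` annotated
targets among the top `d`; the tail is computed by direct summation of the
hypergeometric mass with exact integer binomials, and the minimum over `d`
(smallest `d` on ties) is the enrichment value. No multiple-testing
correction is applied — the 0.1 threshold is used raw. Term reachability is
`P_reach(G, S_a, T_a)` over the term's annotated sources and targets; terms
annotating no source or no target are *not applicable* (distinct from a
reachability of 0) and excluded from rankings.

Ontology depth is the shortest is-a/part-of chain from any root (depth 0);
the "top five levels" filter removes terms at depth ≤ 4, a configurable
boundary since level counting is convention-dependent. Terms without depth
information are kept with a logged warning — filtering is optional
preprocessing. Annotated genes absent from the network are ignored with a
warning at use time.

Matrix rows are clustered agglomeratively (scipy; average linkage on
Euclidean row distances, both configurable — correlation distance is a
plausible alternative and a config switch away) and emitted in dendrogram
leaf order for heat-map rendering; tie handling follows scipy's
deterministic implementation.

## Synthetic data

The generator emulates a three-layer pathway: sources → internal →
targets, each cross-layer edge drawn independently at density 0.5 with
probability sampled uniformly on [0.2, 0.8] — mid-range confidences typical
of score-derived edge probabilities. Defaults: 3 sources, 6 internal
nodes, 10 targets, a 20-term background pool with 1–4 terms per gene, and
one planted term annotating the 3 most reachable targets plus one source,
with incoming edges of the designated planted targets boosted by
`p → p + 0.9·(1−p)`. Every target is guaranteed topologically reachable
from at least one source (repair edges are added if a draw disconnects;
optionally disabled, in which case disconnected draws raise). A
`cycle_edges` option adds internal→internal edges since the reachability
math does not require acyclicity.

What the generator does *not* emulate: scale-free degree structure,
feedback loops onto receptors, correlated edge probabilities, and the
much larger size of curated pathways. Passing the planted-recovery test
therefore shows the enrichment machinery detects a reachability-aligned
annotation signal under idealized layered topologies, not that real
pathway annotations behave this way.

## Problem sizes and determinism

Validation suites use random digraphs with `|V| ≤ 10`, `|E| ≤ 14` for
enumeration cross-checks (200 networks), 100 seeded synthetic datasets for
planted-term recovery, and 30–200 replicates for perturbation statistics —
sizes at which the enumeration oracle is exact and the full analysis runs
in seconds on a laptop while exercising every code path. All stochastic
components take explicit seeds (numpy `SeedSequence` sub-streams), and the
command-line layer refuses silent nondeterminism: a missing seed is
generated, logged and recorded in the run manifest.

## Known limitations

* Exactness costs exponential worst-case time/space; very dense
  set-to-set queries can exceed the term cap. Monte-Carlo approximation is
  deliberately out of scope.
* Edge probabilities are treated as independent; correlated uncertainty
  (shared experimental provenance) is not modeled.
* Enrichment uses annotations as given — no propagation to ancestor terms
  through the ontology.
* The deterministic-betweenness comparison fixes one normalization and
  direction convention; other conventions would shift ranks, though the
  disagreement statistic is insensitive to monotone rescalings.
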