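"""Exact signal-reachability probability via a collapsible xy-polynomial.

The reachability probability ``P_reach(G, S, T)`` is the total probability
mass of the deterministic instances of ``G`` (subsets of edges assumed
present) that contain a directed path from some source in ``S`` to some
target in ``T``.  Enumerating all ``2**|E|`` instances is exponential; the
xy-polynomial algorithm instead multiplies one binomial ``p_i*x_i + q_i*y_i``
per edge into a growing polynomial and, after every multiplication,
*collapses* terms whose fate is already decided:

* a term whose present-edge set contains an S->T path is folded into the
  free coefficient ``b`` (reachable mass, the ``x*`` variable);
* a term whose absent-edge set is an S->T cut — even with every undecided
  edge present, T is unreachable — is folded into ``c`` (the ``y*``
  variable).

Total probability ``b + c + sum(a_i) == 1`` is conserved at every step, and
after the last edge every instance is decided, so ``b + c == 1`` and ``b``
is the reachability probability.  The worst case remains ``O(2**|E|)``, but
collapsing keeps the live term count small on sparse signaling topologies.
"""

from __future__ import annotations

import itertools
import random
from collections import deque
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .network_model import (
    ProbabilisticNetwork,
    ValidationError,
    ancestors,
    descendants,
)

#: Default cap on simultaneously live (undecided) polynomial terms.
DEFAULT_TERM_CAP = 2**22

#: Default |E| bound for the brute-force enumeration oracle.
DEFAULT_ENUM_BOUND = 20

CONSERVATION_TOL = 1e-12


class StateError(RuntimeError):
    """An operation was applied to a polynomial in an invalid state."""


class ResourceError(RuntimeError):
    """A configured resource bound (term cap, enumeration bound) was exceeded."""


@dataclass
class XYPolynomial:
    """The growing reachability polynomial.

    ``terms`` maps each undecided present-edge set ``S_i`` (a frozenset of
    edge indices, subset of ``processed``) to its coefficient ``a_i``; ``b``
    and ``c`` are the free coefficients of ``x*`` (decided reachable) and
    ``y*`` (decided unreachable).
    """

    processed: frozenset[int] = frozenset()
    terms: dict[frozenset[int], float] = field(
        default_factory=lambda: {frozenset(): 1.0}
    )
    b: float = 0.0
    c: float = 0.0

    @property
    def mass(self) -> float:
        return self.b + self.c + sum(self.terms.values())

    def check_conservation(self, tol: float = CONSERVATION_TOL) -> None:
        if abs(self.mass - 1.0) > tol:
            raise StateError(f"probability mass {self.mass!r} deviates from 1")
        if self.b < 0 or self.c < 0 or any(a < 0 for a in self.terms.values()):
            raise StateError("negative coefficient in xy-polynomial")
        for s in self.terms:
            if not s <= self.processed:
                raise StateError("term present-set outside processed edge set")


def initial_polynomial() -> XYPolynomial:
    """Empty product: one term (no edges decided) with coefficient 1."""
    return XYPolynomial()


def multiply_binomial(F: XYPolynomial, e: int, p: float) -> XYPolynomial:
    """Multiply the polynomial by the binomial ``p*x_e + (1-p)*y_e``.

    Each non-free term splits into a present branch (coefficient scaled by
    ``p``) and an absent branch (scaled by ``1-p``); exact-zero branches are
    dropped.  The free coefficients absorb both branches unchanged since
    ``b*p + b*(1-p) == b``.
    """
    if e in F.processed:
        raise StateError(f"edge {e} already processed")
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"probability {p!r} outside [0, 1]")
    q = 1.0 - p
    new_terms: dict[frozenset[int], float] = {}
    for s, a in F.terms.items():
        if p > 0.0:
            new_terms[s | {e}] = a * p
        if q > 0.0:
            new_terms[s] = a * q
    return XYPolynomial(
        processed=F.processed | {e}, terms=new_terms, b=F.b, c=F.c
    )


def has_path(
    net: ProbabilisticNetwork,
    present: Iterable[int],
    S: Iterable[str],
    T: Iterable[str],
) -> bool:
    """True iff the graph restricted to ``present`` edges has an S->T path.

    A node in both S and T counts as a zero-length path.
    """
    S, T = set(S), set(T)
    if S & T:
        return True
    reach = descendants(net, S, present)
    return bool(reach & T)


def is_cut(
    net: ProbabilisticNetwork,
    absent: Iterable[int],
    S: Iterable[str],
    T: Iterable[str],
) -> bool:
    """True iff removing ``absent`` disconnects S from T even with all other
    edges present."""
    S, T = set(S), set(T)
    if S & T:
        return False
    remaining = set(range(net.n_edges)) - set(absent)
    reach = descendants(net, S, remaining)
    return not (reach & T)


def collapse(
    F: XYPolynomial,
    net: ProbabilisticNetwork,
    S: Iterable[str],
    T: Iterable[str],
    *,
    _path_cache: dict[frozenset[int], bool] | None = None,
    _cut_cache: dict[frozenset[int], bool] | None = None,
) -> XYPolynomial:
    """Fold decided terms into the free coefficients ``b`` and ``c``.

    Idempotent; conserves total probability exactly (coefficients are moved,
    never rescaled).  The optional caches memoize path/cut verdicts keyed by
    the present/absent edge set across repeated collapse passes of one query.
    """
    S, T = set(S), set(T)
    path_cache = {} if _path_cache is None else _path_cache
    cut_cache = {} if _cut_cache is None else _cut_cache
    survivors: dict[frozenset[int], float] = {}
    b, c = F.b, F.c
    for present, a in F.terms.items():
        verdict = path_cache.get(present)
        if verdict is None:
            verdict = has_path(net, present, S, T)
            path_cache[present] = verdict
        if verdict:
            b += a
            continue
        absent = F.processed - present
        cut = cut_cache.get(absent)
        if cut is None:
            cut = is_cut(net, absent, S, T)
            cut_cache[absent] = cut
        if cut:
            c += a
        else:
            survivors[present] = a
    return XYPolynomial(processed=F.processed, terms=survivors, b=b, c=c)


def edge_order(
    net: ProbabilisticNetwork, sources: Iterable[str] | None = None
) -> list[int]:
    """Deterministic edge-processing order: BFS from the source set.

    Edges are emitted as their tail node is dequeued, ties broken by input
    edge index; edges unreachable from the sources are appended in input
    order.  The order never affects the reachability value (the binomial
    product commutes) — it only influences how early terms collapse.
    """
    srcs = sorted(net.sources if sources is None else set(sources))
    out_adj = net.out_adjacency()
    order: list[int] = []
    emitted: set[int] = set()
    visited = set(srcs)
    queue = deque(srcs)
    while queue:
        u = queue.popleft()
        for i in out_adj.get(u, ()):
            if i not in emitted:
                emitted.add(i)
                order.append(i)
            v = net.edges[i][1]
            if v not in visited:
                visited.add(v)
                queue.append(v)
    order.extend(i for i in range(net.n_edges) if i not in emitted)
    return order


def _relevant_edges(
    net: ProbabilisticNetwork, S: set[str], T: set[str]
) -> list[int]:
    """Edges that can lie on some S->T path (others never affect P_reach)."""
    fwd = descendants(net, S)
    back = ancestors(net, T)
    return [
        i for i, (u, v) in enumerate(net.edges) if u in fwd and v in back
    ]


def reachability(
    net: ProbabilisticNetwork,
    S: Iterable[str] | None = None,
    T: Iterable[str] | None = None,
    *,
    term_cap: int = DEFAULT_TERM_CAP,
    debug: bool = False,
    prune: bool = True,
    order: Sequence[int] | None = None,
    prune_eps: float = 0.0,
) -> float:
    """Exact ``P_reach(G, S, T)`` via the collapsing xy-polynomial.

    Parameters
    ----------
    S, T
        Source and target node sets; default to the network's designated
        sources and targets.  A common member makes the result 1.
    term_cap
        Maximum number of simultaneously live terms; exceeding it raises
        :class:`ResourceError` naming the cap (worst case is exponential).
    debug
        Assert probability conservation after every multiplication and
        collapse, and the end-state invariants (no surviving non-free term,
        ``b + c == 1`` within 1e-12).
    prune
        Drop edges that cannot lie on any S->T path before processing; this
        never changes the result.
    order
        Explicit edge-processing permutation (indices into the full edge
        list); defaults to BFS order from ``S``.
    prune_eps
        If positive, live terms with coefficient below this value are
        discarded (their mass is reported in neither b nor c).  The result
        is then a lower bound accurate to the discarded mass; exact by
        default.
    """
    S = set(net.sources if S is None else S)
    T = set(net.targets if T is None else T)
    if not S or not T:
        raise ValidationError("source and target sets must be non-empty")
    missing = (S | T) - net.nodes
    if missing:
        raise ValidationError(f"nodes {sorted(missing)} not in the network")
    if S & T:
        return 1.0

    if prune:
        edges = _relevant_edges(net, S, T)
        if not edges:
            return 0.0
    else:
        edges = list(range(net.n_edges))

    edges_set = set(edges)
    if order is None:
        seq = [i for i in edge_order(net, S) if i in edges_set]
    else:
        seq = [i for i in order if i in edges_set]
        if len(seq) != len(edges):
            raise ValidationError("order must cover every processed edge exactly once")

    F = initial_polynomial()
    path_cache: dict[frozenset[int], bool] = {}
    cut_cache: dict[frozenset[int], bool] = {}
    # Cut checks run against the full edge set: edges pruned as irrelevant
    # can never create an S->T path, so verdicts are unchanged and every
    # term is decided once the relevant edges are processed.
    for e in seq:
        F = multiply_binomial(F, e, net.probs[e])
        if debug:
            F.check_conservation()
        if len(F.terms) > term_cap:
            raise ResourceError(
                f"live term count {len(F.terms)} exceeds cap {term_cap}"
            )
        F = collapse(F, net, S, T, _path_cache=path_cache, _cut_cache=cut_cache)
        if debug:
            F.check_conservation()
        if prune_eps > 0.0:
            F.terms = {s: a for s, a in F.terms.items() if a >= prune_eps}
    if debug:
        if F.terms:
            raise StateError("undecided terms survive after the final edge")
        if abs(F.b + F.c - 1.0) > CONSERVATION_TOL:
            raise StateError("b + c deviates from 1 after the final edge")
    return min(max(F.b, 0.0), 1.0)


class DeterministicInstance(NamedTuple):
    """One concrete instance: the present edge subset and its probability."""

    present: frozenset[int]
    probability: float


def deterministic_instances(
    net: ProbabilisticNetwork, bound: int = DEFAULT_ENUM_BOUND
) -> Iterable[DeterministicInstance]:
    """Yield all ``2**|E|`` deterministic instances (small networks only)."""
    n = net.n_edges
    if n > bound:
        raise ResourceError(f"|E| = {n} exceeds enumeration bound {bound}")
    for mask in range(1 << n):
        prob = 1.0
        present = []
        for i in range(n):
            if mask >> i & 1:
                prob *= net.probs[i]
                present.append(i)
            else:
                prob *= 1.0 - net.probs[i]
        yield DeterministicInstance(frozenset(present), prob)


def reachability_bruteforce(
    net: ProbabilisticNetwork,
    S: Iterable[str] | None = None,
    T: Iterable[str] | None = None,
    bound: int = DEFAULT_ENUM_BOUND,
) -> float:
    """Enumeration oracle: sum instance probabilities over path-containing
    instances.

    Exact up to floating-point summation.  Independent of the polynomial
    machinery (own adjacency and search code); two elementary speedups are
    used — instance probabilities via an iterated outer product, and the
    fact that supersets of a path-containing edge set also contain a path.
    """
    S = set(net.sources if S is None else S)
    T = set(net.targets if T is None else T)
    if not S or not T:
        raise ValidationError("source and target sets must be non-empty")
    if S & T:
        return 1.0
    n = net.n_edges
    if n > bound:
        raise ResourceError(f"|E| = {n} exceeds enumeration bound {bound}")

    # Probability of each of the 2**n masks (bit i = edge i present).
    mass = np.ones(1)
    for i in range(n):
        p = net.probs[i]
        mass = np.concatenate([mass * (1.0 - p), mass * p])

    nodes = sorted(net.nodes)
    node_id = {v: k for k, v in enumerate(nodes)}
    edge_pairs = [(node_id[u], node_id[v]) for u, v in net.edges]
    src_ids = [node_id[s] for s in S]
    tgt_mask = 0
    for t in T:
        tgt_mask |= 1 << node_id[t]

    def path_bfs(mask: int) -> bool:
        adj: dict[int, list[int]] = {}
        for i in range(n):
            if mask >> i & 1:
                u, v = edge_pairs[i]
                adj.setdefault(u, []).append(v)
        seen = set(src_ids)
        stack = list(src_ids)
        while stack:
            u = stack.pop()
            if tgt_mask >> u & 1:
                return True
            for v in adj.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return any(tgt_mask >> u & 1 for u in seen)

    flags = bytearray(1 << n)
    total = 0.0
    for mask in range(1 << n):
        if mask:
            sub = mask & (mask - 1)  # mask without its lowest set bit
            if flags[sub]:
                flags[mask] = 1
                total += mass[mask]
                continue
        if path_bfs(mask):
            flags[mask] = 1
            total += mass[mask]
    return float(total)


def random_network(
    rng: random.Random | np.random.Generator,
    n_nodes: int = 8,
    n_edges: int = 12,
) -> ProbabilisticNetwork:
    """Small random digraph with uniform [0,1] edge probabilities and random
    non-empty source/target sets; used by the oracle-equivalence suites."""
    if isinstance(rng, np.random.Generator):
        randint = lambda a, b: int(rng.integers(a, b + 1))
        uniform = lambda: float(rng.random())
        sample = lambda pop, k: list(rng.choice(pop, size=k, replace=False))
    else:
        randint = rng.randint
        uniform = rng.random
        sample = rng.sample
    nodes = [f"n{i}" for i in range(n_nodes)]
    pairs = [(u, v) for u, v in itertools.permutations(nodes, 2)]
    k = min(n_edges, len(pairs))
    idx = sample(range(len(pairs)), k)
    edges = tuple(pairs[i] for i in sorted(idx))
    probs = tuple(uniform() for _ in edges)
    n_src = randint(1, max(1, n_nodes // 3))
    n_tgt = randint(1, max(1, n_nodes // 3))
    srcs = frozenset(nodes[i] for i in sample(range(n_nodes), n_src))
    tgts = frozenset(nodes[i] for i in sample(range(n_nodes), n_tgt))
    return ProbabilisticNetwork(
        edges=edges, probs=probs, sources=srcs, targets=tgts,
        extra_nodes=frozenset(nodes) - {u for e in edges for u in e},
    )
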