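"""Domain model and I/O for probabilistic signaling networks.

A probabilistic network is a directed graph ``G = (V, E, P)`` in which every
edge ``e`` carries an independent existence probability ``P(e)`` in ``[0, 1]``.
Designated *source* nodes model receptors (where an extracellular signal
enters) and *target* nodes model reporters (typically transcription factors).
Such a network summarizes ``2**|E|`` deterministic instances, one per subset
of edges assumed present.

File formats
------------
Edge list: tab-separated, ``#`` comment lines allowed, no header.  A 3-field
line is ``source  target  probability`` with the probability already on the
``[0, 1]`` scale.  A 4-field line carries a raw confidence score on the
``[1, 1000]`` scale (as distributed by interaction databases such as STRING)
in the 4th field; it is divided by 1000 via :func:`normalize_confidence` and
used as the edge probability (the 3rd field may then be a placeholder such
as ``.``).

Roles file: tab-separated ``node  role`` with role one of ``source``,
``target``, ``internal``.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path


class NetworkError(ValueError):
    """Base class for network model errors."""


class ParseError(NetworkError):
    """A line of an input file could not be parsed."""


class ValidationError(NetworkError):
    """A structural invariant of the network is violated."""


ROLES = ("source", "target", "internal")

#: Reserved node names used by :func:`augment_super_terminals`.
SUPER_SOURCE = "__super_source__"
SUPER_SINK = "__super_sink__"


@dataclass(frozen=True)
class ProbabilisticNetwork:
    """Directed graph with per-edge existence probabilities and terminal sets.

    Parameters
    ----------
    edges
        Ordered tuple of directed ``(u, v)`` pairs; input order is preserved
        and edge indices into this tuple are the canonical edge identifiers.
    probs
        Existence probability of each edge, aligned with ``edges``.
    sources, targets
        Non-empty subsets of the node set (receptors and reporters; they may
        overlap).
    extra_nodes
        Nodes that appear in no edge (e.g. declared only in a roles file).
    """

    edges: tuple[tuple[str, str], ...]
    probs: tuple[float, ...]
    sources: frozenset[str]
    targets: frozenset[str]
    extra_nodes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.probs):
            raise ValidationError("edges and probs must have equal length")
        seen: set[tuple[str, str]] = set()
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-loop {u!r} -> {v!r} is not allowed")
            if (u, v) in seen:
                raise ValidationError(f"duplicate edge {u!r} -> {v!r}")
            seen.add((u, v))
        for (u, v), p in zip(self.edges, self.probs):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"probability {p!r} of edge {u!r} -> {v!r} outside [0, 1]"
                )
        nodes = self.nodes
        if not self.sources:
            raise ValidationError("source set is empty")
        if not self.targets:
            raise ValidationError("target set is empty")
        for s in self.sources | self.targets:
            if s not in nodes:
                raise ValidationError(f"terminal node {s!r} is not in the network")

    @property
    def nodes(self) -> frozenset[str]:
        """All node identifiers (edge endpoints plus isolated declared nodes)."""
        out: set[str] = set(self.extra_nodes)
        for u, v in self.edges:
            out.add(u)
            out.add(v)
        return frozenset(out)

    @property
    def prob(self) -> dict[tuple[str, str], float]:
        """Mapping ``(u, v) -> P(e)``."""
        return dict(zip(self.edges, self.probs))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_adjacency(self) -> dict[str, list[int]]:
        """Node -> list of outgoing edge indices, in input-edge order."""
        adj: dict[str, list[int]] = defaultdict(list)
        for i, (u, _) in enumerate(self.edges):
            adj[u].append(i)
        return dict(adj)

    def in_adjacency(self) -> dict[str, list[int]]:
        adj: dict[str, list[int]] = defaultdict(list)
        for i, (_, v) in enumerate(self.edges):
            adj[v].append(i)
        return dict(adj)


@dataclass(frozen=True)
class EdgeSubset:
    """A subset of a network's edges, stored as indices into its edge list."""

    indices: frozenset[int]

    @classmethod
    def of(cls, indices: Iterable[int]) -> "EdgeSubset":
        idx = frozenset(indices)
        if not all(isinstance(i, int) and i >= 0 for i in idx):
            raise ValidationError("edge indices must be non-negative integers")
        return cls(idx)

    def validate_against(self, net: ProbabilisticNetwork) -> None:
        bad = [i for i in self.indices if i >= net.n_edges]
        if bad:
            raise ValidationError(f"edge indices {sorted(bad)} out of range")


def normalize_confidence(score: int | float) -> float:
    """Map a raw confidence score on the [1, 1000] scale to a probability.

    A score of 1000 means 100% confidence; the probability is ``score / 1000``.
    """
    if not (1 <= score <= 1000):
        raise ValidationError(f"confidence score {score!r} outside [1, 1000]")
    return float(score) / 1000.0


def _parse_prob(text: str, path: str, lineno: int) -> float:
    try:
        p = float(text)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: cannot parse probability {text!r}") from exc
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"{path}:{lineno}: probability {p} outside [0, 1]")
    return p


def read_network(edge_path: str | Path, roles_path: str | Path) -> ProbabilisticNetwork:
    """Read a probabilistic network from an edge-list and a roles file.

    The node set is the union of edge endpoints and nodes declared in the
    roles file.  Raises :class:`ParseError` for malformed lines (with line
    numbers) and :class:`ValidationError` for out-of-range probabilities,
    duplicate edges, self-loops and empty terminal sets.
    """
    edge_path, roles_path = Path(edge_path), Path(roles_path)
    edges: list[tuple[str, str]] = []
    probs: list[float] = []
    for lineno, raw in enumerate(edge_path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 3:
            u, v, ptext = fields
            p = _parse_prob(ptext, str(edge_path), lineno)
        elif len(fields) == 4:
            u, v, _, stext = fields
            try:
                score = float(stext)
            except ValueError as exc:
                raise ParseError(
                    f"{edge_path}:{lineno}: cannot parse confidence {stext!r}"
                ) from exc
            p = normalize_confidence(score)
        else:
            raise ParseError(
                f"{edge_path}:{lineno}: expected 3 or 4 tab-separated fields, "
                f"got {len(fields)}"
            )
        if not u or not v:
            raise ParseError(f"{edge_path}:{lineno}: empty node identifier")
        edges.append((u, v))
        probs.append(p)

    sources: set[str] = set()
    targets: set[str] = set()
    declared: set[str] = set()
    for lineno, raw in enumerate(roles_path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"{roles_path}:{lineno}: expected 2 tab-separated fields, "
                f"got {len(fields)}"
            )
        node, role = fields
        if role not in ROLES:
            raise ParseError(
                f"{roles_path}:{lineno}: unknown role {role!r} "
                f"(expected one of {ROLES})"
            )
        declared.add(node)
        if role == "source":
            sources.add(node)
        elif role == "target":
            targets.add(node)

    endpoint_nodes = {u for u, _ in edges} | {v for _, v in edges}
    return ProbabilisticNetwork(
        edges=tuple(edges),
        probs=tuple(probs),
        sources=frozenset(sources),
        targets=frozenset(targets),
        extra_nodes=frozenset(declared - endpoint_nodes),
    )


def write_network(
    net: ProbabilisticNetwork, edge_path: str | Path, roles_path: str | Path
) -> None:
    """Write the network in the same dialect :func:`read_network` consumes.

    Probabilities are emitted with 12 decimal digits; roles are written for
    every node (``internal`` when neither source nor target).
    """
    edge_lines = [
        f"{u}\t{v}\t{p:.12f}" for (u, v), p in zip(net.edges, net.probs)
    ]
    Path(edge_path).write_text("\n".join(edge_lines) + ("\n" if edge_lines else ""))
    role_lines = []
    for node in sorted(net.nodes):
        if node in net.sources:
            role = "source"
        elif node in net.targets:
            role = "target"
        else:
            role = "internal"
        role_lines.append(f"{node}\t{role}")
    Path(roles_path).write_text("\n".join(role_lines) + "\n")


def remove_node(net: ProbabilisticNetwork, v: str) -> ProbabilisticNetwork:
    """Return a copy of the network without ``v`` and its incident edges.

    ``v`` is also dropped from the source/target sets if present.  Raises
    ``KeyError`` if ``v`` is not a node.  Terminal sets may become empty in
    the result; reachability queries on such a network will reject them.
    """
    if v not in net.nodes:
        raise KeyError(v)
    keep = [(e, p) for e, p in zip(net.edges, net.probs) if v not in e]
    edges = tuple(e for e, _ in keep)
    probs = tuple(p for _, p in keep)
    sources = net.sources - {v}
    targets = net.targets - {v}
    endpoint_nodes = {u for u, _ in edges} | {w for _, w in edges}
    extra = (net.nodes - {v}) - endpoint_nodes
    # Frozen-dataclass validation requires non-empty terminals; build leniently.
    obj = object.__new__(ProbabilisticNetwork)
    object.__setattr__(obj, "edges", edges)
    object.__setattr__(obj, "probs", probs)
    object.__setattr__(obj, "sources", frozenset(sources))
    object.__setattr__(obj, "targets", frozenset(targets))
    object.__setattr__(obj, "extra_nodes", frozenset(extra))
    return obj


def augment_super_terminals(
    net: ProbabilisticNetwork,
    src_set: Iterable[str],
    tgt_set: Iterable[str],
) -> ProbabilisticNetwork:
    """Wire a virtual super-source/super-sink pair to node sets with p = 1.

    The returned network has one extra source (:data:`SUPER_SOURCE`) with a
    probability-1 edge to every node of ``src_set``, and one extra target
    (:data:`SUPER_SINK`) fed by a probability-1 edge from every node of
    ``tgt_set``.  Super-source -> super-sink reachability then equals the
    probability that at least one ``tgt_set`` node is reachable from at least
    one ``src_set`` node.
    """
    src_set = sorted(set(src_set))
    tgt_set = sorted(set(tgt_set))
    if not src_set or not tgt_set:
        raise ValidationError("super-terminal augmentation needs non-empty node sets")
    nodes = net.nodes
    for n in [*src_set, *tgt_set]:
        if n not in nodes:
            raise ValidationError(f"node {n!r} not in the network")
    if SUPER_SOURCE in nodes or SUPER_SINK in nodes:
        raise ValidationError("network already contains super-terminal nodes")
    new_edges = list(net.edges)
    new_probs = list(net.probs)
    for s in src_set:
        new_edges.append((SUPER_SOURCE, s))
        new_probs.append(1.0)
    for t in tgt_set:
        new_edges.append((t, SUPER_SINK))
        new_probs.append(1.0)
    return ProbabilisticNetwork(
        edges=tuple(new_edges),
        probs=tuple(new_probs),
        sources=frozenset({SUPER_SOURCE}),
        targets=frozenset({SUPER_SINK}),
        extra_nodes=net.extra_nodes,
    )


def descendants(
    net: ProbabilisticNetwork,
    roots: Iterable[str],
    edge_indices: Iterable[int] | None = None,
) -> set[str]:
    """Nodes reachable from ``roots`` (inclusive) along the given edges.

    ``edge_indices`` defaults to all edges (the underlying topology).
    """
    allowed = set(range(net.n_edges)) if edge_indices is None else set(edge_indices)
    adj: dict[str, list[str]] = defaultdict(list)
    for i in allowed:
        u, v = net.edges[i]
        adj[u].append(v)
    seen = set(roots)
    stack = list(seen)
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def ancestors(
    net: ProbabilisticNetwork,
    roots: Iterable[str],
    edge_indices: Iterable[int] | None = None,
) -> set[str]:
    """Nodes from which ``roots`` (inclusive) can be reached along the edges."""
    allowed = set(range(net.n_edges)) if edge_indices is None else set(edge_indices)
    radj: dict[str, list[str]] = defaultdict(list)
    for i in allowed:
        u, v = net.edges[i]
        radj[v].append(u)
    seen = set(roots)
    stack = list(seen)
    while stack:
        u = stack.pop()
        for v in radj.get(u, ()):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen
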