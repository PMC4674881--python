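"""Probabilistic node centrality and comparison with betweenness.

A node ``v`` is *essential* for a source-target pair ``(s, t)`` if its
removal disconnects ``s`` from ``t``.  In a probabilistic network this is a
random event; its probability is the drop in reachability caused by
removing ``v``::

    C_v(G, s, t) = P_reach(G, s, t) - P_reach(G', s, t)

where ``G'`` is ``G`` without ``v`` and its incident edges.  The number of
pairs for which ``v`` is essential, ``X_v``, follows a Poisson-binomial
distribution with parameters ``C_v(G, s, t)``, so the node's centrality —
the expected essential-pair count — is simply the sum of the ``C_v`` values
over all source-target pairs.

For comparison with the deterministic world, the module also computes the
classical shortest-path betweenness of the underlying topology (all edges
certain) and a per-node rank-disagreement statistic between the two
rankings.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network_model import ProbabilisticNetwork, ValidationError, remove_node
from .preach_core import reachability

_CLAMP_TOL = 1e-9


class ConsistencyError(RuntimeError):
    """A computed quantity violates a mathematical guarantee (e.g. a
    substantially negative essentiality probability)."""


def pair_essentiality(
    net: ProbabilisticNetwork, v: str, s: str, t: str, **reach_kwargs
) -> float:
    """Probability that ``v`` is essential for the pair ``(s, t)``.

    Requires ``v`` distinct from both terminals.  The value is clamped to 0
    when floating-point noise makes it negative by at most 1e-9; a larger
    negative value (impossible mathematically: node removal cannot increase
    reachability) raises :class:`ConsistencyError`.
    """
    if v in (s, t):
        raise ValidationError(f"node {v!r} is a terminal of the pair ({s!r}, {t!r})")
    for n in (v, s, t):
        if n not in net.nodes:
            raise KeyError(n)
    before = reachability(net, {s}, {t}, **reach_kwargs)
    reduced = remove_node(net, v)
    after = reachability(reduced, {s}, {t}, **reach_kwargs)
    diff = before - after
    if diff < -_CLAMP_TOL:
        raise ConsistencyError(
            f"essentiality of {v!r} for ({s!r}, {t!r}) is {diff}, "
            "below the floating-point tolerance"
        )
    return min(max(diff, 0.0), before if before > 0 else 0.0)


def node_centrality(
    net: ProbabilisticNetwork,
    v: str,
    *,
    include_terminal_pairs: bool = False,
    **reach_kwargs,
) -> float:
    """Expected number of source-target pairs for which ``v`` is essential.

    By default pairs with ``v in {s, t}`` are excluded: essentiality
    formalizes the importance of *relay* nodes, and counting a receptor or
    reporter as essential for its own pairs would trivially inflate its
    score.  With ``include_terminal_pairs=True`` such pairs contribute
    ``P_reach(G, s, t)`` (removal of a terminal disconnects the pair with
    certainty whenever it was connected).
    """
    if v not in net.nodes:
        raise KeyError(v)
    total = 0.0
    for s in sorted(net.sources):
        for t in sorted(net.targets):
            if v in (s, t):
                if include_terminal_pairs:
                    total += reachability(net, {s}, {t}, **reach_kwargs)
                continue
            if s == t:
                continue  # reachability is identically 1; no node is essential
            total += pair_essentiality(net, v, s, t, **reach_kwargs)
    return total


def deterministic_betweenness(net: ProbabilisticNetwork) -> dict[str, float]:
    """Shortest-path betweenness of the underlying deterministic topology.

    All edges are treated as certain and unweighted; the directed
    normalization ``1 / ((|V|-1)(|V|-2))`` is applied.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    return dict(nx.betweenness_centrality(g, normalized=True))


def rank_by_score(scores: Mapping[str, float]) -> list[str]:
    """Descending-score ranking, ties broken by node identifier."""
    return sorted(scores, key=lambda n: (-scores[n], n))


def rank_disagreement(
    rank_a: Sequence[str] | Mapping[str, float],
    rank_b: Sequence[str] | Mapping[str, float],
) -> dict[str, float]:
    """Per-node disagreement between two rankings, normalized to [0, 1].

    For each node ``x`` the statistic counts the nodes ``y`` that precede
    ``x`` in one ranking but follow it in the other, divided by the total
    number of nodes.  Rankings may be given as ordered sequences (most
    central first) or as score mappings; with score mappings, nodes with
    equal scores count as agreeing in that ranking.
    """
    order_a, score_a = _as_order(rank_a)
    order_b, score_b = _as_order(rank_b)
    if set(order_a) != set(order_b):
        raise ValidationError("rankings must cover the same node set")
    n = len(order_a)
    pos_a = {v: i for i, v in enumerate(order_a)}
    pos_b = {v: i for i, v in enumerate(order_b)}
    out: dict[str, float] = {}
    for x in order_a:
        count = 0
        for y in order_a:
            if y == x:
                continue
            if score_a is not None and score_a[x] == score_a[y]:
                continue
            if score_b is not None and score_b[x] == score_b[y]:
                continue
            da = pos_a[y] - pos_a[x]
            db = pos_b[y] - pos_b[x]
            if da * db < 0:
                count += 1
        out[x] = count / n
    return out


def _as_order(
    ranking: Sequence[str] | Mapping[str, float],
) -> tuple[list[str], Mapping[str, float] | None]:
    if isinstance(ranking, Mapping):
        return rank_by_score(ranking), ranking
    order = list(ranking)
    if len(set(order)) != len(order):
        raise ValidationError("ranking contains duplicate nodes")
    return order, None


@dataclass
class CentralityTable:
    """Per-node centrality summary.

    ``pair_values`` stores ``C_v(G, s, t)`` per node and pair; ``totals``
    the Poisson-binomial expected essential-pair counts (their sums);
    ``betweenness`` the deterministic companion values.
    """

    pair_values: dict[str, dict[tuple[str, str], float]]
    totals: dict[str, float]
    betweenness: dict[str, float]
    disagreement: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per node with both centralities, ranks and
        rank disagreement, sorted by descending probabilistic centrality."""
        prob_rank = {v: i + 1 for i, v in enumerate(rank_by_score(self.totals))}
        det_rank = {v: i + 1 for i, v in enumerate(rank_by_score(self.betweenness))}
        rows = [
            {
                "node": v,
                "probabilistic_centrality": self.totals[v],
                "deterministic_betweenness": self.betweenness[v],
                "prob_rank": prob_rank[v],
                "det_rank": det_rank[v],
                "disagreement": self.disagreement.get(v, float("nan")),
            }
            for v in sorted(self.totals, key=lambda n: prob_rank[n])
        ]
        return pd.DataFrame(rows)


def centrality_table(
    net: ProbabilisticNetwork,
    *,
    include_terminal_pairs: bool = False,
    **reach_kwargs,
) -> CentralityTable:
    """Compute probabilistic centrality, betweenness and rank disagreement
    for every node of the network."""
    pair_values: dict[str, dict[tuple[str, str], float]] = {}
    totals: dict[str, float] = {}
    for v in sorted(net.nodes):
        per_pair: dict[tuple[str, str], float] = {}
        for s in sorted(net.sources):
            for t in sorted(net.targets):
                if s == t:
                    continue
                if v in (s, t):
                    if include_terminal_pairs:
                        per_pair[(s, t)] = reachability(net, {s}, {t}, **reach_kwargs)
                    continue
                per_pair[(s, t)] = pair_essentiality(net, v, s, t, **reach_kwargs)
        pair_values[v] = per_pair
        totals[v] = sum(per_pair.values())
    betw = deterministic_betweenness(net)
    disagreement = rank_disagreement(totals, betw)
    return CentralityTable(
        pair_values=pair_values,
        totals=totals,
        betweenness=betw,
        disagreement=disagreement,
    )
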