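"""Network stability under random perturbation.

A signaling network is *stable* if small random perturbations of its edge
probabilities or of its topology leave the source-to-target reachability
probabilities largely unchanged.  The perturbation response is::

    delta_P = 1/(|S||T|) * sum_{s in S, t in T} [P_reach(G_d, s, t) - P_reach(G, s, t)]

where ``G_d`` is the perturbed network.  A large magnitude indicates an
unstable network; a negative sign a drop in reachability (the cell becoming
unresponsive), a positive sign a rise (over-sensitivity).

Two parametric perturbation models are provided:

* **probability** — every edge probability is redrawn uniformly at random
  from the truncated window ``[P(e) - d, P(e) + d] ∩ [0, 1]``;
* **topology** — degree-preserving edge shuffling: ``d * |E|`` randomly
  selected edges are rewired in pairs, ``(u1,v1), (u2,v2)`` becoming
  ``(u1,v2), (u2,v1)`` with the old probabilities reassigned to the new
  edges in random order.  Every node keeps its in- and out-degree and the
  multiset of edge probabilities is conserved.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .network_model import ProbabilisticNetwork, ValidationError
from .preach_core import reachability

MODELS = ("probability", "topology")


class PerturbationError(RuntimeError):
    """A perturbation could not be realized (e.g. swap retry budget spent)."""


def perturb_probabilities(
    net: ProbabilisticNetwork,
    delta: float,
    seed: int | np.random.Generator,
) -> ProbabilisticNetwork:
    """Redraw each edge probability uniformly on [max(0, p-d), min(1, p+d)].

    The draw is uniform on the *intersected* interval (not drawn wide and
    clamped, which would put point mass at 0 and 1).  ``delta = 0`` returns
    identical probabilities.  Deterministic given the seed.
    """
    if delta < 0:
        raise ValidationError("delta must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    new_probs = []
    for p in net.probs:
        lo = max(0.0, p - delta)
        hi = min(1.0, p + delta)
        new_probs.append(float(rng.uniform(lo, hi)) if hi > lo else lo)
    return ProbabilisticNetwork(
        edges=net.edges,
        probs=tuple(new_probs),
        sources=net.sources,
        targets=net.targets,
        extra_nodes=net.extra_nodes,
    )


def perturb_topology(
    net: ProbabilisticNetwork,
    delta: float,
    seed: int | np.random.Generator,
    *,
    retry_factor: int = 100,
) -> ProbabilisticNetwork:
    """Degree-preserving shuffle of a fraction ``delta`` of the edges.

    ``round(delta * |E| / 2)`` swap operations are performed (each swap
    rewires two edges).  Proposals that would create a self-loop or a
    duplicate edge are rejected and resampled within a retry budget of
    ``retry_factor`` draws per swap; exhausting it raises
    :class:`PerturbationError` reporting the swaps achieved.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValidationError("delta must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = net.n_edges
    n_swaps = round(delta * n / 2.0)
    if n_swaps == 0:
        return net
    if n < 2:
        raise PerturbationError("cannot swap with fewer than 2 edges")
    edges = list(net.edges)
    probs = list(net.probs)
    edge_set = set(edges)
    budget = retry_factor * n_swaps
    done = 0
    while done < n_swaps:
        if budget <= 0:
            raise PerturbationError(
                f"retry budget exhausted after {done} of {n_swaps} swaps"
            )
        budget -= 1
        i, j = (int(x) for x in rng.choice(n, size=2, replace=False))
        u1, v1 = edges[i]
        u2, v2 = edges[j]
        new1, new2 = (u1, v2), (u2, v1)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        survivors = edge_set - {edges[i], edges[j]}
        if new1 in survivors or new2 in survivors or new1 == new2:
            continue
        edge_set = survivors | {new1, new2}
        edges[i], edges[j] = new1, new2
        if rng.random() < 0.5:
            probs[i], probs[j] = probs[j], probs[i]
        done += 1
    return ProbabilisticNetwork(
        edges=tuple(edges),
        probs=tuple(probs),
        sources=net.sources,
        targets=net.targets,
        extra_nodes=net.extra_nodes,
    )


def stability_delta(
    net: ProbabilisticNetwork,
    perturbed: ProbabilisticNetwork,
    **reach_kwargs,
) -> float:
    """Average per-pair reachability change between a network and a
    perturbed version sharing its source and target sets."""
    if net.sources != perturbed.sources or net.targets != perturbed.targets:
        raise ValidationError("networks must share source and target sets")
    total = 0.0
    n_pairs = 0
    for s in sorted(net.sources):
        for t in sorted(net.targets):
            total += reachability(perturbed, {s}, {t}, **reach_kwargs) - reachability(
                net, {s}, {t}, **reach_kwargs
            )
            n_pairs += 1
    return total / n_pairs


@dataclass
class StabilityCurve:
    """Perturbation-response curve for one perturbation model.

    ``replicate_deltas[k]`` holds the per-replicate mean reachability
    changes at ``deltas[k]``; ``means[k]`` their grand mean.
    """

    model: str
    deltas: list[float]
    replicate_deltas: list[list[float]]
    means: list[float]
    replicates: int
    seed: int

    def to_rows(self) -> list[dict]:
        rows = []
        for d, reps, m in zip(self.deltas, self.replicate_deltas, self.means):
            for r, val in enumerate(reps):
                rows.append({"delta": d, "replicate": r, "mean_delta": val})
            rows.append({"delta": d, "replicate": "mean", "mean_delta": m})
        return rows


def stability_curve(
    net: ProbabilisticNetwork,
    model: str,
    delta_grid: Sequence[float],
    replicates: int = 30,
    seed: int = 0,
    **reach_kwargs,
) -> StabilityCurve:
    """Mean reachability change per perturbation magnitude.

    For each delta, ``replicates`` independently perturbed networks are
    generated from per-replicate RNG streams derived from the single user
    seed, and the per-pair mean change is recorded for each; reproducible
    bit-identically for a given seed.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown perturbation model {model!r}")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(delta_grid) * replicates)
    perturb = perturb_probabilities if model == "probability" else perturb_topology
    all_reps: list[list[float]] = []
    means: list[float] = []
    for di, d in enumerate(delta_grid):
        reps: list[float] = []
        for r in range(replicates):
            rng = np.random.default_rng(streams[di * replicates + r])
            try:
                pert = perturb(net, d, rng)
            except PerturbationError as exc:
                raise PerturbationError(
                    f"delta={d}, replicate={r}: {exc}"
                ) from exc
            reps.append(stability_delta(net, pert, **reach_kwargs))
        all_reps.append(reps)
        means.append(float(np.mean(reps)))
    return StabilityCurve(
        model=model,
        deltas=list(delta_grid),
        replicate_deltas=all_reps,
        means=means,
        replicates=replicates,
        seed=seed,
    )
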