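"""Seeded generators for synthetic signaling networks and annotations.

The generator emulates the layered structure of a signaling pathway: a
signal enters at receptor (source) nodes, propagates through intermediate
proteins, and reaches reporter (target) nodes.  Networks are layered DAGs
(sources -> internal -> targets) with independently sampled layer edges and
edge probabilities drawn from a configurable distribution; every target is
guaranteed topologically reachable from at least one source.

Annotation tables carry a configurable pool of background terms plus one
*planted* term: its designated targets get boosted incoming-edge
probabilities, and the term is assigned to the targets with the highest
set-source reachability (and to at least one source), so it is both
enrichable among the most reachable targets and term-reachable.  This is
the positive control every enrichment analysis can be validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .network_model import ProbabilisticNetwork, ValidationError, descendants
from .functions import AnnotationMap, target_reachability_ranking


class GenerationError(RuntimeError):
    """The requested configuration cannot produce a valid network."""


@dataclass(frozen=True)
class PlantedTermSpec:
    """A term planted into the annotations as a known enrichment signal."""

    term: str = "GO:PLANTED"
    count: int = 3                 # annotated targets (the most reachable ones)
    boost: float = 0.9             # incoming-edge boost p -> p + boost*(1-p)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a desk-scale three-layer pathway: 3 receptors, 6
    intermediates, 10 reporters, each cross-layer edge present with
    probability ``density`` and carrying an existence probability from
    ``prob_dist`` (``("uniform", lo, hi)`` or ``("beta", alpha, beta)``).
    """

    n_sources: int = 3
    n_internal: int = 6
    n_targets: int = 10
    density: float = 0.5
    prob_dist: tuple = ("uniform", 0.2, 0.8)
    planted: PlantedTermSpec = field(default_factory=PlantedTermSpec)
    n_terms: int = 20
    connectivity_guarantee: bool = True
    cycle_edges: int = 0           # optional internal->internal back edges
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sources, self.n_internal, self.n_targets) < 1:
            raise ValidationError("layer sizes must be positive")
        if not (0.0 < self.density <= 1.0):
            raise ValidationError("density must be in (0, 1]")
        if self.planted.count > self.n_targets:
            raise ValidationError("planted count exceeds the number of targets")
        if not (0.0 <= self.planted.boost <= 1.0):
            raise ValidationError("boost must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_prob(rng: np.random.Generator, spec: tuple) -> float:
    kind = spec[0]
    if kind == "uniform":
        _, lo, hi = spec
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("uniform bounds must satisfy 0 <= lo <= hi <= 1")
        return float(rng.uniform(lo, hi))
    if kind == "beta":
        _, a, b = spec
        return float(rng.beta(a, b))
    raise ValidationError(f"unknown probability distribution {kind!r}")


def source_names(cfg: GeneratorConfig) -> list[str]:
    return [f"S{i+1}" for i in range(cfg.n_sources)]


def internal_names(cfg: GeneratorConfig) -> list[str]:
    return [f"I{i+1}" for i in range(cfg.n_internal)]


def target_names(cfg: GeneratorConfig) -> list[str]:
    return [f"T{i+1}" for i in range(cfg.n_targets)]


def generate_network(cfg: GeneratorConfig) -> ProbabilisticNetwork:
    """Layered random DAG with the configured density and probabilities.

    Deterministic given ``cfg.seed``.  With the connectivity guarantee on
    (default), extra edges are added so that every target is topologically
    reachable from at least one source; with it off, a disconnected draw
    raises :class:`GenerationError`.  Incoming edges of the planted term's
    designated targets (the first ``planted.count`` target nodes) have
    their probabilities boosted by ``p -> p + boost*(1-p)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5ea]))
    srcs, mids, tgts = source_names(cfg), internal_names(cfg), target_names(cfg)
    edges: list[tuple[str, str]] = []
    probs: list[float] = []

    for s in srcs:
        for m in mids:
            if rng.random() < cfg.density:
                edges.append((s, m))
                probs.append(_sample_prob(rng, cfg.prob_dist))
    for m in mids:
        for t in tgts:
            if rng.random() < cfg.density:
                edges.append((m, t))
                probs.append(_sample_prob(rng, cfg.prob_dist))
    for _ in range(cfg.cycle_edges):
        m1, m2 = rng.choice(cfg.n_internal, size=2, replace=False)
        e = (mids[int(m1)], mids[int(m2)])
        if e not in set(edges):
            edges.append(e)
            probs.append(_sample_prob(rng, cfg.prob_dist))

    def _net() -> ProbabilisticNetwork:
        return ProbabilisticNetwork(
            edges=tuple(edges),
            probs=tuple(probs),
            sources=frozenset(srcs),
            targets=frozenset(tgts),
            extra_nodes=frozenset(srcs) | frozenset(mids) | frozenset(tgts),
        )

    # Connectivity repair: every target reachable from >= 1 source.
    net = _net()
    existing = set(edges)
    reached = descendants(net, srcs)
    fed_mids = [m for m in mids if m in reached]
    if not fed_mids:
        if not cfg.connectivity_guarantee:
            raise GenerationError("no internal node is fed by any source")
        s = srcs[int(rng.integers(cfg.n_sources))]
        m = mids[int(rng.integers(cfg.n_internal))]
        if (s, m) not in existing:
            edges.append((s, m))
            probs.append(_sample_prob(rng, cfg.prob_dist))
            existing.add((s, m))
        fed_mids = [m]
        net = _net()
        reached = descendants(net, srcs)
    for t in tgts:
        if t not in reached:
            if not cfg.connectivity_guarantee:
                raise GenerationError(f"target {t} unreachable from every source")
            m = fed_mids[int(rng.integers(len(fed_mids)))]
            if (m, t) not in existing:
                edges.append((m, t))
                probs.append(_sample_prob(rng, cfg.prob_dist))
                existing.add((m, t))

    # Boost the paths into the planted targets.
    boosted = set(tgts[: cfg.planted.count])
    b = cfg.planted.boost
    for i, (u, v) in enumerate(edges):
        if v in boosted:
            probs[i] = probs[i] + b * (1.0 - probs[i])
    return _net()


def generate_annotations(
    net: ProbabilisticNetwork,
    cfg: GeneratorConfig,
    n_terms: int | None = None,
) -> AnnotationMap:
    """Random background annotations plus the planted enrichment signal.

    Every gene receives 1-4 terms drawn from a pool of ``n_terms``
    background terms.  The planted term additionally annotates the
    ``planted.count`` targets with the highest set-source reachability and
    one source node.  Deterministic given ``cfg.seed``.
    """
    n_terms = cfg.n_terms if n_terms is None else n_terms
    if cfg.planted.count > len(net.targets):
        raise ValidationError("planted count exceeds the number of targets")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xa770]))
    pool = [f"GO:{i+1:07d}" for i in range(n_terms)]
    gene_terms: dict[str, set[str]] = {}
    for gene in sorted(net.nodes):
        k = int(rng.integers(1, 5))
        chosen = rng.choice(n_terms, size=min(k, n_terms), replace=False)
        gene_terms[gene] = {pool[int(i)] for i in chosen}

    ranking = target_reachability_ranking(net)
    top = [t for t, _ in ranking[: cfg.planted.count]]
    for t in top:
        gene_terms.setdefault(t, set()).add(cfg.planted.term)
    src = sorted(net.sources)[int(rng.integers(len(net.sources)))]
    gene_terms.setdefault(src, set()).add(cfg.planted.term)
    return AnnotationMap(gene_terms=gene_terms)
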