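"""Functional characterization of a probabilistic signaling network.

Target genes are annotated with ontology terms (e.g. Gene Ontology); the
functions a network serves are characterized two ways:

* **Enrichment** — targets are ranked by their reachability from the source
  set; for each term the hypergeometric upper tail ``P(X >= n | |T|, d, N)``
  is computed for every prefix length ``d`` of the ranking (``N`` annotated
  targets overall, ``n`` of them among the top ``d``) and the minimum tail
  over ``d`` is the term's enrichment value.  Values of 0.1 or lower mark a
  highly enriched term.
* **Term reachability** — the probability that a signal travels from any
  source annotated with the term to any target annotated with it.

Generic terms near the ontology root (the top five hierarchy levels, i.e.
shortest-path depth 0-4 over is-a/part-of links) can be filtered out before
the analysis.  The module also builds the protein-by-term and
protein-by-protein reachability matrices and clusters their rows
hierarchically to expose groups of functionally similar proteins.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .network_model import ProbabilisticNetwork, ValidationError
from .preach_core import reachability

logger = logging.getLogger(__name__)

#: Ontology relationship types that define the term hierarchy.
HIERARCHY_RELATIONS = ("is_a", "part_of")

#: Enrichment threshold below which a term counts as highly enriched.
HIGHLY_ENRICHED = 0.1

#: "Top five levels": terms at depth <= 4 are considered generic.
GENERIC_MAX_DEPTH = 4


class OntologyError(ValueError):
    """The ontology file is malformed, cyclic, or references unknown terms."""


class TermNotApplicable(ValueError):
    """The term annotates no source or no target, so its reachability is
    undefined (distinct from a reachability of 0)."""


@dataclass
class AnnotationMap:
    """Gene -> term assignments with optional term depths."""

    gene_terms: dict[str, set[str]]
    term_depth: dict[str, int] | None = None

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out

    def genes_with(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a two-column (gene, term) TSV; ``#`` comment lines allowed."""
    gene_terms: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        gene, term = fields
        gene_terms.setdefault(gene, set()).add(term)
    return AnnotationMap(gene_terms=gene_terms)


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    lines = [
        f"{gene}\t{term}"
        for gene in sorted(ann.gene_terms)
        for term in sorted(ann.gene_terms[gene])
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def term_depths(ontology_path: str | Path) -> dict[str, int]:
    """Shortest-path depth of every term from the ontology roots.

    The hierarchy is the union of is-a and part-of links; a root is a term
    with no parent, at depth 0, and a term's depth is the length of the
    shortest parent chain from any root.  Cycles and references to terms
    without their own record raise :class:`OntologyError`.
    """
    import obonet

    graph = obonet.read_obo(str(ontology_path))
    child_parent = nx.DiGraph()
    child_parent.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key in HIERARCHY_RELATIONS:
            if parent not in graph.nodes or not graph.nodes[parent]:
                raise OntologyError(
                    f"term {child!r} references undefined parent {parent!r}"
                )
            child_parent.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(child_parent):
        cycle = nx.find_cycle(child_parent)
        raise OntologyError(f"ontology hierarchy contains a cycle: {cycle}")
    roots = [t for t in child_parent.nodes if child_parent.out_degree(t) == 0]
    parent_child = child_parent.reverse()
    depths = nx.multi_source_dijkstra_path_length(parent_child, roots)
    return {t: int(d) for t, d in depths.items()}


def filter_generic_terms(
    ann: AnnotationMap,
    depths: Mapping[str, int] | None = None,
    *,
    max_generic_depth: int = GENERIC_MAX_DEPTH,
) -> AnnotationMap:
    """Drop generic terms (depth <= ``max_generic_depth``) from every gene.

    Terms without depth information are kept, with a logged warning: depth
    filtering is optional preprocessing and an ontology may not cover every
    annotated term.
    """
    if depths is None:
        depths = ann.term_depth or {}
    missing = sorted(t for t in ann.terms() if t not in depths)
    if missing:
        logger.warning(
            "no depth information for %d term(s) (e.g. %s); keeping them",
            len(missing),
            ", ".join(missing[:3]),
        )
    kept = {
        gene: {t for t in ts if depths.get(t, max_generic_depth + 1) > max_generic_depth}
        for gene, ts in ann.gene_terms.items()
    }
    return AnnotationMap(gene_terms=kept, term_depth=dict(depths))


def _known_genes(net: ProbabilisticNetwork, genes: Iterable[str]) -> set[str]:
    genes = set(genes)
    unknown = genes - net.nodes
    if unknown:
        logger.warning(
            "ignoring %d annotated gene(s) absent from the network (e.g. %s)",
            len(unknown),
            ", ".join(sorted(unknown)[:3]),
        )
    return genes & net.nodes


def target_reachability_ranking(
    net: ProbabilisticNetwork, **reach_kwargs
) -> list[tuple[str, float]]:
    """Targets ranked by reachability from at least one source.

    Returns ``(target, probability)`` pairs sorted by descending
    probability, ties broken by node identifier ascending.
    """
    vals = {
        t: reachability(net, net.sources, {t}, **reach_kwargs)
        for t in net.targets
    }
    return sorted(vals.items(), key=lambda kv: (-kv[1], kv[0]))


def hypergeometric_tail(population: int, successes: int, draws: int, observed: int) -> float:
    """Upper tail ``P(X >= observed)`` for a hypergeometric variable.

    ``X`` counts successes in ``draws`` draws without replacement from a
    population of size ``population`` containing ``successes`` marked
    items.  Computed by direct summation of the probability mass from
    ``observed`` to ``min(successes, draws)`` with exact integer binomials.
    """
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValidationError("invalid hypergeometric parameters")
    if observed <= 0:
        return 1.0
    hi = min(successes, draws)
    if observed > hi:
        return 0.0
    denom = comb(population, draws)
    num = sum(
        comb(successes, k) * comb(population - successes, draws - k)
        for k in range(observed, hi + 1)
    )
    return num / denom


@dataclass
class EnrichmentRecord:
    """Best-prefix hypergeometric enrichment of one term."""

    term: str
    n_annotated: int          # N: annotated targets overall
    best_d: int               # prefix length minimizing the tail
    n_at_best_d: int          # annotated targets among the top best_d
    enrichment: float         # minimal tail probability, in (0, 1]

    @property
    def highly_enriched(self) -> bool:
        return self.enrichment <= HIGHLY_ENRICHED


def term_enrichment(
    term: str,
    ranking: Sequence[tuple[str, float]] | Sequence[str],
    ann: AnnotationMap,
) -> EnrichmentRecord:
    """Enrichment of ``term`` among the most reachable targets.

    ``ranking`` is the output of :func:`target_reachability_ranking` (or a
    plain ordered list of targets).  All prefix lengths ``d`` are tried and
    the minimal tail (smallest ``d`` on ties) is returned.  Raises
    ``ValidationError`` if the term annotates no ranked target.
    """
    order = [x[0] if isinstance(x, tuple) else x for x in ranking]
    annotated = ann.genes_with(term) & set(order)
    N = len(annotated)
    if N == 0:
        raise ValidationError(f"term {term!r} annotates no ranked target")
    total = len(order)
    best: tuple[float, int, int] | None = None
    n = 0
    for d, t in enumerate(order, start=1):
        if t in annotated:
            n += 1
        tail = hypergeometric_tail(total, N, d, n)
        if best is None or tail < best[0]:
            best = (tail, d, n)
    tail, d, n = best
    return EnrichmentRecord(
        term=term, n_annotated=N, best_d=d, n_at_best_d=n, enrichment=tail
    )


def enrich_all(
    net: ProbabilisticNetwork,
    ann: AnnotationMap,
    *,
    ranking: Sequence[tuple[str, float]] | None = None,
    **reach_kwargs,
) -> pd.DataFrame:
    """Enrichment table over every term annotating at least one target."""
    if ranking is None:
        ranking = target_reachability_ranking(net, **reach_kwargs)
    ranked = {t for t, _ in ranking}
    rows = []
    for term in sorted(ann.terms()):
        if not (ann.genes_with(term) & ranked):
            continue
        rec = term_enrichment(term, ranking, ann)
        rows.append(
            {
                "term": rec.term,
                "N": rec.n_annotated,
                "best_d": rec.best_d,
                "n": rec.n_at_best_d,
                "enrichment": rec.enrichment,
                "highly_enriched": rec.highly_enriched,
            }
        )
    return pd.DataFrame(
        rows, columns=["term", "N", "best_d", "n", "enrichment", "highly_enriched"]
    ).sort_values(["enrichment", "term"], ignore_index=True)


def term_reachability(
    net: ProbabilisticNetwork,
    ann: AnnotationMap,
    term: str,
    **reach_kwargs,
) -> float:
    """Reachability of a term: from its annotated sources to its annotated
    targets.

    Raises :class:`TermNotApplicable` when the term annotates no source or
    no target — such terms are excluded from rankings rather than scored 0.
    """
    genes = _known_genes(net, ann.genes_with(term))
    S_a = genes & net.sources
    T_a = genes & net.targets
    if not S_a or not T_a:
        raise TermNotApplicable(
            f"term {term!r} annotates {len(S_a)} source(s) and {len(T_a)} target(s)"
        )
    return reachability(net, S_a, T_a, **reach_kwargs)


def term_reachability_table(
    net: ProbabilisticNetwork, ann: AnnotationMap, **reach_kwargs
) -> pd.DataFrame:
    """Applicable terms ranked by their reachability probability."""
    rows = []
    for term in sorted(ann.terms()):
        genes = ann.genes_with(term) & net.nodes
        S_a, T_a = genes & net.sources, genes & net.targets
        if not S_a or not T_a:
            continue
        rows.append(
            {
                "term": term,
                "n_sources": len(S_a),
                "n_targets": len(T_a),
                "probability": reachability(net, S_a, T_a, **reach_kwargs),
            }
        )
    return pd.DataFrame(
        rows, columns=["term", "n_sources", "n_targets", "probability"]
    ).sort_values(["probability", "term"], ascending=[False, True], ignore_index=True)


def protein_term_matrix(
    net: ProbabilisticNetwork, ann: AnnotationMap, **reach_kwargs
) -> pd.DataFrame:
    """Reachability from every protein to every term's annotated targets.

    Entry ``(i, j)`` is the probability that protein ``i`` reaches at least
    one target annotated with term ``j``; a protein that is itself such a
    target scores 1 (zero-length path).  Terms annotating no target are
    omitted.
    """
    proteins = sorted(net.nodes)
    term_targets = {}
    for term in sorted(ann.terms()):
        tgts = _known_genes(net, ann.genes_with(term)) & net.targets
        if tgts:
            term_targets[term] = tgts
    data = np.zeros((len(proteins), len(term_targets)))
    for j, (term, tgts) in enumerate(term_targets.items()):
        for i, p in enumerate(proteins):
            data[i, j] = reachability(net, {p}, tgts, **reach_kwargs)
    return pd.DataFrame(data, index=proteins, columns=list(term_targets))


def protein_protein_matrix(
    net: ProbabilisticNetwork, **reach_kwargs
) -> pd.DataFrame:
    """Pairwise reachability between all proteins (diagonal is 1)."""
    proteins = sorted(net.nodes)
    data = np.zeros((len(proteins), len(proteins)))
    for i, p in enumerate(proteins):
        for j, q in enumerate(proteins):
            data[i, j] = 1.0 if p == q else reachability(net, {p}, {q}, **reach_kwargs)
    return pd.DataFrame(data, index=proteins, columns=proteins)


@dataclass
class ClusterResult:
    """Row clustering of a reachability matrix for heat-map rendering."""

    leaf_order: list[int]
    labels: list[str]
    linkage: np.ndarray

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def cluster_matrix(
    matrix: pd.DataFrame | np.ndarray,
    *,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of matrix rows.

    Average linkage on Euclidean row distances by default (both
    configurable).  Returns the merge tree and the dendrogram leaf order
    used to reorder the matrix; deterministic for a given input.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        data = matrix.to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(data.shape[0])]
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValidationError("clustering needs a 2-D matrix with at least 2 rows")
    if not np.isfinite(data).all():
        raise ValidationError("matrix entries must be finite")
    Z = linkage(data, method=method, metric=metric)
    order = [int(i) for i in leaves_list(Z)]
    return ClusterResult(leaf_order=order, labels=labels, linkage=Z)
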