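"""Ontology DAG and gene-annotation containers.

The enrichment machinery works on an acyclic ``is_a`` graph with a single
root (a Gene Ontology branch, e.g. molecular function) together with a
gene -> term annotation map.  Annotations obey the *true-path rule*: a gene
annotated to a term is implicitly annotated to every ancestor of that term,
so :class:`AnnotationMap` stores the ancestor-closed sets explicitly.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping

import networkx as nx

__all__ = [
    "OntologyError",
    "CyclicOntologyError",
    "MultiRootError",
    "OntologyDAG",
    "AnnotationMap",
    "AnnotationLoadReport",
]


class OntologyError(ValueError):
    """Malformed ontology structure."""


class CyclicOntologyError(OntologyError):
    """The is_a graph contains a cycle (including self-loops)."""


class MultiRootError(OntologyError):
    """More than one term has no parent."""


@dataclasses.dataclass(frozen=True)
class OntologyDAG:
    """Acyclic single-root term graph with ``is_a`` edges child -> parent.

    ``depth`` is the *longest* path from the root, which is robust when a
    term has several parents and is used as the "most general" tie-break
    when labelling groups of terms.
    """

    graph: nx.DiGraph
    root: str
    names: Mapping[str, str]
    depths: Mapping[str, int]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        names: Mapping[str, str] | None = None,
        extra_terms: Iterable[str] = (),
    ) -> "OntologyDAG":
        """Build and validate a DAG from (child, parent) is_a pairs."""
        g = nx.DiGraph()
        for child, parent in edges:
            if child == parent:
                raise CyclicOntologyError(f"self-loop on term {child!r}")
            g.add_edge(child, parent)
        for t in extra_terms:
            g.add_node(t)
        if g.number_of_nodes() == 0:
            raise OntologyError("empty ontology")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CyclicOntologyError(f"is_a cycle detected: {cycle}")
        roots = sorted(n for n in g.nodes if g.out_degree(n) == 0)
        if len(roots) != 1:
            raise MultiRootError(f"expected a single root, found {roots}")
        root = roots[0]
        # every term must reach the root
        reach = nx.ancestors(g, root) | {root}
        missing = sorted(set(g.nodes) - reach)
        if missing:
            raise OntologyError(f"terms not connected to root {root!r}: {missing}")
        # longest path from root: children before parents in topo order of
        # the child->parent graph, so walk it in reverse.
        depths: dict[str, int] = {}
        for node in reversed(list(nx.topological_sort(g))):
            parents = list(g.successors(node))
            depths[node] = 0 if not parents else 1 + max(depths[p] for p in parents)
        nm = dict(names or {})
        for t in g.nodes:
            nm.setdefault(t, t)
        return cls(graph=g, root=root, names=nm, depths=depths)

    # -- queries -----------------------------------------------------------
    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def depth(self, term: str) -> int:
        return self.depths[term]

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All strict ancestors of *term* (towards the root)."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """All strict descendants of *term* (towards the leaves)."""
        return nx.ancestors(self.graph, term)

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if *a* is a strict ancestor of *b*."""
        return a in self.ancestors(b)


@dataclasses.dataclass
class AnnotationLoadReport:
    n_pairs: int = 0
    n_genes: int = 0
    n_terms: int = 0
    skipped_terms: set[str] = dataclasses.field(default_factory=set)
    n_skipped_pairs: int = 0


@dataclasses.dataclass
class AnnotationMap:
    """Mutually consistent gene->terms and term->genes indexes."""

    gene_to_terms: dict[str, set[str]]
    term_to_genes: dict[str, set[str]]
    report: AnnotationLoadReport | None = None

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        dag: OntologyDAG | None = None,
        propagate: bool = True,
    ) -> "AnnotationMap":
        """Build from (gene, term) pairs, optionally propagating to ancestors.

        Pairs naming terms absent from *dag* are skipped and counted in the
        report; duplicate pairs collapse (set semantics).
        """
        report = AnnotationLoadReport()
        gene_to_terms: dict[str, set[str]] = {}
        for gene, term in pairs:
            report.n_pairs += 1
            if dag is not None and term not in dag:
                report.skipped_terms.add(term)
                report.n_skipped_pairs += 1
                continue
            gene_to_terms.setdefault(gene, set()).add(term)
        if propagate:
            if dag is None:
                raise ValueError("propagation requires an ontology DAG")
            anc_cache: dict[str, set[str]] = {}
            for gene, terms in gene_to_terms.items():
                closed = set(terms)
                for t in terms:
                    if t not in anc_cache:
                        anc_cache[t] = dag.ancestors(t)
                    closed |= anc_cache[t]
                gene_to_terms[gene] = closed
        term_to_genes: dict[str, set[str]] = {}
        for gene, terms in gene_to_terms.items():
            for t in terms:
                term_to_genes.setdefault(t, set()).add(gene)
        report.n_genes = len(gene_to_terms)
        report.n_terms = len(term_to_genes)
        return cls(gene_to_terms=gene_to_terms, term_to_genes=term_to_genes, report=report)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    def is_consistent(self) -> bool:
        fwd = {(g, t) for g, ts in self.gene_to_terms.items() for t in ts}
        rev = {(g, t) for t, gs in self.term_to_genes.items() for g in gs}
        return fwd == rev

    def is_ancestor_closed(self, dag: OntologyDAG) -> bool:
        for terms in self.gene_to_terms.values():
            for t in terms:
                if not dag.ancestors(t) <= terms:
                    return False
        return True
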