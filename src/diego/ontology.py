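"""Ontology structure, gene-term associations and true-path propagation.

The enrichment engine counts genes per term after propagating every direct
annotation to all ancestors reachable through ``is_a`` and ``part_of`` edges
(the true-path rule): a gene annotated to a specific term is implicitly
annotated to every broader term above it.  Other relationship types
(``regulates`` and friends) are not propagated, matching standard GO
practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

PROPAGATING_RELATIONS = frozenset({"is_a", "part_of"})


class OntologyError(ValueError):
    """Raised for structural problems: cycles, unknown terms, bad stanzas."""


@dataclass(frozen=True)
class OntologyTerm:
    """One non-obsolete ontology term and its parent links."""

    id: str
    name: str = ""
    namespace: str = "synthetic"
    #: (parent term id, relation) pairs, relation in PROPAGATING_RELATIONS
    parents: tuple[tuple[str, str], ...] = ()


class OntologyGraph:
    """Directed acyclic term graph with child-to-parent ``is_a``/``part_of`` edges.

    Parameters
    ----------
    terms
        Iterable of :class:`OntologyTerm`.  Every parent referenced by a term
        must itself be present.  Acyclicity is verified at construction.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {t.id: t for t in terms}
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            if not t.id:
                raise OntologyError("empty term id")
            for parent, rel in t.parents:
                if parent == t.id:
                    raise OntologyError(f"term {t.id} is its own parent")
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {t.id} has unknown parent {parent}"
                    )
                if rel not in PROPAGATING_RELATIONS:
                    raise OntologyError(f"unsupported relation {rel!r}")
                g.add_edge(t.id, parent, relation=rel)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology contains a cycle through {cycle[0][0]}")
        self._graph = g
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- basic container protocol ------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, str]]:
        """All (child, parent, relation) triples."""
        return [
            (c, p, d["relation"]) for c, p, d in self._graph.edges(data=True)
        ]

    def name(self, term_id: str) -> str:
        term = self.terms.get(term_id)
        return term.name if term is not None else ""

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive is_a/part_of closure above ``term_id``, excluding itself."""
        if term_id not in self.terms:
            raise OntologyError(f"unknown term {term_id}")
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            # edges point child -> parent, so graph descendants are ancestors
            cached = frozenset(nx.descendants(self._graph, term_id))
            self._ancestor_cache[term_id] = cached
        return cached

    def roots(self) -> set[str]:
        return {t for t in self.terms if self._graph.out_degree(t) == 0}


def ancestors(graph: OntologyGraph, term_id: str) -> frozenset[str]:
    """Functional alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term_id)


@dataclass
class AnnotationSet:
    """Direct and propagated gene-term annotations plus the gene universe.

    ``propagated[t]`` is the set of genes annotated to ``t`` or any of its
    descendants; ``universe`` contains every gene with at least one
    annotation plus any explicitly supplied unannotated background genes.
    """

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def genes_for(self, term_id: str) -> set[str]:
        return self.propagated.get(term_id, set())


def parse_obo(source: str | IO[str]) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Obsolete terms are dropped (``replaced_by`` is not followed); only
    ``is_a`` and ``relationship: part_of`` edges are kept.  Edges pointing at
    terms that are absent from the file (e.g. obsolete parents) are dropped
    with a warning.
    """
    try:
        net = obonet.read_obo(source, ignore_obsolete=True)
    except Exception as exc:  # malformed stanza, bad header, ...
        raise OntologyError(f"failed to parse OBO input: {exc}") from exc

    dropped_edges = 0
    terms = []
    for node, data in net.nodes(data=True):
        parents: list[tuple[str, str]] = []
        for _, parent, rel in net.out_edges(node, keys=True):
            if rel not in PROPAGATING_RELATIONS:
                continue
            if parent not in net:
                dropped_edges += 1
                continue
            parents.append((parent, rel))
        terms.append(
            OntologyTerm(
                id=node,
                name=data.get("name", ""),
                namespace=data.get("namespace", "synthetic"),
                parents=tuple(sorted(set(parents))),
            )
        )
    if dropped_edges:
        logger.warning("dropped %d edges to missing terms", dropped_edges)
    return OntologyGraph(terms)


def parse_associations(
    source: str | IO[str] | Iterable[str],
    dialect: str = "tsv",
    gene_column: str = "symbol",
) -> dict[str, set[str]]:
    """Read direct gene-term associations from GAF 2.x or a 2-column TSV.

    Parameters
    ----------
    source
        Path, open text handle, or iterable of lines.
    dialect
        ``"gaf"`` for 17-column GAF 2.x (comment lines start with ``!``;
        rows whose qualifier contains ``NOT`` are skipped), ``"tsv"`` for
        plain ``gene<TAB>term`` lines.
    gene_column
        For GAF input, ``"symbol"`` takes gene identity from column 3
        (DB object symbol), ``"id"`` from column 2 (DB object ID).

    Returns
    -------
    dict mapping gene id to the set of directly annotated term ids.
    """
    if dialect not in ("gaf", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if gene_column not in ("symbol", "id"):
        raise ValueError(f"gene_column must be 'symbol' or 'id', got {gene_column!r}")

    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    direct: dict[str, set[str]] = {}
    n_not = 0
    try:
        for lineno, line in enumerate(source, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if dialect == "gaf":
                if line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) < 5:
                    raise ValueError(
                        f"GAF line {lineno}: expected >=5 columns, got {len(cols)}"
                    )
                qualifier = cols[3]
                if "NOT" in qualifier.split("|"):
                    n_not += 1
                    continue
                gene = cols[2] if gene_column == "symbol" else cols[1]
                term = cols[4]
            else:
                if line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise ValueError(
                        f"association line {lineno}: expected gene<TAB>term"
                    )
                gene, term = cols[0], cols[1]
            if not gene or not term:
                raise ValueError(f"association line {lineno}: empty field")
            direct.setdefault(gene, set()).add(term)
    finally:
        if close:
            source.close()
    if n_not:
        logger.info("skipped %d NOT-qualified GAF rows", n_not)
    return direct


def propagate(
    graph: OntologyGraph,
    direct: Mapping[str, set[str]],
    extra_universe: Iterable[str] = (),
) -> AnnotationSet:
    """Propagate direct annotations up the DAG (true-path rule).

    Every gene directly annotated to a term is added to that term and to all
    its ancestors.  Annotation rows naming terms absent from ``graph`` are
    skipped with a logged count (tolerating ontology/annotation version
    skew).  ``extra_universe`` adds unannotated background genes to the
    universe.
    """
    propagated: dict[str, set[str]] = {t: set() for t in graph.terms}
    universe: set[str] = set(extra_universe)
    n_dangling = 0
    kept_direct: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        kept = set()
        for t in terms:
            if t not in graph:
                n_dangling += 1
                continue
            kept.add(t)
            propagated[t].add(gene)
            for anc in graph.ancestors(t):
                propagated[anc].add(gene)
        if kept:
            kept_direct[gene] = kept
            universe.add(gene)
    if n_dangling:
        logger.warning(
            "skipped %d annotations to terms absent from the ontology", n_dangling
        )
    return AnnotationSet(direct=kept_direct, propagated=propagated, universe=universe)
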