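"""Ontology loading, ancestor closure, and term propagation.

Phenotype vocabularies such as the Human Phenotype Ontology (HPO) organize
clinical concepts in a directed acyclic graph whose ``is_a`` edges express
subsumption: "Absence seizure" is_a "Generalized-onset seizure" is_a
"Seizure".  Propagating each assigned term to all of its ancestors makes
broader concepts comparable across individuals even when providers coded
them at different levels of specificity.

Only ``is_a`` edges are traversed; all other OBO relationship types are
ignored.  The ontology root (the uninformative "All"-type node) is excluded
from ancestor sets and from propagation output, while high-level sub-roots
such as "Phenotypic abnormality" are retained.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

TERM_ID_RE = re.compile(r"^[A-Za-z]+:\d{7}$")

#: Default branch roots whose descendants are treated as phenotype modifiers
#: (age of onset, severity, quality) rather than phenotypes, and are excluded
#: from association testing: "Clinical modifier" and "Clinical course".
DEFAULT_MODIFIER_ROOTS = ("HP:0012823", "HP:0031797")


class OntologyError(ValueError):
    """Raised for structural problems in an ontology file or query."""


def fixture_path(name: str = "mini_hp.obo"):
    """Path to a packaged fixture file (mini ontology or dictionary)."""
    return resources.files("phenochron.fixtures") / name


@dataclass
class OntologyGraph:
    """An ``is_a`` DAG over ontology terms.

    Parameters
    ----------
    graph
        Directed graph with child -> parent edges, one node per
        non-obsolete term, each carrying a ``name`` attribute.
    root
        The unique term with no parents (the "All"-type node).
    alt_ids
        Mapping from alternate (merged) accession to primary accession.
    """

    graph: nx.DiGraph
    root: str
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[self.resolve(term)]["name"]

    def resolve(self, term: str) -> str:
        """Resolve an accession, mapping alt_ids to their primary id.

        Raises :class:`OntologyError` for ids absent from the ontology.
        """
        if term in self.graph:
            return term
        if term in self.alt_ids:
            primary = self.alt_ids[term]
            logger.debug("alt_id %s resolved to primary id %s", term, primary)
            return primary
        raise OntologyError(f"unknown ontology term id: {term!r}")

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(self.resolve(term)))

    def ancestors(self, term: str, include_self: bool = False) -> set[str]:
        """Transitive ``is_a`` closure of *term*, excluding the root.

        With ``include_self`` the term itself is part of the returned set
        (even if the term *is* the root).
        """
        term = self.resolve(term)
        if term not in self._ancestor_cache:
            anc = nx.descendants(self.graph, term)  # edges point child->parent
            anc.discard(self.root)
            self._ancestor_cache[term] = frozenset(anc)
        result = set(self._ancestor_cache[term])
        if include_self:
            result.add(term)
        return result

    def propagate(self, terms: Iterable[str]) -> set[str]:
        """Union of the terms and all their ancestors (root excluded).

        Idempotent: ``propagate(propagate(S)) == propagate(S)``.
        """
        out: set[str] = set()
        for t in terms:
            out |= self.ancestors(t, include_self=True)
        out.discard(self.root)
        return out

    def in_branch(self, term: str, branch_roots: Iterable[str]) -> bool:
        """True iff *term* lies at or below any of *branch_roots*."""
        closure = self.ancestors(term, include_self=True)
        return any(self.resolve(r) in closure for r in branch_roots)


def load_ontology(path) -> OntologyGraph:
    """Load an OBO file into an :class:`OntologyGraph`.

    Keeps only non-obsolete ``[Term]`` stanzas and ``is_a`` edges.  ``alt_id``
    tags are recorded as aliases resolving to their primary id.  A cycle or
    an ``is_a`` reference to an undeclared term is a hard error.
    """
    try:
        multi = obonet.read_obo(str(path), ignore_obsolete=True)
    except FileNotFoundError:
        raise
    g = nx.DiGraph()
    alt_ids: dict[str, str] = {}
    for node, data in multi.nodes(data=True):
        if "name" not in data:
            # node only referenced as an is_a target, never declared
            raise OntologyError(f"is_a reference to undeclared term: {node!r}")
        g.add_node(node, name=data["name"])
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, key in multi.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in g:
            raise OntologyError(
                f"term {child!r} has is_a pointing to undeclared id {parent!r}"
            )
        g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        cycle_edge = nx.find_cycle(g)[0]
        raise OntologyError(
            f"is_a cycle detected involving edge {cycle_edge[0]!r} -> {cycle_edge[1]!r}"
        )
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise OntologyError(f"expected a single root term, found {sorted(roots)}")
    logger.info(
        "loaded ontology: %d terms, %d is_a edges, root %s",
        g.number_of_nodes(), g.number_of_edges(), roots[0],
    )
    return OntologyGraph(graph=g, root=roots[0], alt_ids=alt_ids)


@lru_cache(maxsize=1)
def load_fixture_ontology() -> OntologyGraph:
    """The packaged ~27-term miniature ontology used in tests and examples."""
    return load_ontology(fixture_path("mini_hp.obo"))
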