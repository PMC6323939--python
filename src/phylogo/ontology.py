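"""Directed acyclic graphs of function terms with typed ``is_a``/``part_of`` relations.

The ontology is modelled the way GO is used for slim construction and
annotation closure: only ``is_a`` and ``part_of`` edges are traversed; every
term belongs to exactly one aspect (namespace) and every non-obsolete term
must reach exactly one aspect root through relation edges.  Other relation
types found in an OBO document (``regulates``, ``occurs_in``, ...) are
dropped at parse time with a warning.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx
import obonet

from .errors import ParseError, StructureError, TermLookupError

logger = logging.getLogger(__name__)

RELATIONS = ("is_a", "part_of")

ASPECTS = ("biological_process", "molecular_function", "cellular_component")

#: GAF single-letter aspect codes.
ASPECT_CODES = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}


@dataclass(frozen=True)
class TermRecord:
    """One ontology term: accession, human-readable name, aspect, obsolete flag."""

    term_id: str
    name: str = ""
    aspect: str | None = None
    obsolete: bool = False


@dataclass
class OntologyGraph:
    """A validated DAG of terms connected by ``is_a`` and ``part_of`` edges.

    Edges are stored child -> parent, i.e. following an edge moves toward
    the aspect root.  ``roots`` maps each aspect to its unique root term.
    """

    terms: dict[str, TermRecord] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    _dag: nx.DiGraph = field(default_factory=nx.DiGraph, repr=False)
    roots: dict[str, str] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_parts(
        cls,
        terms: Iterable[TermRecord],
        edges: Iterable[tuple[str, str, str]],
    ) -> "OntologyGraph":
        g = cls()
        for t in terms:
            if t.term_id in g.terms:
                raise StructureError(f"duplicate term id {t.term_id!r}")
            g.terms[t.term_id] = t
        for child, parent, rel in edges:
            if rel not in RELATIONS:
                raise StructureError(f"unsupported relation {rel!r}")
            g.edges.add((child, parent, rel))
        g._rebuild()
        g.validate()
        return g

    def _rebuild(self) -> None:
        self._dag = nx.DiGraph()
        self._dag.add_nodes_from(self.terms)
        for child, parent, rel in self.edges:
            if self._dag.has_edge(child, parent):
                self._dag[child][parent]["relations"].add(rel)
            else:
                self._dag.add_edge(child, parent, relations={rel})

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise StructureError otherwise."""
        for child, parent, rel in self.edges:
            for end in (child, parent):
                if end not in self.terms:
                    raise StructureError(
                        f"edge ({child} -{rel}-> {parent}) references unknown term {end!r}"
                    )
            c, p = self.terms[child], self.terms[parent]
            if c.obsolete or p.obsolete:
                raise StructureError(
                    f"obsolete term on edge ({child} -{rel}-> {parent})"
                )
            if c.aspect != p.aspect:
                raise StructureError(
                    f"cross-aspect edge {child} ({c.aspect}) -{rel}-> {parent} ({p.aspect})"
                )
        if not nx.is_directed_acyclic_graph(self._dag):
            cycle = nx.find_cycle(self._dag)
            raise StructureError(f"ontology contains a cycle: {cycle}")
        # roots: live terms with no outgoing relation edge, one per aspect
        self.roots = {}
        for tid, rec in self.terms.items():
            if rec.obsolete:
                continue
            if self._dag.out_degree(tid) == 0:
                aspect = rec.aspect or "unspecified"
                if aspect in self.roots:
                    raise StructureError(
                        f"multiple roots in aspect {aspect!r}: "
                        f"{self.roots[aspect]} and {tid}"
                    )
                self.roots[aspect] = tid

    # -- queries -----------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise TermLookupError(f"unknown term {term_id!r}")

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` via is_a/part_of, excluding itself."""
        self._require(term_id)
        return nx.descendants(self._dag, term_id)

    def descendants(self, term_id: str) -> set[str]:
        """All terms from which ``term_id`` is reachable, excluding itself."""
        self._require(term_id)
        return nx.ancestors(self._dag, term_id)

    def parents(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(self._dag.successors(term_id))

    def aspect_of(self, term_id: str) -> str | None:
        self._require(term_id)
        return self.terms[term_id].aspect

    def aspect_root(self, term_id: str) -> str:
        """The root of the aspect that ``term_id`` belongs to."""
        aspect = self.aspect_of(term_id) or "unspecified"
        try:
            return self.roots[aspect]
        except KeyError:  # pragma: no cover - validate() guarantees a root
            raise StructureError(f"no root for aspect {aspect!r}")

    def relation_edges(self, term_id: str) -> list[tuple[str, str]]:
        """Outgoing (parent, relation) pairs for a term, sorted."""
        self._require(term_id)
        out = []
        for _, parent, data in self._dag.out_edges(term_id, data=True):
            for rel in data["relations"]:
                out.append((parent, rel))
        return sorted(out)


# -- OBO I/O ---------------------------------------------------------------


def parse_obo(stream: TextIO | str) -> OntologyGraph:
    """Parse OBO 1.4 text into a validated :class:`OntologyGraph`.

    Only ``is_a`` and ``relationship: part_of`` edges are retained; any other
    relationship type is dropped with a warning.  Obsolete terms are kept as
    isolated records so downstream references to them fail loudly.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        raw = obonet.read_obo(stream, ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise ParseError(f"not parseable as OBO: {exc}") from exc

    terms: list[TermRecord] = []
    edges: set[tuple[str, str, str]] = set()
    stanza_ids = set()
    for tid, data in raw.nodes(data=True):
        if not data:
            # node created only by a parent reference in someone's is_a line
            continue
        stanza_ids.add(tid)
        terms.append(
            TermRecord(
                term_id=tid,
                name=data.get("name", ""),
                aspect=data.get("namespace"),
                obsolete=bool(data.get("is_obsolete") == "true"),
            )
        )
        for parent in data.get("is_a", []):
            edges.add((tid, parent, "is_a"))
        for entry in data.get("relationship", []):
            rel, _, parent = entry.partition(" ")
            parent = parent.strip()
            if rel == "part_of":
                edges.add((tid, parent, "part_of"))
            else:
                logger.warning(
                    "dropping unsupported relation %r on term %s", rel, tid
                )
    dangling = {p for _, p, _ in edges} - stanza_ids
    if dangling:
        raise StructureError(
            f"dangling parent reference(s): {sorted(dangling)}"
        )
    return OntologyGraph.from_parts(terms, edges)


def write_obo(graph: OntologyGraph, stream: TextIO) -> None:
    """Write OBO 1.4; terms sorted by id, relations sorted, byte-deterministic."""
    stream.write("format-version: 1.4\n")
    stream.write("ontology: phylogo\n")
    for tid in sorted(graph.terms):
        rec = graph.terms[tid]
        stream.write("\n[Term]\n")
        stream.write(f"id: {tid}\n")
        if rec.name:
            stream.write(f"name: {rec.name}\n")
        if rec.aspect:
            stream.write(f"namespace: {rec.aspect}\n")
        if rec.obsolete:
            stream.write("is_obsolete: true\n")
        for parent, rel in graph.relation_edges(tid):
            if rel == "is_a":
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: {rel} {parent}\n")


def dumps_obo(graph: OntologyGraph) -> str:
    buf = io.StringIO()
    write_obo(graph, buf)
    return buf.getvalue()


def ancestors(graph: OntologyGraph, term_id: str) -> set[str]:
    """Module-level alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term_id)


def descendants(graph: OntologyGraph, term_id: str) -> set[str]:
    """Module-level alias for :meth:`OntologyGraph.descendants`."""
    return graph.descendants(term_id)
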