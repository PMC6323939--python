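"""GO-slim construction from branch-level annotation usage.

A slim is built automatically from curated gain events across a corpus of
annotated family trees: a term enters the slim when it (or any of its more
specific descendants, following is_a/part_of) was used to annotate strictly
more than ``min_branches`` distinct tree branches; any term that is an
ancestor of two or more such terms is then added so every slim term can be
traced to its aspect root inside the slim itself.  Full-GO annotations are
mapped onto the slim by replacing each term with its most specific slim
ancestor(s).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx

from .annotation import AnnotationRecord, AnnotationSet, BranchEventSet
from .errors import StructureError, TermLookupError
from .ontology import OntologyGraph, TermRecord
from .phylo import FamilyTree

logger = logging.getLogger(__name__)

SELECTED = "selected_by_count"
ANCESTOR = "added_as_ancestor"
ROOT = "root"


@dataclass
class BranchUsageTable:
    """term -> number of distinct (family, branch) pairs annotated with the
    term or any of its descendants (gain events only)."""

    counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, term_id: str) -> int:
        return self.counts.get(term_id, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def items(self):
        return self.counts.items()

    def check_coherence(self, graph: OntologyGraph) -> None:
        """count(ancestor) >= count(descendant) must hold for all pairs."""
        for term, count in self.counts.items():
            for anc in graph.ancestors(term):
                if self.counts.get(anc, 0) < count:
                    raise StructureError(
                        f"usage count incoherence: {anc} < {term}"
                    )


def branch_usage_counts(
    families: Iterable[tuple[FamilyTree, BranchEventSet]],
    graph: OntologyGraph,
) -> BranchUsageTable:
    """Count distinct annotated branches per term with descendant closure.

    A branch is a (family id, node id) pair; each gain of term t marks that
    branch for t and every ancestor of t.  A branch carrying gains of several
    descendants of u still counts once for u.  Losses never count.
    """
    return branch_usage_from_events(
        {tree.family_id: events for tree, events in families}, graph
    )


def branch_usage_from_events(
    events_by_family: Mapping[str, BranchEventSet],
    graph: OntologyGraph,
) -> BranchUsageTable:
    """As :func:`branch_usage_counts`, from an event table alone (branches are
    identified by family id and node id, so trees are not required)."""
    marked: dict[str, set[tuple[str, int]]] = defaultdict(set)
    for family_id, events in events_by_family.items():
        for ev in events.gains():
            if ev.term_id not in graph:
                raise TermLookupError(f"unknown term {ev.term_id!r}")
            branch = (family_id, ev.node_id)
            marked[ev.term_id].add(branch)
            for anc in graph.ancestors(ev.term_id):
                marked[anc].add(branch)
    table = BranchUsageTable({t: len(b) for t, b in marked.items()})
    table.check_coherence(graph)
    return table


@dataclass
class SlimGraph:
    """A reduced ontology whose edges are the transitive reduction of the
    source graph's reachability restricted to slim terms."""

    graph: OntologyGraph
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> dict[str, TermRecord]:
        return self.graph.terms

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def __len__(self) -> int:
        return len(self.graph)

    def assert_root_connected(self, source: OntologyGraph) -> None:
        """Every slim term must reach its aspect root through slim terms."""
        for tid in self.graph.terms:
            root = source.aspect_root(tid)
            if tid == root:
                continue
            if root not in self.graph.ancestors(tid):
                raise StructureError(
                    f"slim term {tid} cannot reach its aspect root {root} "
                    "inside the slim"
                )


def build_slim(
    counts: BranchUsageTable | Mapping[str, int],
    graph: OntologyGraph,
    min_branches: int = 5,
) -> SlimGraph:
    """Two-rule slim construction.

    Step 1 selects terms used on strictly more than ``min_branches`` distinct
    branches.  Step 2 adds every term with >= 2 distinct step-1 terms among
    its descendants, which also guarantees root traceability.  Aspect roots
    are always included.  Edges are the transitive reduction of source-graph
    reachability among slim terms; an edge is labelled ``is_a`` when the two
    terms are connected by an is_a-only path, otherwise ``part_of``.
    """
    get = counts.__getitem__ if isinstance(counts, BranchUsageTable) else (
        lambda t: counts.get(t, 0)
    )
    selected = {
        t for t in graph.terms
        if not graph.terms[t].obsolete and get(t) > min_branches
    }
    members: dict[str, str] = {t: SELECTED for t in selected}
    for t in graph.terms:
        if t in members or graph.terms[t].obsolete:
            continue
        if len(graph.descendants(t) & selected) >= 2:
            members[t] = ANCESTOR
    for root in graph.roots.values():
        members.setdefault(root, ROOT)
    if not selected:
        logger.warning(
            "no term exceeds the %d-branch threshold; slim is roots-only",
            min_branches,
        )

    # reachability DAG among slim terms (child -> parent), then reduce
    reach = nx.DiGraph()
    reach.add_nodes_from(members)
    for t in members:
        for anc in graph.ancestors(t):
            if anc in members:
                reach.add_edge(t, anc)
    reduced = nx.transitive_reduction(reach)

    # is_a-only reachability, for labelling reduced edges
    isa = nx.DiGraph()
    isa.add_nodes_from(graph.terms)
    for child, parent, rel in graph.edges:
        if rel == "is_a":
            isa.add_edge(child, parent)

    edges = set()
    for child, parent in reduced.edges:
        rel = "is_a" if nx.has_path(isa, child, parent) else "part_of"
        edges.add((child, parent, rel))

    slim_graph = OntologyGraph.from_parts(
        [graph.terms[t] for t in members], edges
    )
    slim = SlimGraph(graph=slim_graph, provenance=members)
    slim.assert_root_connected(graph)
    return slim


def map_to_slim(
    annotations: AnnotationSet,
    slim: SlimGraph,
    graph: OntologyGraph,
) -> AnnotationSet:
    """Re-express annotations in slim terms (most specific slim ancestors).

    A record to a term that is itself in the slim maps to that term only;
    otherwise to every minimal slim term among its ancestors (no reported
    term may have another reported term among its descendants).  Records
    with no slim ancestor map to their aspect root.
    """
    out = AnnotationSet(negated=set(annotations.negated))
    cache: dict[str, frozenset[str]] = {}
    for rec in annotations.records:
        if rec.term_id not in graph:
            raise TermLookupError(f"unknown term {rec.term_id!r}")
        if rec.term_id not in cache:
            cache[rec.term_id] = frozenset(_slim_targets(rec.term_id, slim, graph))
        for target in cache[rec.term_id]:
            out.records.add(AnnotationRecord(rec.gene_id, target, rec.evidence))
    return out


def _slim_targets(term_id: str, slim: SlimGraph, graph: OntologyGraph) -> set[str]:
    if term_id in slim:
        return {term_id}
    candidates = graph.ancestors(term_id) & set(slim.terms)
    if not candidates:
        return {graph.aspect_root(term_id)}
    minimal = {
        c for c in candidates
        if not (graph.descendants(c) & candidates)
    }
    return minimal


def write_usage_tsv(table: BranchUsageTable, stream: TextIO) -> None:
    stream.write("term_id\tbranch_count\n")
    for term in sorted(table.counts):
        stream.write(f"{term}\t{table.counts[term]}\n")


def usage_histogram(
    table: BranchUsageTable, bins: tuple[tuple[int, float], ...] = (
        (1, 1), (2, 4), (5, 10), (11, 100), (101, float("inf")),
    )
) -> dict[str, int]:
    """Bin terms by how many distinct branches use them (summary reporting)."""
    out: dict[str, int] = {}
    for lo, hi in bins:
        label = f"{lo}" if lo == hi else (f">{lo - 1}" if hi == float("inf") else f"{lo}-{int(hi)}")
        out[label] = sum(1 for _, c in table.items() if lo <= c <= hi)
    return out
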