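"""Gene-to-term associations and gain/loss events on gene-tree branches.

Curated annotation of a gene family asserts, per GO term, the tree branch on
which the function was gained and (optionally) branches on which it was
subsequently lost.  Functions propagate from the gain branch to all
descendant leaves except through lineages carrying a loss; propagated leaf
annotations receive the IBA evidence code.  Events attach to the branch
ABOVE a node and take effect for that node and all of its descendants; a
re-gain below a loss re-activates the term for that clade (nearest event on
the root-to-leaf path wins).
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, TextIO

from .errors import InputError, ParseError, TermLookupError
from .ontology import ASPECT_CODES, OntologyGraph
from .phylo import FamilyTree, TreeNode

IBA = "IBA"

GAF_COLUMNS = 17


class AnnotationRecord(NamedTuple):
    gene_id: str
    term_id: str
    evidence: str


@dataclass
class AnnotationSet:
    """Set of (gene, term, evidence) triples with gene/term indexes.

    NOT-qualified rows from a GAF never enter ``records``; they are kept in
    ``negated`` for audit only and take no part in propagation or counting.
    """

    records: set[AnnotationRecord] = field(default_factory=set)
    negated: set[AnnotationRecord] = field(default_factory=set)

    def add(self, gene_id: str, term_id: str, evidence: str = "IEA") -> None:
        self.records.add(AnnotationRecord(gene_id, term_id, evidence))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def genes(self) -> set[str]:
        return {r.gene_id for r in self.records}

    def terms(self) -> set[str]:
        return {r.term_id for r in self.records}

    def by_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for r in self.records:
            out[r.gene_id].add(r.term_id)
        return dict(out)

    def by_term(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for r in self.records:
            out[r.term_id].add(r.gene_id)
        return dict(out)


# -- GAF I/O -----------------------------------------------------------------


def parse_gaf(stream: TextIO | str) -> AnnotationSet:
    """Parse GAF 2.x text; rows with a NOT qualifier go to the negated store."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = AnnotationSet()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            raise ParseError(
                f"GAF line {lineno}: expected >= 15 tab-separated columns, "
                f"got {len(cols)}"
            )
        gene_id = cols[1]
        qualifier = cols[3]
        term_id = cols[4]
        evidence = cols[6]
        rec = AnnotationRecord(gene_id, term_id, evidence)
        if "NOT" in qualifier.split("|"):
            out.negated.add(rec)
        else:
            out.records.add(rec)
    return out


def write_gaf(
    annotations: AnnotationSet,
    stream: TextIO,
    graph: OntologyGraph | None = None,
    db: str = "PHYLOGO",
) -> None:
    """Write GAF 2.2; rows sorted for byte-deterministic output."""
    stream.write("!gaf-version: 2.2\n")

    def row(rec: AnnotationRecord, qualifier: str) -> str:
        aspect = ""
        if graph is not None and rec.term_id in graph:
            aspect = ASPECT_CODES.get(graph.aspect_of(rec.term_id) or "", "")
        cols = [""] * GAF_COLUMNS
        cols[0] = db
        cols[1] = rec.gene_id
        cols[2] = rec.gene_id
        cols[3] = qualifier
        cols[4] = rec.term_id
        cols[5] = f"{db}:REF"
        cols[6] = rec.evidence
        cols[8] = aspect
        cols[11] = "protein"
        cols[12] = "taxon:0"
        cols[13] = "20180101"
        cols[14] = db
        return "\t".join(cols) + "\n"

    for rec in sorted(annotations.records):
        stream.write(row(rec, "involved_in"))
    for rec in sorted(annotations.negated):
        stream.write(row(rec, "NOT|involved_in"))


# -- branch events -----------------------------------------------------------


class BranchEvent(NamedTuple):
    node_id: int
    term_id: str
    kind: str  # "gain" | "loss"


@dataclass
class BranchEventSet:
    """Gain/loss assertions attached to the branches of one family tree."""

    events: set[BranchEvent] = field(default_factory=set)

    def add(self, node_id: int, term_id: str, kind: str) -> None:
        if kind not in ("gain", "loss"):
            raise InputError(f"event kind must be gain|loss, got {kind!r}")
        self.events.add(BranchEvent(node_id, term_id, kind))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def by_node(self) -> dict[int, list[BranchEvent]]:
        out: dict[int, list[BranchEvent]] = defaultdict(list)
        for ev in self.events:
            out[ev.node_id].append(ev)
        return dict(out)

    def gains(self) -> list[BranchEvent]:
        return [e for e in self.events if e.kind == "gain"]


@dataclass(frozen=True)
class EventViolation:
    kind: str  # "duplicate_event" | "loss_without_gain" | "unknown_node"
    node_id: int
    term_id: str

    def __str__(self) -> str:
        return f"{self.kind} for term {self.term_id} at node {self.node_id}"


def validate_events(
    tree: FamilyTree, events: BranchEventSet
) -> list[EventViolation]:
    """Return violations: duplicated (node, term) events, losses with no
    ancestral gain of the same term, and events on nodes not in the tree."""
    violations: list[EventViolation] = []
    seen: dict[tuple[int, str], int] = defaultdict(int)
    for ev in events:
        seen[(ev.node_id, ev.term_id)] += 1
        if ev.node_id not in tree.nodes_by_id:
            violations.append(
                EventViolation("unknown_node", ev.node_id, ev.term_id)
            )
    for (node_id, term_id), n in seen.items():
        if n > 1:
            violations.append(
                EventViolation("duplicate_event", node_id, term_id)
            )

    by_node = events.by_node()

    def walk(node: TreeNode, gained: set[str]) -> None:
        local = set(gained)
        for ev in by_node.get(node.node_id, []):
            if ev.kind == "gain":
                local.add(ev.term_id)
            elif ev.term_id not in local:
                violations.append(
                    EventViolation("loss_without_gain", node.node_id, ev.term_id)
                )
        for child in node.children:
            walk(child, local)

    walk(tree.root, set())
    return violations


def propagate(tree: FamilyTree, events: BranchEventSet) -> AnnotationSet:
    """Propagate gains to descendant leaves, honouring losses (IBA records).

    A leaf is annotated with a term iff the nearest event for that term on
    its root-to-leaf path is a gain.
    """
    violations = validate_events(tree, events)
    if violations:
        raise InputError(
            "invalid event set: " + "; ".join(str(v) for v in violations)
        )
    out = AnnotationSet()
    by_node = events.by_node()

    def walk(node: TreeNode, active: frozenset[str]) -> None:
        local = set(active)
        for ev in by_node.get(node.node_id, []):
            if ev.kind == "gain":
                local.add(ev.term_id)
            else:
                local.discard(ev.term_id)
        if node.is_leaf:
            for term in local:
                out.add(node.gene_id, term, IBA)
        for child in node.children:
            walk(child, frozenset(local))

    walk(tree.root, frozenset())
    return out


def close_over_ontology(
    annotations: AnnotationSet, graph: OntologyGraph
) -> AnnotationSet:
    """Expand every record to all its ancestor terms (evidence preserved).

    Idempotent; never removes records.  Unknown terms raise a lookup error.
    """
    out = AnnotationSet(negated=set(annotations.negated))
    cache: dict[str, set[str]] = {}
    for rec in annotations.records:
        if rec.term_id not in graph:
            raise TermLookupError(f"unknown term {rec.term_id!r}")
        if rec.term_id not in cache:
            cache[rec.term_id] = graph.ancestors(rec.term_id)
        out.records.add(rec)
        for anc in cache[rec.term_id]:
            out.records.add(AnnotationRecord(rec.gene_id, anc, rec.evidence))
    return out


# -- event-table I/O ---------------------------------------------------------


def write_events_tsv(
    families: Iterable[tuple[FamilyTree, BranchEventSet]], stream: TextIO
) -> None:
    """Write gain/loss events as TSV: family_id, node_id, term_id, kind."""
    stream.write("family_id\tnode_id\tterm_id\tkind\n")
    for tree, events in families:
        for ev in sorted(events):
            stream.write(f"{tree.family_id}\t{ev.node_id}\t{ev.term_id}\t{ev.kind}\n")


def parse_events_tsv(stream: TextIO | str) -> dict[str, BranchEventSet]:
    """Read the TSV written by :func:`write_events_tsv`, keyed by family id."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: dict[str, BranchEventSet] = defaultdict(BranchEventSet)
    header = stream.readline()
    if not header.startswith("family_id"):
        raise ParseError("expected events TSV header 'family_id\\t...'")
    for lineno, line in enumerate(stream, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ParseError(f"events TSV line {lineno}: expected 4 columns")
        fam, node_id, term_id, kind = cols
        out[fam].add(int(node_id), term_id, kind)
    return dict(out)
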