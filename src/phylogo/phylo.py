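"""Event-labeled gene family trees: parsing, subfamilies, ortholog inference.

Internal nodes of a family tree carry the evolutionary event that caused the
divergence at that node — speciation, gene duplication, or horizontal
transfer — encoded in NHX comments (``[&&NHX:Ev=S]``, ``D``, ``H``).  Leaves
carry a gene identifier and a species label (``[&&NHX:Sp=...]`` or, as a
fallback, the suffix after the last underscore of the leaf name).

Subfamilies are defined at duplication nodes: the duplicate with the more
highly diverged sequence founds a new subfamily, except for recent
duplications confined to a single reference species.  Pairwise orthologs are
gene pairs whose lowest common ancestor is a speciation node.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

from .errors import ParseError, StructureError

EVENTS = ("speciation", "duplication", "horizontal_transfer")
LEAF = "leaf"

_EVENT_CODE = {"S": "speciation", "D": "duplication", "H": "horizontal_transfer"}
_CODE_EVENT = {v: k for k, v in _EVENT_CODE.items()}


@dataclass
class TreeNode:
    """A node of a :class:`FamilyTree`; the branch length is the edge above it."""

    event: str
    node_id: int = -1
    gene_id: str | None = None
    species: str | None = None
    branch_length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.event == LEAF

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]


@dataclass
class FamilyTree:
    """Rooted gene tree with event labels; leaves indexed by gene id."""

    root: TreeNode
    family_id: str = "FAM"
    leaf_index: dict[str, TreeNode] = field(default_factory=dict)
    nodes_by_id: dict[int, TreeNode] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index()
        self.validate()

    def _index(self) -> None:
        self.leaf_index = {}
        self.nodes_by_id = {}
        for i, node in enumerate(self.root.preorder()):
            node.node_id = i
            self.nodes_by_id[i] = node
            if node.is_leaf:
                if node.gene_id in self.leaf_index:
                    raise StructureError(f"duplicate gene id {node.gene_id!r}")
                self.leaf_index[node.gene_id] = node

    def validate(self) -> None:
        for node in self.root.preorder():
            if node.is_leaf:
                if not node.gene_id:
                    raise StructureError("leaf without gene id")
                if not node.species:
                    raise StructureError(
                        f"leaf {node.gene_id!r} has no species label"
                    )
                if node.children:
                    raise StructureError("leaf with children")
            else:
                if node.event not in EVENTS:
                    raise StructureError(
                        f"internal node {node.node_id} has invalid event "
                        f"{node.event!r}"
                    )
                if len(node.children) < 2:
                    raise StructureError(
                        f"internal node {node.node_id} has "
                        f"{len(node.children)} child(ren); need >= 2"
                    )
            if node.branch_length < 0:
                raise StructureError("negative branch length")

    def preorder(self):
        return self.root.preorder()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_index)

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]


# -- Newick/NHX I/O ----------------------------------------------------------


def parse_tree(newick: str, family_id: str = "FAM") -> FamilyTree:
    """Parse a Newick/NHX string into a validated :class:`FamilyTree`.

    NHX keys: ``Ev`` in {S, D, H} on internal nodes (required), ``Sp`` species
    on leaves (falls back to the ``_species`` suffix of the leaf name).
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed Newick: {exc}") from exc

    def annotation(dnode, key):
        for ann in dnode.annotations:
            if ann.name == key:
                return str(ann.value)
        return None

    def convert(dnode) -> TreeNode:
        length = float(dnode.edge.length or 0.0)
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise StructureError("leaf without a name")
            gene_id = dnode.taxon.label
            species = annotation(dnode, "Sp")
            if species is None and "_" in gene_id:
                species = gene_id.rsplit("_", 1)[1]
            return TreeNode(
                event=LEAF,
                gene_id=gene_id,
                species=species,
                branch_length=length,
            )
        code = annotation(dnode, "Ev")
        if code is None:
            raise StructureError("internal node without an Ev event tag")
        if code not in _EVENT_CODE:
            raise StructureError(f"unknown event code {code!r}")
        return TreeNode(
            event=_EVENT_CODE[code],
            branch_length=length,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    root = dtree.seed_node
    # unwrap unary wrapper nodes that Newick's outermost parentheses create
    while len(root.child_nodes()) == 1:
        root = root.child_nodes()[0]
    return FamilyTree(root=convert(root), family_id=family_id)


def _format_length(x: float) -> str:
    return repr(float(x))


def write_tree(tree: FamilyTree) -> str:
    """Serialize to Newick with NHX tags; parse(write(t)) reproduces t."""

    def emit(node: TreeNode) -> str:
        if node.is_leaf:
            return (
                f"{node.gene_id}:{_format_length(node.branch_length)}"
                f"[&&NHX:Sp={node.species}]"
            )
        inner = ",".join(emit(c) for c in node.children)
        return (
            f"({inner}):{_format_length(node.branch_length)}"
            f"[&&NHX:Ev={_CODE_EVENT[node.event]}]"
        )

    return emit(tree.root) + ";"


# -- subfamilies -------------------------------------------------------------


@dataclass
class SubfamilyAssignment:
    """Partition of the leaves into subfamilies, with founding nodes."""

    leaf_to_subfamily: dict[str, str]
    founders: dict[str, int]  # subfamily label -> founding node_id

    @property
    def n_subfamilies(self) -> int:
        return len(self.founders)


def _mean_depth(node: TreeNode) -> float:
    """Mean summed branch length from above ``node`` down to its leaves."""
    total, count = _depth_sums(node, node.branch_length)
    return total / count


def _depth_sums(node: TreeNode, acc: float) -> tuple[float, int]:
    if node.is_leaf:
        return acc, 1
    total, count = 0.0, 0
    for child in node.children:
        t, c = _depth_sums(child, acc + child.branch_length)
        total += t
        count += c
    return total, count


def _first_gene(node: TreeNode) -> str:
    return min(leaf.gene_id for leaf in node.leaves())


def assign_subfamilies(
    tree: FamilyTree, reference_species: set[str]
) -> SubfamilyAssignment:
    """Partition leaves into subfamilies at duplication nodes.

    At each duplication node (pre-order), the least diverged child subtree —
    smallest mean root-to-leaf path length measured from the duplication
    node — keeps the parent subfamily; every other child founds a new one.
    A duplication whose entire clade belongs to one reference species is
    treated as recent and creates no subfamily.  Ties on mean depth are
    broken by the lexicographically smallest leading gene id keeping the
    parent label.
    """
    if not reference_species:
        raise StructureError("reference_species must be non-empty")
    labels: dict[str, str] = {}
    founders: dict[str, int] = {"SF0": tree.root.node_id}
    counter = itertools.count(1)

    def walk(node: TreeNode, label: str) -> None:
        if node.is_leaf:
            labels[node.gene_id] = label
            return
        if node.event == "duplication":
            species_below = {leaf.species for leaf in node.leaves()}
            if len(species_below) == 1 and species_below <= reference_species:
                for child in node.children:
                    walk(child, label)
                return
            keeper = min(
                node.children,
                key=lambda c: (_mean_depth(c), _first_gene(c)),
            )
            for child in node.children:
                if child is keeper:
                    walk(child, label)
                else:
                    new_label = f"SF{next(counter)}"
                    founders[new_label] = child.node_id
                    walk(child, new_label)
        else:
            for child in node.children:
                walk(child, label)

    walk(tree.root, "SF0")
    return SubfamilyAssignment(leaf_to_subfamily=labels, founders=founders)


# -- orthologs ---------------------------------------------------------------


def infer_orthologs(tree: FamilyTree) -> set[frozenset[str]]:
    """Pairs of genes whose LCA is a speciation node, across species.

    Returned as a set of 2-element frozensets.  Horizontal-transfer and
    duplication LCAs never yield ortholog pairs, nor do same-species pairs.
    """
    pairs: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> list[TreeNode]:
        if node.is_leaf:
            return [node]
        child_leaves = [walk(c) for c in node.children]
        if node.event == "speciation":
            for la, lb in itertools.combinations(child_leaves, 2):
                for x in la:
                    for y in lb:
                        if x.species != y.species:
                            pairs.add(frozenset((x.gene_id, y.gene_id)))
        return [leaf for grp in child_leaves for leaf in grp]

    walk(tree.root)
    return pairs
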