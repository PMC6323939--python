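"""Deterministic synthetic-data generators.

Every generator is a pure function of its arguments (including ``seed``):
the same call produces byte-identical objects and files, and every generated
object satisfies the invariants of its target type (DAGs are acyclic with
one root per aspect, planted event sets always validate, split alignments
realise the requested column geometry exactly).  The generators target the
structural properties the library operates on, not realistic sequence
evolution.
"""

from __future__ import annotations

import numpy as np

from .annotation import AnnotationSet, BranchEventSet
from .errors import InputError
from .ontology import ASPECTS, OntologyGraph, TermRecord
from .phylo import FamilyTree, TreeNode

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# -- ontology DAGs -------------------------------------------------------------


def make_dag(
    n_terms: int,
    seed: int,
    aspects: tuple[str, ...] = (ASPECTS[0],),
    part_of_prob: float = 0.2,
    extra_parent_prob: float = 0.3,
) -> OntologyGraph:
    """Random ontology DAG: one root per aspect, edges only from a higher to
    a lower topological index, so acyclicity holds by construction."""
    if n_terms < 1:
        raise InputError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    terms: list[TermRecord] = []
    edges: set[tuple[str, str, str]] = set()
    per_aspect = [n_terms // len(aspects)] * len(aspects)
    per_aspect[0] += n_terms - sum(per_aspect)
    tid = 0
    for aspect, count in zip(aspects, per_aspect):
        ids = []
        for i in range(count):
            term_id = f"GO:{tid:07d}"
            tid += 1
            ids.append(term_id)
            terms.append(
                TermRecord(term_id=term_id, name=f"synthetic term {tid}", aspect=aspect)
            )
            if i == 0:
                continue  # aspect root
            n_parents = 1 + int(rng.random() < extra_parent_prob and i >= 2)
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            for p in np.atleast_1d(parents):
                rel = "part_of" if rng.random() < part_of_prob else "is_a"
                edges.add((term_id, ids[int(p)], rel))
    return OntologyGraph.from_parts(terms, edges)


# -- event-labeled family trees -------------------------------------------------


def make_tree(
    n_leaves: int,
    seed: int,
    dup_prob: float = 0.3,
    n_species: int | None = None,
    family_id: str = "FAM00001",
) -> FamilyTree:
    """Random binary event-labeled tree with random species on the leaves."""
    if n_leaves < 2:
        raise InputError("n_leaves must be >= 2")
    rng = np.random.default_rng(seed)
    n_species = n_species or max(2, n_leaves // 2)
    species = [f"sp{j:02d}" for j in range(n_species)]
    nodes: list[TreeNode] = [
        TreeNode(
            event="leaf",
            gene_id=f"{family_id}G{i:03d}",
            species=species[int(rng.integers(n_species))],
            branch_length=round(float(rng.uniform(0.05, 1.0)), 6),
        )
        for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        event = "duplication" if rng.random() < dup_prob else "speciation"
        nodes.append(
            TreeNode(
                event=event,
                branch_length=round(float(rng.uniform(0.05, 1.0)), 6),
                children=[left, right],
            )
        )
    nodes[0].branch_length = 0.0
    return FamilyTree(root=nodes[0], family_id=family_id)


def make_family(
    n_leaves: int,
    dup_prob: float,
    gain_rate: float,
    loss_rate: float,
    graph: OntologyGraph,
    seed: int,
    family_id: str = "FAM00001",
    max_terms: int = 10,
) -> tuple[FamilyTree, BranchEventSet]:
    """Random tree plus a planted, always-valid gain/loss event set.

    Each candidate term receives, with probability ``gain_rate``, one gain on
    a uniformly random branch; every branch strictly below a gain then loses
    the term independently with probability ``loss_rate``.  By construction
    every loss lies below a gain, so ``validate_events`` returns no
    violations.
    """
    rng = np.random.default_rng(seed)
    tree = make_tree(
        n_leaves,
        seed=int(rng.integers(2**31)),
        dup_prob=dup_prob,
        family_id=family_id,
    )
    pool = sorted(t for t, rec in graph.terms.items() if not rec.obsolete)
    picks = rng.choice(len(pool), size=min(max_terms, len(pool)), replace=False)
    candidates = [pool[int(i)] for i in sorted(picks)]
    events = BranchEventSet()
    node_ids = sorted(tree.nodes_by_id)
    for term in candidates:
        if rng.random() >= gain_rate:
            continue
        gain_node = int(rng.choice(node_ids))
        events.add(gain_node, term, "gain")
        below = [
            n.node_id
            for n in tree.nodes_by_id[gain_node].preorder()
            if n.node_id != gain_node
        ]
        for node_id in below:
            if rng.random() < loss_rate:
                events.add(node_id, term, "loss")
    return tree, events


# -- split alignments -----------------------------------------------------------


def _clade(
    member_ids: list[str], species_prefix: str, branch_length: float = 0.1
) -> TreeNode:
    """Caterpillar clade of speciation nodes, one species per leaf."""
    leaves = [
        TreeNode(
            event="leaf",
            gene_id=m,
            species=f"{species_prefix}{i:02d}",
            branch_length=branch_length,
        )
        for i, m in enumerate(member_ids)
    ]
    node = leaves[0]
    for leaf in leaves[1:]:
        node = TreeNode(
            event="speciation", branch_length=branch_length, children=[node, leaf]
        )
    return node


def make_split_msa(
    n_members_a: int,
    n_members_b: int,
    width_a: int,
    width_b: int,
    overlap: int,
    seed: int,
    family_id: str = "FAM00001",
) -> tuple["MultipleAlignment", FamilyTree]:
    """Block alignment of two clades overlapping in ``overlap`` columns.

    Clade A occupies columns [0, width_a); clade B occupies
    [width_a - overlap, width_a + width_b - overlap).  The returned tree is
    two speciation caterpillars joined at the root, so its A|B split is an
    internal-edge bipartition.
    """
    from .familyqc import MultipleAlignment  # local import avoids a cycle

    if min(width_a, width_b) < 1 or overlap > min(width_a, width_b):
        raise InputError("invalid block geometry")
    if min(n_members_a, n_members_b) < 2:
        raise InputError("each clade needs >= 2 members")
    rng = np.random.default_rng(seed)
    width = width_a + width_b - overlap
    ids_a = [f"{family_id}A{i:03d}" for i in range(n_members_a)]
    ids_b = [f"{family_id}B{i:03d}" for i in range(n_members_b)]

    def block_row(start: int, stop: int) -> str:
        body = "".join(
            AMINO_ACIDS[int(c)]
            for c in rng.integers(len(AMINO_ACIDS), size=stop - start)
        )
        return GAP_FILL(start) + body + GAP_FILL(width - stop)

    def GAP_FILL(n: int) -> str:
        return "-" * n

    rows = [(m, block_row(0, width_a)) for m in ids_a]
    rows += [(m, block_row(width_a - overlap, width)) for m in ids_b]
    msa = MultipleAlignment.from_rows(rows)
    root = TreeNode(
        event="speciation",
        branch_length=0.0,
        children=[_clade(ids_a, "spA"), _clade(ids_b, "spB")],
    )
    tree = FamilyTree(root=root, family_id=family_id)
    return msa, tree


# -- annotations and enriched gene lists ----------------------------------------


def make_annotations(
    n_genes: int,
    graph: OntologyGraph,
    seed: int,
    terms_per_gene: int = 2,
    evidence: str = "IEA",
) -> AnnotationSet:
    """Annotate each gene to a few random non-root, non-obsolete terms."""
    rng = np.random.default_rng(seed)
    roots = set(graph.roots.values())
    pool = sorted(
        t for t, rec in graph.terms.items()
        if not rec.obsolete and t not in roots
    )
    if not pool:
        raise InputError("ontology has no annotatable terms")
    out = AnnotationSet()
    for i in range(n_genes):
        gene = f"GENE{i:05d}"
        n_terms = min(len(pool), 1 + int(rng.integers(terms_per_gene)))
        for t in rng.choice(len(pool), size=n_terms, replace=False):
            out.add(gene, pool[int(t)], evidence)
    return out


def make_enriched_lists(
    annotations: AnnotationSet,
    target_term: str,
    effect: float,
    seed: int,
    list_size: int | None = None,
) -> tuple[set[str], set[str]]:
    """Gene list oversampling the genes of ``target_term`` by ``effect``.

    Weighted sampling without replacement (Efraimidis-Spirakis keys), so
    effect=1 is the null and larger effects enrich the target class.
    The reference is all annotated genes, unchanged.
    """
    if effect <= 0:
        raise InputError("effect must be positive")
    reference = sorted(annotations.genes())
    target_genes = annotations.by_term().get(target_term, set())
    if len(target_genes) < 5:
        raise InputError(
            f"target term {target_term!r} annotates "
            f"{len(target_genes)} genes; need >= 5"
        )
    rng = np.random.default_rng(seed)
    list_size = list_size or max(5, len(reference) // 10)
    weights = np.array(
        [effect if g in target_genes else 1.0 for g in reference]
    )
    keys = rng.random(len(reference)) ** (1.0 / weights)
    chosen = np.argsort(keys)[::-1][:list_size]
    return {reference[int(i)] for i in chosen}, set(reference)
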