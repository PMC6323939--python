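"""Independent brute-force oracles used to check the library implementations.

Each oracle recomputes a quantity by the most direct method available
(repeated edge expansion, per-leaf path scans, all-pairs LCA, exhaustive
enumeration) and deliberately shares no code path with the implementation it
checks.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict


# -- ontology ----------------------------------------------------------------


def reachable_by_expansion(edges: set[tuple[str, str, str]], start: str) -> set[str]:
    """Transitive closure child->parent via repeated edge expansion."""
    parents = defaultdict(set)
    for child, parent, _rel in edges:
        parents[child].add(parent)
    out: set[str] = set()
    frontier = {start}
    while frontier:
        nxt = set()
        for t in frontier:
            for p in parents[t]:
                if p not in out:
                    out.add(p)
                    nxt.add(p)
        frontier = nxt
    return out


def descendants_by_expansion(edges: set[tuple[str, str, str]], start: str) -> set[str]:
    flipped = {(p, c, r) for c, p, r in edges}
    return reachable_by_expansion(flipped, start)


# -- trees -------------------------------------------------------------------


def parent_map(tree) -> dict[int, int | None]:
    parents: dict[int, int | None] = {tree.root.node_id: None}
    for node in tree.preorder():
        for child in node.children:
            parents[child.node_id] = node.node_id
    return parents


def root_path(tree, node_id: int) -> list[int]:
    """Node ids from the root down to node_id, inclusive."""
    parents = parent_map(tree)
    path = [node_id]
    while parents[path[-1]] is not None:
        path.append(parents[path[-1]])
    return list(reversed(path))


def lca(tree, node_a: int, node_b: int) -> int:
    pa, pb = root_path(tree, node_a), root_path(tree, node_b)
    last = pa[0]
    for x, y in zip(pa, pb):
        if x != y:
            break
        last = x
    return last


def orthologs_all_pairs(tree) -> set[frozenset[str]]:
    """All-pairs LCA-event check: O(n^2) path-based ortholog oracle."""
    pairs: set[frozenset[str]] = set()
    leaves = list(tree.leaf_index.values())
    for a, b in itertools.combinations(leaves, 2):
        anc = tree.nodes_by_id[lca(tree, a.node_id, b.node_id)]
        if anc.event == "speciation" and a.species != b.species:
            pairs.add(frozenset((a.gene_id, b.gene_id)))
    return pairs


def propagate_path_scan(tree, events) -> set[tuple[str, str]]:
    """Per-leaf root-to-leaf scan: the nearest event for a term decides.

    Returns (gene_id, term_id) pairs.
    """
    by_node = defaultdict(list)
    for ev in events:
        by_node[ev.node_id].append(ev)
    out = set()
    terms = {ev.term_id for ev in events}
    for gene_id, leaf in tree.leaf_index.items():
        path = root_path(tree, leaf.node_id)
        for term in terms:
            state = None
            for node_id in path:
                for ev in by_node[node_id]:
                    if ev.term_id == term:
                        state = ev.kind
            if state == "gain":
                out.add((gene_id, term))
    return out


# -- slim --------------------------------------------------------------------


def usage_counts_double_loop(families, graph_edges) -> dict[str, int]:
    """Branch-usage oracle: loop over every (branch, term) pair directly."""
    branches = set()
    gains_by_branch = defaultdict(set)
    for tree, events in families:
        for ev in events:
            if ev.kind == "gain":
                branch = (tree.family_id, ev.node_id)
                branches.add(branch)
                gains_by_branch[branch].add(ev.term_id)
    all_terms = {t for terms in gains_by_branch.values() for t in terms}
    closure_terms = set(all_terms)
    for t in all_terms:
        closure_terms |= reachable_by_expansion(graph_edges, t)
    counts = {}
    for term in closure_terms:
        below = descendants_by_expansion(graph_edges, term) | {term}
        n = sum(1 for b in branches if gains_by_branch[b] & below)
        if n:
            counts[term] = n
    return counts


def slim_membership_two_rules(
    counts: dict[str, int],
    graph_edges: set[tuple[str, str, str]],
    all_terms: set[str],
    roots: set[str],
    min_branches: int,
) -> set[str]:
    """Direct evaluation of the two slim rules on raw edge sets."""
    step1 = {t for t in all_terms if counts.get(t, 0) > min_branches}
    step2 = set()
    for t in all_terms:
        below = descendants_by_expansion(graph_edges, t)
        if len(below & step1) >= 2:
            step2.add(t)
    return step1 | step2 | roots


def most_specific_slim_ancestors(
    term: str,
    slim_terms: set[str],
    graph_edges: set[tuple[str, str, str]],
    aspect_root: str,
) -> set[str]:
    if term in slim_terms:
        return {term}
    candidates = reachable_by_expansion(graph_edges, term) & slim_terms
    if not candidates:
        return {aspect_root}
    return {
        c for c in candidates
        if not (descendants_by_expansion(graph_edges, c) & candidates)
    }


# -- statistics ---------------------------------------------------------------


def fisher_enumeration(k: int, n: int, K: int, N: int, alternative: str) -> float:
    """Hypergeometric tail by direct enumeration with math.comb."""
    kmin, kmax = max(0, n + K - N), min(n, K)
    pmf = {
        kk: math.comb(K, kk) * math.comb(N - K, n - kk)
        for kk in range(kmin, kmax + 1)
    }
    total = sum(pmf.values())
    if alternative == "greater":
        num = sum(v for kk, v in pmf.items() if kk >= k)
    elif alternative == "less":
        num = sum(v for kk, v in pmf.items() if kk <= k)
    else:
        num = sum(v for v in pmf.values() if v <= pmf[k])
    return num / total


def mwu_pairwise_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney via pairwise-comparison counting over all
    label assignments (independent of rank arithmetic)."""

    def u_of(sample, rest):
        u = 0.0
        for a in sample:
            for b in rest:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    pooled = list(x) + list(y)
    nx = len(x)
    mu = nx * len(y) / 2.0
    u_obs = u_of(list(x), list(y))
    dev = abs(u_obs - mu)
    hits = total = 0
    for pos in itertools.combinations(range(len(pooled)), nx):
        sample = [pooled[i] for i in pos]
        rest = [pooled[i] for i in range(len(pooled)) if i not in pos]
        if abs(u_of(sample, rest) - mu) >= dev - 1e-9:
            hits += 1
        total += 1
    return u_obs, hits / total
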