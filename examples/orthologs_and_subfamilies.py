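"""Infer pairwise orthologs and subfamilies from an event-labeled tree.

Orthologs are cross-species gene pairs whose lowest common ancestor is a
speciation node.  Subfamilies are founded at duplication nodes: the more
diverged duplicate (larger mean branch-length to its leaves) starts a new
subfamily, while a recent duplication confined to one reference species
does not.
"""

from phylogo.phylo import assign_subfamilies, infer_orthologs, parse_tree

tree = parse_tree(
    "(((kcnA1_human:0.1,kcnA1_mouse:0.1):0.1[&&NHX:Ev=S],"
    "(kcnA2_human:0.6,kcnA2_mouse:0.7):0.5[&&NHX:Ev=S])"
    ":0.2[&&NHX:Ev=D]);",
    family_id="KCNA",
)

pairs = sorted(tuple(sorted(p)) for p in infer_orthologs(tree))
print(f"ortholog pairs ({len(pairs)}):")
for a, b in pairs:
    print(f"  {a} <-> {b}")
print("paralog pairs created by the duplication (e.g. kcnA1 vs kcnA2 in the")
print("same species) are excluded: their LCA is the duplication node.")

assignment = assign_subfamilies(tree, reference_species={"human", "mouse"})
print(f"\nsubfamilies ({assignment.n_subfamilies}):")
for gene, sf in sorted(assignment.leaf_to_subfamily.items()):
    print(f"  {gene}\t{sf}")
print("the kcnA2 clade is more diverged (longer branches), so it founds the")
print("new subfamily; kcnA1 keeps the parent label SF0.")
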