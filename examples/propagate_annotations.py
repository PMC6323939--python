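"""Propagate curated gain/loss events down a gene family tree (IBA).

A function gained on an ancestral branch is inherited by every descendant
gene except in lineages where a curator recorded a loss; propagated
annotations carry the IBA evidence code.
"""

from phylogo.annotation import BranchEventSet, propagate
from phylogo.phylo import parse_tree

tree = parse_tree(
    "(((hbb_human:0.1,hbb_mouse:0.12):0.2[&&NHX:Ev=S],"
    "(hbb_chick:0.3,hbb_frog:0.35):0.25[&&NHX:Ev=S]):0.0[&&NHX:Ev=S]);",
    family_id="GLOBIN",
)

events = BranchEventSet()
events.add(tree.root.node_id, "GO:0005344", "gain")  # oxygen transport, at root
amniote_clade = tree.root.children[1]
events.add(amniote_clade.node_id, "GO:0005344", "loss")  # lost in one clade

annotations = propagate(tree, events)
print("leaf annotations after propagation (gene, term, evidence):")
for rec in sorted(annotations):
    print(f"  {rec.gene_id}\t{rec.term_id}\t{rec.evidence}")
print("the two leaves under the loss branch are unannotated: the nearest")
print("event on their root-to-leaf path is the loss, not the root gain.")
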