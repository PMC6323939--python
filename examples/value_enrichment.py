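"""Value-based enrichment: Mann-Whitney U of class values vs all genes.

Assigns every gene a numeric value (think log fold-change); genes of one
class are drawn from a shifted distribution.  Each class's values are
compared to the distribution for all genes with the Mann-Whitney U test,
BH-FDR corrected.
"""

import numpy as np

from phylogo.enrich import run_enrichment
from phylogo.fixtures import make_annotations, make_dag

graph = make_dag(30, seed=5)
annotations = make_annotations(200, graph, seed=6)
by_term = annotations.by_term()
target = max(by_term, key=lambda t: len(by_term[t]))

rng = np.random.default_rng(7)
values = {
    gene: float(rng.normal(2.0 if gene in by_term[target] else 0.0))
    for gene in annotations.genes()
}

results = run_enrichment(values, annotations, graph, correction="fdr")

print(f"shifted class: {target} ({len(by_term[target])} genes, +2.0 shift)\n")
print("term            genes  class mean / overall   raw p      FDR q")
for r in results[:5]:
    print(f"{r.term_id}  {r.k:5d}  {r.fold_enrichment:19.2f}  "
          f"{r.p_raw:9.3g}  {r.p_adjusted:9.3g}")
print("\nthe shifted class has the smallest adjusted p; classes drawn from")
print("the background distribution stay near p = 1.")
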