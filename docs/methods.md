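# Methods

This note records the models and conventions phylogo implements, the
parameters that matter, the design choices made where more than one
reasonable convention exists, and what the synthetic-data generators do and
do not emulate.

## Ontology model

The ontology is a DAG of terms connected by `is_a` and `part_of` edges
(stored child → parent, so traversal moves toward the root). All closure
operations — ancestor/descendant queries, annotation closure, slim counting
— follow both relation types and nothing else; any other relationship found
in an OBO document (`regulates`, `occurs_in`, …) is dropped at parse time
with a warning, because closure semantics over those relations are not
sound for counting.

Structural invariants enforced at construction: acyclicity; unique term
ids; one root per aspect (a term with no outgoing relation edges); no edge
between terms of different aspects; obsolete terms kept as isolated records
(so annotations referencing them fail loudly) but banned from edges.
Cross-aspect `part_of` edges, which have existed historically between
cellular-component and biological-process terms, are deliberately rejected:
aspect-homogeneous graphs make per-aspect corrections and root-traceability
unambiguous.

The OBO writer sorts stanzas by term id and relations lexicographically, so
identical graphs serialize to identical bytes and parse→write→parse is the
identity.

## Event-labeled trees, subfamilies, orthologs

Family trees are rooted; internal nodes carry an event label — speciation,
duplication, or horizontal transfer — from NHX `Ev` tags (`S`/`D`/`H`);
leaves carry a gene id and a species label (NHX `Sp` tag, falling back to
the suffix after the last underscore of the leaf name). The branch length
stored on a node is the length of the edge above it.

**Subfamilies.** The root founds subfamily `SF0`. At each duplication node,
in pre-order: if every leaf below belongs to a single species and that
species is a designated reference species, the duplication is treated as
recent and creates nothing; otherwise the child subtree with the *smallest*
mean path length from the duplication node to its leaves (summed branch
lengths, averaged over leaves) continues the parent subfamily, and every
other child founds a new one — the more diverged duplicate starts the new
subfamily. Mean depth is the divergence proxy; ties break to the subtree
whose lexicographically smallest gene id keeps the parent label, making the
assignment deterministic.

**Orthologs.** A pair of genes is orthologous iff the lowest common
ancestor of their leaves is a speciation node and the two genes are from
different species. Duplication LCAs give paralogs (excluded);
horizontal-transfer LCAs are excluded too, since ortholog semantics across
transfers are not well defined; same-species pairs under a speciation LCA
(possible with unsampled lineages) are excluded because orthology here is a
cross-species relation. The implementation aggregates cross-child pairs at
each speciation node; tests compare it against an all-pairs LCA oracle.

## Gain/loss events and propagation

An event set attaches `(node, term, gain|loss)` assertions to a tree. The
coordinate convention: an event sits on the branch *above* its node and
takes effect for that node and all descendants. A valid event set has at
most one event per (node, term) and every loss strictly below a gain of the
same term on the same root path; `validate_events` reports violations as
data rather than raising, so curation pipelines can triage them.

Propagation is nearest-event-wins: a leaf is annotated with a term
(evidence code IBA) iff the closest event for that term on its root-to-leaf
path is a gain. A re-gain below a loss therefore re-activates the term for
that clade — the simplest consistent layering of gains and losses, and the
convention this library commits to. Consequences: adding a gain can never
remove a leaf annotation, adding a loss can never create one; both
monotonicity properties are tested.

GAF rows with a `NOT` qualifier never enter positive annotation sets; they
are retained in a separate negated store for audit and take no part in
propagation or counting.

## Slim construction

Branch usage is counted per term as the number of distinct (family, node)
pairs carrying a gain of the term *or any of its descendants*; a branch
gaining several descendants of a term still counts once for it, and losses
never count. This makes `count(ancestor) ≥ count(descendant)` an invariant,
asserted on every table.

The slim is then: (1) every term used on strictly more than `min_branches`
branches (default 5 — the published cutoff is "more than five", so a count
of exactly 5 does not qualify); (2) every term with at least two step-1
terms among its descendants. Rule 2 is implemented as "≥ 2 selected
descendants" rather than only pairwise LCAs because this reading alone also
guarantees that every slim term reaches its aspect root inside the slim,
with no separate repair step; root-connectivity is asserted on every build
anyway, and aspect roots are always included. Provenance
(`selected_by_count` / `added_as_ancestor` / `root`) is recorded per term.
Note a consequence of closure counting: when the count table itself is
closure-coherent (count(ancestor) ≥ count(descendant), as every table this
library produces is), any ancestor of a step-1 term exceeds the threshold
too, so rule 2 adds nothing — it does real work only for externally
supplied count tables that were counted without closure.

Slim edges are the transitive reduction of source-graph reachability
restricted to slim terms, keeping the slim a minimal DAG; an edge is
labeled `is_a` when its endpoints are connected by an is_a-only path in the
source graph, `part_of` otherwise. Mapping full-ontology annotations onto a
slim replaces each term by its *most specific* slim ancestors (the minimal
elements of the slim ancestors; a term already in the slim maps to itself;
a term with no slim ancestor maps to its aspect root).

## Family-boundary diagnostics

The "core" of an alignment is the set of columns with non-gap occupancy of
at least 0.5. The occupancy threshold is a configurable stand-in for the
trimming recipe behind published core alignments, which is not specified in
enough detail to reproduce; 50% column occupancy is the standard choice.

The four criteria, with their comparisons exactly as stated by the
thresholds they implement:

- **E1** — a member "does not align to the core" when it has residues in
  fewer than 30 core columns; flag when the fraction of such members is
  strictly greater than 0.5.
- **E2** — flag when the core is shorter than 100 columns *and* the total
  width is at least 4× the core.
- **P1** — flag when at least 10% of members each have residues in fewer
  than 30 core columns. Counting against core columns (rather than raw
  columns) avoids crediting residues in junk columns; raw-column counting
  is available as an option.
- **P2** — for every internal edge, split the leaves into the two induced
  subtrees; a column is shared when at least 50% of the members on *each*
  side have a residue there; flag when any split shares fewer than 30
  columns. Splits are edge-induced bipartitions; on a tree with no internal
  edge no split exists, the reported worst-split count equals the alignment
  width, and the criterion cannot fire.

The 30-column floor in E1 reuses the floor printed for P1/P2, for internal
consistency; all floors and fractions are keyword arguments. A family's
report carries the union of fired flags plus the underlying measurements,
so a family flagged by several criteria is still one flagged family.

Forward-tracking after re-clustering maps each old family id to the new
cluster containing the largest number of its former members (ties to the
lexicographically smallest cluster id); clusters receiving no old id get
fresh identifiers, and old families with no surviving members are retired.

## Enrichment statistics

**Fisher.** Tail probabilities are computed in exact integer arithmetic:
the hypergeometric weights C(K,k)·C(N−K,n−k) are generated by an integer
recurrence over the support and tails are ratios of integer sums, converted
to float once at the end. This makes the p-values exact to one floating-
point rounding — the all-tables enumeration check in the acceptance suite
measures a maximum absolute difference of 0.0 — and costs O(support) big-
integer operations per table, which stays comfortably fast at reference
sizes in the tens of thousands. The two-sided p-value uses the
point-probability rule (sum over outcomes with weight ≤ the observed
weight, an exact integer comparison). The default alternative is two-sided,
with an over/under direction label per class (k ≥ nK/N ⇒ over): the test
reports both over- and underrepresentation.

**Binomial** (legacy option): exact binomial tails at p₀ = K/N via
`scipy.stats.binomtest`.

**Mann–Whitney.** Class values are compared against the distribution for
*all* genes — including the class members — taking the published
description of the comparison literally, not class-vs-complement. U uses
midranks for ties. For combined sample sizes up to 20 the two-sided p is
exact by enumerating all label assignments (deviation |U − nm/2| with a
1e-9 float guard); beyond that, the normal approximation with tie and
continuity corrections. If all pooled values are identical, p = 1. The
crossover at 20 keeps the exact path at ≤ C(20,10) ≈ 1.8e5 enumerations,
and at that size the approximation agrees with exact to < 0.01.

**Corrections.** BH step-up (default) and Bonferroni, applied across all
tested terms *within one ontology aspect* — the correction universe is a
convention, made explicit and configurable here; the unclassified
pseudo-class forms its own group. The step-up multiplies by the factor
m/rank rather than computing p·m/rank, so `adjusted ≥ raw` holds exactly in
floating point.

**Drivers.** The overrepresentation driver closure-expands annotations over
the ontology before counting, tests every class with at least one annotated
reference gene, pools unannotated genes into an `UNCLASSIFIED`
pseudo-class, and errors on list genes missing from the reference unless
explicitly told to coerce them (silent coercion hides upload mistakes). The
value-based driver skips classes with fewer than 2 valued genes (logged)
and reports class-mean/overall-mean as its effect measure. Results are
sorted by adjusted p, then raw p, then term id — fully deterministic.

## Synthetic data

The generators are pure functions of their arguments including the seed;
identical calls give byte-identical files. They emulate the *structural*
conditions the algorithms operate on:

- `make_dag` — one aspect root, edges only from higher to lower topological
  index (acyclic by construction), ~30% of terms with a second parent, 20%
  `part_of` edges.
- `make_family` — random binary join trees; internal nodes are duplications
  with probability 0.3 by default; each candidate term gains on one uniform
  random branch with probability `gain_rate`, and each branch below a gain
  loses the term with probability `loss_rate`, so planted event sets are
  valid by construction.
- `make_split_msa` — two clades occupying column blocks with a controlled
  overlap, realizing exact shared-site counts for the P2 boundary sweep.
- `make_enriched_lists` — weighted sampling without replacement
  (Efraimidis–Spirakis keys) oversampling a target class by a chosen
  effect; effect 1 is the null.

They do **not** emulate realistic sequence evolution, branch-length
heterogeneity, annotation bias, or the correlation structure of real GO
annotations. Passing tests therefore demonstrate algorithmic correctness
against the stated rules and calibration under idealized nulls — not
performance on any real corpus.

Problem sizes used by the acceptance script (chosen to exercise each
property at meaningful scale): all 2×2 tables to N = 30 for the Fisher
enumeration; 1000 simulated terms at reference size 20 000 and list size
2000 for null calibration (margins large enough that the exact test's
discrete conservatism is negligible; small-margin tables are intrinsically
conservative); 100 replicates of 200 terms with 20% planted signal for the
FDR simulation (with genuine signals present the false-discovery proportion
is well defined per replicate, and BH's FDR ≤ π₀·q guarantee leaves
margin); 200 propagation fixtures and 60 ortholog trees up to 64 leaves;
100 slim DAGs; a 300-family pipeline for the end-to-end slim build.

## Known limitations

- "More highly diverged" uses mean branch-length depth, not a sequence
  divergence measure; with unusual rate heterogeneity the two can disagree.
- The recent-duplication exception requires *all* leaves below the
  duplication to be one reference species; a duplication with one
  additional unsampled lineage is not exempted.
- The core-alignment definition is occupancy trimming, a declared stand-in
  for unpublished trimming recipes.
- Re-gain after loss is permitted (nearest-event-wins); curation pipelines
  that forbid it should reject such event sets upstream.
- The slim's relation edges are transitively reduced; a published slim may
  retain redundant edges, so edge sets (not memberships) can differ.
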