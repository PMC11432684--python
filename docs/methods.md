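# Methods

## Model and procedure

`ncaxis` operates on an undirected, typed tripartite graph. Node types are
*seed* (a curated gene or protein biomarker; mRNA and protein identifiers
are deliberately one class, since interaction databases report both as
targets), *miRNA*, and *lncRNA*. Only three edge types can exist —
seed–miRNA, seed–lncRNA, miRNA–lncRNA — mirroring the three interaction
modes of the ceRNA model: miRNAs repress mRNAs, lncRNAs sponge miRNAs, and
lncRNAs can also bind mRNAs directly. Every edge carries an
`evidence_count`, the number of database rows supporting the pair, so
redundant curation is collapsed but not lost.

### Axis construction

The two-step extraction is deliberately asymmetric. Step 1 keeps miRNAs
with direct seed evidence. Step 2 keeps lncRNAs that touch both a seed and
*any* miRNA — not only step-1 miRNAs. This reading is what allows
seed-independent miRNA neighborhoods of a seed-linked lncRNA to enter the
network (step 3 then pulls those miRNAs in), and it is the mechanism by
which the characteristic large "miRNA blocks" appear around hub lncRNAs
such as NEAT1 and MALAT1. The alternative reading (step-2 lncRNAs must
touch a *seed-linked* miRNA) would make seedless blocks impossible by
construction, contradicting the block phenomenon the workflow exists to
expose, so it was rejected.

A seed with no retained edge does not appear in the network; seeds that
match no row at all are reported in a warning rather than silently dropped.

### Occurrence threshold

`threshold_filter(network, k, mode, scope)` removes, in a single
simultaneous pass, every in-scope node whose occurrence count is below `k`
(k = 1 is the identity; "occurs three times or more" survives k = 3).
Two countable notions of "occurrence" exist in row-oriented interaction
databases, and the choice matters because curation is redundant:

* `degree` (default) — number of distinct neighbors; robust to the same
  pair being deposited by many experiments;
* `rows` — total supporting rows; closer to raw file "occurrences" and kept
  for sensitivity analysis.

The threshold scope defaults to ncRNA nodes only: the seed list is a
curated input, and seeds should leave the network through edge loss and
pruning rather than by thresholding the very markers the analyst chose.
Both choices are configurable (`occurrence_mode`, `threshold_scope`).

### Single-interactor pruning

One simultaneous pass removes every in-scope node with exactly one
neighbor, then removes any node left isolated. The default scope is seeds
only, single pass: repeated whole-network pruning to a fixed point would
dismantle the chain-like peripheries that the axis networks legitimately
retain. `scope="all_nodes"` and `fixed_point=True` are available, and the
fixed-point variant is idempotent.

The pipeline order is pinned: organism/evidence scoping at read time →
`build_axis` → `threshold_filter` → `prune_single_interactors`. The order
is recorded in every run manifest.

### miRNA blocks and governed genes

A block is operationalized as a connected component of the bipartite
subgraph induced on lncRNA nodes and *seedless* miRNAs (miRNAs with zero
seed edges), containing at least `min_size` miRNAs (default 5 — small
enough to catch real blocks, large enough to ignore incidental seedless
pairs) and at least one governor. Components without any lncRNA are not
blocks: block membership is defined by shared governance, and every member
must be held by ≥ 1 governor. Governors are ranked by within-block degree.

`governed_genes` counts *distinct* block miRNAs per lncRNA (not rows) when
applying the ≥ `min_links` rule (default 2), then returns all mRNA/protein
partners of the qualifying lncRNAs. Raising `min_links` can only shrink
the result.

### State propagation

States are binary by design (`expressed`/`down` on lncRNAs, derived
`sponged`/`active` on miRNAs, `repressed`/`uninhibited` on genes):
quantitative expression modeling is explicitly out of scope, and the binary
closure is exactly the sponge logic — one expressed sponge suffices to
inhibit a miRNA, one active miRNA suffices to repress a gene. Unassigned
lncRNAs default to `expressed` (the null hypothesis of normal expression);
a miRNA with no lncRNA neighbor is `active`. The rules form a two-layer
monotone closure, so the result is independent of node iteration order.
Seed–lncRNA edges have no agreed propagation semantics (a direct
lncRNA→mRNA effect is neither repression-via-miRNA nor sponging), so they
are returned as `unresolved_edges` for the analyst instead of being folded
into either rule.

### Interactor expansion and enrichment

Expansion is plain first-degree adjacency over the organism-filtered
BioGRID tab3 table; self-pairs are retained in the table (flagged) but
contribute no new gene. Per-input-gene contributions are kept as
provenance.

The over-representation test is the right-tailed hypergeometric
probability, computed by `scipy.stats.hypergeom.sf`. Multiple-testing
correction is Holm's step-down procedure, implemented directly from the
recurrence (sort raw p ascending; adjusted = running max of
min(1, (m−rank+1)·p)), which is the "Bonferroni step-down" of the ClueGO
lineage of tools; the implementation is cross-checked against
`statsmodels` in the test suite. Defaults: alpha 0.05, `min_study_count`
2 (a term represented once in the study carries no loop information).

This is an emulation of a ClueGO-style analysis, not a port: kappa-score
term grouping, term fusion, and GO-level windows are out of scope. The
background population defaults to all annotated genes of the loaded GAF
(configurable); published ClueGO p-values are not exactly recoverable
because those run parameters and database versions are generally unstated,
so agreement with published values is treated as qualitative only.

Annotations are restricted to experimental evidence codes by default
(EXP, IDA, IPI, IMP, IGI, IEP plus the high-throughput HTP, HDA, HMP, HGI,
HEP); `NOT`-qualified rows are skipped; annotations to unknown or obsolete
terms are skipped with counts. Each direct annotation is propagated to all
ancestors via `is_a` and `part_of` (other relations ignored), and the
propagation invariant — a term's gene set is a subset of every ancestor's —
is checked in the test suite for every loaded annotation set.

## Identifier handling

Identifiers are stripped of surrounding whitespace and compared
case-folded, preserving first-seen casing for display. This unifies the
`hsa-miR-…`/`hsa-mir-…` spelling variants that real miRNA tables mix.
Composite names (e.g. `hsa-mir-19a/19b`) are carried as opaque
identifiers, not split.

## The synthetic data generator

`ncaxis.synth.generate_fixture` emulates the full input surface — an
NPInter-dialect TSV, a seed list, a BioGRID tab3 table, an OBO ontology, a
GAF 2.2 annotation file, and an expression-state file — as a pure function
of its config (one integer seed governs all randomness; identical configs
yield byte-identical files).

Default conditions: 30 seeds, 40 miRNAs, 15 lncRNAs, one planted block of
12 miRNAs on 2 governors (named NEAT1/MALAT1 to mirror the recurring
real-data hubs), 3 extra governed genes per block, background edge density
0.08, 5 wrong-organism decoy rows, 2 unrecognized-type decoy rows, a
200-gene annotation background with per-term annotation probability 0.05,
and one GO term planted at 8-fold enrichment on the seed set. These sizes
keep a planted block unambiguous at `min_size=5`, give the background
enough edges to exercise filtering without entangling the planted
structure, and put the planted term's expected study count (~12/30 vs
~10/200 background) far enough from the Holm threshold to be detectable
while leaving real statistical variation in place.

Planted guarantees, by construction: block miRNAs interact *only* with
their governors (never seeds), so they are seedless; governor j of a block
binds `size − j` members (strict degree ranking, every governor ≥ 2
members); each governor also gets one seed edge so it survives axis step 2;
background miRNAs each get a guaranteed seed edge so they can never form
spurious seedless blocks. Planted GO terms are kept as ontology leaves and
are never used as fallback "anchor" annotations — otherwise descendant or
anchor annotations would leak into the planted term's background count and
the configured fold would not be the fold actually present in the file.

What the fixtures do **not** mimic: the heavy-tailed degree distributions,
identifier vocabulary, tissue/evidence metadata, and scale of the real
NPInter/BioGRID/GO releases. Passing tests therefore demonstrate
correctness of the *rules* (parsing, construction, filtering, detection,
statistics) under controlled truth, not performance or biological findings
on real databases; real-data runs remain a separate reproduction exercise
requiring the corresponding downloads.

## Numerical and degeneracy choices

* Hypergeometric tails come from scipy (log-space internally); the test
  suite verifies them against exact integer enumeration for every instance
  with population ≤ 30 at 1e-12.
* Holm adjustment is exact arithmetic on floats; ties in raw p receive
  identical adjusted values, making the output order-invariant.
* Empty inputs degrade gracefully: header-only tables parse to empty
  tables, an empty study or block yields an empty result plus a warning,
  and malformed rows are counted-and-skipped, never fatal.
* Network exports sort nodes and edges, so outputs are byte-stable and
  re-import reconstructs an isomorphic network.
* Ontology loading rejects cyclic `is_a`/`part_of` graphs outright.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: 200 random instances
of ≤ 20 nodes for brute-force equivalence; fixture configurations with 1–3
planted blocks (sizes 6–12, 1–3 governors) for recovery; the exhaustive
hypergeometric sweep over all populations ≤ 30 (≈ 87k instances); 200
random p-vectors (m ≤ 30) for Holm; 50 generator seeds for the planted-term
Monte-Carlo rate; and a 17-node toy network for the expression-hypothesis
narrative. These sizes make every check exact or tightly bounded while the
whole suite runs in seconds.

## Known limitations

* Identifier matching is purely lexical; no cross-database identifier
  mapping (aliases, Ensembl/RefSeq ids) is attempted.
* Only two ncRNA layers are supported; other ncRNA classes are carried as
  `other` and excluded from axis construction.
* The sponge logic is qualitative; no interaction strengths, expression
  levels, or stoichiometry.
* ClueGO-style term grouping/fusion is not implemented; enrichment output
  is per-term.
* Whether the occurrence threshold should also apply to seeds is genuinely
  ambiguous in the source protocol; the default (ncRNA-only) is a design
  choice, and the alternative is one config key away
  (`threshold_scope: all`).
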