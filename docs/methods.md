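# Methods

## Problem and model

A postcoordinated SNOMED CT expression (PCE) combines precoordinated
concepts under the Compositional Grammar: one or more focus concepts plus a
refinement of `attribute = value` pairs, optionally bracketed into role
groups.  `pcebridge` re-expresses a PCE through the FHIR information model:
a single precoordinated **Superconcept** stored where a code is expected,
plus the residual **Delta** of attribute–value pairs distributed over other
resource elements.  The TermInfo overlap between terminology and
information model is what makes this translation possible in both
directions.

## Terminology and reasoning

The terminology is loaded from RF2-snapshot-dialect TSV files (concepts,
relationships, optional descriptions).  Snapshot semantics apply: only
active rows enter the is-a DAG and the concept definitions; inactive rows
are retained in a side index and excluded from all reasoning.  Only
inferred relationships feed definitions — classification operates against
the distributed (inferred) view, not stated axioms.  The is-a DAG is a
`networkx` digraph (child → parent); ancestor sets are self-inclusive,
memoised, and computed over is-a edges only.  Attribute relationships are
stored separately as role-grouped definitions, never as hierarchy edges;
this is a deliberate choice where the alternative (treating every
relationship type as a graph edge for ancestor computation) would
contaminate similarity counts with non-taxonomic neighbours.

Expression-vs-concept subsumption is decided structurally on normal forms
(proximal primitive supertypes plus merged refinements), the EL fragment
with role groups:

* every proximal primitive required by the subsumer must subsume some
  proximal primitive of the expression;
* an ungrouped subsumer pair may be matched by any expression pair, grouped
  or ungrouped; a subsumer *group* must be matched wholly inside a single
  expression group (grouping is significant, so a grouped expression and
  its ungrouped flattening are *not* equivalent);
* a pair matches when the expression's attribute is a subtype of the
  subsumer's attribute and its value is subsumed by the subsumer's value,
  recursing structurally for nested expression values.

This procedure is sound but incomplete with respect to full OWL semantics
(no property chains, no transitive attributes besides is-a); the OWL
functional-syntax export exists so an external reasoner can be used as a
cross-check where completeness matters.  Superconcept candidates are the
minimal (most specific) precoordinated subsumers under is-a; when mutual
subsumption with a precoordinated concept holds, that concept is returned
alone as an equivalence and downstream similarity is skipped.

## Superconcept selection

A transient `pce` node is inserted below the expression's focus concepts
and all candidates (the underlying terminology is never mutated).  For a
candidate *c*, with `T(·)` the self-inclusive ancestor set on the augmented
graph and the pce node included in the counts,

```
nonshared = |T(pce) \ T(c)|        union = |T(pce) ∪ T(c)|
sim       = −log₂((nonshared − 1) / union),   +∞ when nonshared = 1
```

The subtracted 1 removes the transient pce node itself from the nonshared
count; `nonshared = 1` means nothing but the pce node separates the two and
the candidate is equivalent.  The score strictly decreases in `nonshared`
at fixed `union` and strictly increases in `union` at fixed
`nonshared > 1`, so ranking by score equals ranking by ascending
nonshared/union ratio.  Because the pce node sits below every candidate,
`T(c) ⊆ T(pce)` and the union equals `|T(pce)|` for all candidates of one
expression — consistent with published candidate tables where all rows
share one union count.  Ties break toward the candidate with the larger
ancestor set (more specific), then the lower numeric id; no principled rule
exists for genuinely symmetric candidates, and the choice is surfaced via a
`tie_break_used` flag.

## Delta

The Delta is pure edge subtraction between two dummy-rooted graphs: the
expression's flattened (attribute, value) pairs minus the Superconcept's
flattened defining pairs, under **exact** pair equality.  A pair whose
value is merely subsumed by (not equal to) a defining value is "not
precisely represented" and deliberately stays in the Delta.  Role-group
structure is flattened here: the mapping rules address attributes, not
groups, so grouping cannot survive the FHIR representation (see
limitations).  Nested-expression values are keyed by their canonical
serialization.

## FHIR mapping

Content categories are disjoint partitions defined by ECL-lite constraints
(`<<`, `<`, `AND`, `MINUS`, parentheses); membership is tested on the focus
concepts first, with the Superconcept as fallback.  Each (category,
profile set) pair has one FHIR R4 StructureMap whose rules bind the string
`Superconcept` or an attribute id to a FHIRPath; the path dialect covers
dotted element names, `:sliceName` suffixes and `extension(<url>)` steps.
A Delta edge binds via the rule matching its attribute, or the nearest rule
source that is an ancestor of the attribute; edges with no applicable rule
are reported as `unmapped`, never silently dropped (matched ⊎ delta = all
pairs is a tested invariant).  Rules marked "via extension" denote
attributes representable only through foreign (e.g. HL7-published)
extensions: they count as unmappable in the coverage table but
extension-coverable, while profile-native extension paths count as directly
mappable.  Coverage aggregates are element-weighted (sum over sum), the
only weighting consistent with the per-row counts and both aggregate
percentages simultaneously.

Emission writes one JSON document per bound resource type, creating
intermediate objects/arrays on demand, fills displays from FSNs,
materialises inter-resource references from the map's reference entries,
and preserves the original expression in `meta.tag` as a safeguard against
lossy mappings.

## Reverse direction

Extraction collects every SNOMED coding at any rule's target path
(non-SNOMED codings ignored).  Where several attributes share one path the
attribute is recovered by three successive rules: (1) keep candidates whose
concept-model value range admits the code — a unique survivor wins; (2) if
the survivors form a chain in the attribute hierarchy, take the most
general; (3) otherwise take the attribute most frequently used with such a
value across all concept definitions.  Final ties break to the lowest
numeric id.  Rule (2) intentionally generalizes (e.g. a device recorded at
a shared device path recomposes under the more general device attribute),
so such round trips are subsumption-comparable rather than equivalent — the
recomposed expression subsumes the original, which the comparison verdict
reports explicitly.  The recomposed expression uses the Superconcept as
focus and ungrouped pairs for all other bindings.

## Synthetic data

The generator emulates the structural features the pipeline depends on: an
acyclic polyhierarchy with a single root, random multi-parent content
subtrees (one per content category, guaranteeing disjoint categories), a
value subtree, an attribute subtree containing a three-level chain, a
configurable fraction of fully defined concepts with role-grouped
definitions, and a concept-model table consistent with the generated
content.  Defaults (120 concepts, ≤3 parents, 6 attributes, 30% fully
defined, 40% grouped) are chosen to exercise multi-inheritance and group
matching at desk scale.  Generation is deterministic: equal specs and seed
yield byte-identical files.  The expression-corpus generator draws focus
concepts and concept-model-admissible refinements so every corpus member
passes semantic validation; the bundled corpus size of 33 mirrors a
realistic small evaluation set.

What the generator does **not** emulate: the degree distribution, depth and
density of a real release, concrete domains, property chains, and
description-logic features beyond EL with role groups.  Passing tests
therefore demonstrate correctness of the algorithms on EL-with-role-groups
terminologies, not performance or completeness on a full release.

The bundled allergy-mini fixture is hand-constructed so that its flagship
expression produces exactly two incomparable Superconcept candidates with
an unambiguous similarity decision, the ten StructureMaps reproduce the
published coverage table row for row, and the procedure subtree exercises
all three reverse-mapping rules.  Content concepts use synthetic `1000xx`
identifiers; the attribute subtree and RF2 metadata reuse real SNOMED CT
identifiers so the maps can carry the published rule table verbatim
(e.g. Causative agent `246075003` → `AllergyIntolerance.code`).

## Numerical and degenerate cases

Similarity counts outside `1 ≤ nonshared ≤ union`, `union ≥ 1` raise;
equivalence scores +∞ rather than dividing by zero.  Scores are kept
unrounded internally and rounded to two decimals only in user output.
Verhoeff check-digit validation is off by default (synthetic ids) and
enabled by a flag for real releases.  Duplicate focus concepts are rejected
at parse time to surface authoring errors.  Nested sub-expression values
are limited to a configurable depth (default 2).  Normalization prunes a
pair only when a strictly more specific sibling subsumes it, and merges a
definitional group into a refinement group only when the refinement group
already refines one of its pairs; side-by-side retention is the
conservative default.

## Known limitations

* Structural subsumption is incomplete for content using OWL features
  beyond EL with role groups.
* Role-group structure does not survive the FHIR representation; grouped
  originals recompose as ungrouped expressions and compare as
  subsumption-related, not equivalent, under the strict grouping semantics.
* Many-to-one path collisions can lose attribute precision by design
  (rule 2); the original expression in `meta.tag` is the recovery path.
* The FHIRPath dialect covers simple traversals only; resources are plain
  JSON dicts and are not validated against profile StructureDefinitions.
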