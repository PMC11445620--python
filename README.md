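# pcebridge

Postcoordinated SNOMED CT expressions (PCEs) are precise but awkward to
store: electronic health records and FHIR-based systems are built around
single precoordinated codes, and searching or displaying an arbitrary
compositional-grammar expression is hard.  `pcebridge` decomposes a PCE
into components that fit the FHIR information model and puts it back
together again:

1. **Validate** the expression against the Compositional Grammar and a
   declarative concept-model (MRCM) table.
2. **Classify** it inside the terminology with a built-in structural
   EL-subsumption engine to find its direct precoordinated subsumers
   (*Superconcept candidates*).
3. **Choose the Superconcept** with a shared-ancestor semantic similarity:
   after inserting a transient `pce` node below the focus concepts and all
   candidates, each candidate *c* is scored

   ```
   sim(pce, c) = −log₂( (|T(pce) \ T(c)| − 1) / |T(pce) ∪ T(c)| )
   ```

   where `T(·)` is the self-inclusive ancestor set in the is-a DAG.  The
   candidate sharing the largest ratio of ancestors wins.
4. **Compute the Delta** — the attribute–value pairs of the PCE not covered
   verbatim by the Superconcept's definition — by graph subtraction of two
   dummy-rooted attribute graphs.
5. **Map to FHIR** — assign the PCE to a content category via ECL
   constraints, pick the category's FHIR R4 StructureMap, bind the
   Superconcept and every Delta edge to FHIRPaths, and emit resource JSON
   (Condition, AllergyIntolerance, Procedure, Observation).
6. **Recompose** — read the SNOMED codings back out of stored resources,
   recover each coding's attribute with three successive disambiguation
   rules (value-range filtering, most-general-in-hierarchy, usage-count
   heuristic), rebuild a PCE, and verify equivalence with the original by
   mutual structural subsumption.

The package is self-contained: it ships a synthetic mini-terminology
generator and a bundled "allergy-mini" fixture (RF2-dialect snapshot files,
MRCM table, five content categories, ten StructureMaps), so everything runs
without a licensed SNOMED CT release.  Real RF2 snapshots load through the
same reader (Verhoeff check-digit validation is opt-in).

## Worked example

```bash
pcebridge fixtures allergy-mini --out /tmp/mini
pcebridge decompose "100014:116676008=100050,363698007=100041" \
    --terminology /tmp/mini/rf2 --mrcm /tmp/mini/mrcm.yaml \
    --categories /tmp/mini/categories.yaml --maps /tmp/mini/maps \
    --profile-set nashp-like --format text
```

prints

```
expression: 100014:116676008=100050,363698007=100041
validation: ok
candidates: 100014, 100015
  100014: nonshared=2 union=6 sim=2.58
  100015: nonshared=3 union=6 sim=1.58
superconcept: 100014
delta: 116676008=100050, 363698007=100041
category: allergic-reaction
  Condition.code <- 100014 |Allergic reaction caused by tree nut (disorder)|
  AllergyIntolerance.reaction.manifestation.coding:snomed <- 100050 |Swelling (morphologic abnormality)|
  Condition.bodySite <- 100041 |Eyelid structure (body structure)|
```

The expression — an allergic reaction caused by tree nut, refined with an
associated morphology (swelling) and a finding site (eyelid) — has two
incomparable subsumers: the tree-nut reaction concept (`100014`, nonshared
2 of 6) and the fully defined swelling finding (`100015`, nonshared 3
of 6).  The former shares more ancestors, scores higher and becomes the
Superconcept; the two refinement pairs it does not define form the Delta
and are bound to `AllergyIntolerance`/`Condition` elements per the
allergic-reaction StructureMap.  Feeding the emitted resources back through
`pcebridge recompose --original …` reports `equivalent`: no information was
lost in the round trip.

`pcebridge coverage` prints the element-coverage table of the shipped map
bundle, including the element-weighted aggregates (76.1% direct, 93.5%
when foreign extensions are admitted).

## Library surface

Every pipeline stage is an ordinary function (`pcebridge.parse`,
`normalize`, `superconcept_candidates`, `score_candidates`,
`compute_delta`, `apply_mapping`, `emit_resources`, `extract_bindings`,
`recompose`, …); the CLI is a thin wrapper.  `pcebridge.ontology_axioms`
and `write_functional_syntax` export the terminology and any expression as
OWL functional syntax for external reasoners.

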