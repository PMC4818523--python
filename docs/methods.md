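# Methods

## The pattern language

Patterns are parsed by a hand-written tokenizer and recursive-descent
parser implementing the additive OPPL subset: typed variable declarations
(`?name:KIND` with kinds `CLASS`, `OBJECTPROPERTY`, `DATAPROPERTY`,
`ANNOTATIONPROPERTY`, `INDIVIDUAL`, `CONSTANT`), a `BEGIN … END;` block,
and `ADD` actions. Supported axiom templates: `SubClassOf`,
`EquivalentTo`, class assertions (`?i Type C`, `InstanceOf` accepted as a
synonym) and annotation assertions (`?x.IRI property value`, value a
`CONSTANT` variable or a double-quoted literal). Class expressions follow
Manchester syntax with the usual precedence (`or` < `and` < `not` /
quantifiers, quantifiers right-associative). `REMOVE` and `SELECT` are
rejected with an explicit unsupported-construct error: this engine only
adds content to a target ontology, so a narrower grammar is a feature — a
template can never delete anything.

Keywords are case-insensitive (`SubClassOf` ≡ `subClassOf`); variable
names are case-sensitive. Actions are separated by newlines or `;`, both
accepted. The canonical renderer emits one declaration and one action per
line, parenthesizes every compound operand and filler, and round-trips:
`parse(render(p)) == p` structurally (property-tested over generated
ASTs). Parse errors carry 1-based line/column and the expected-token set;
variable discipline (undeclared use, duplicate declaration, annotation
subjects restricted to `CLASS`/`INDIVIDUAL`, annotation values to
`CONSTANT`) is enforced after parsing.

Entity references in patterns (`hasNucleation`, `'blood cell'`,
`obo:IAO_0000115`, `<http://…>`) are resolved at instantiation time
against the ontology label index, then the CURIE prefix map; an
unresolvable name is an error, never a silently created property.
Annotation-property names get one extra fallback: a per-template map with
defaults `definition` → the IAO textual-definition property
(`IAO_0000115`) and `label` → `rdfs:label`, both configurable — spreadsheet
templates habitually write `definition` as a bare name.

## Ontology index and queries

The source ontology (any rdflib-readable RDF serialization; the package's
own functional-syntax subset is also accepted) is indexed into: entity
sets by kind, primary labels (priority list, default `rdfs:label` then
`skos:prefLabel`, ties broken lexicographically), a normalized
label→IRI map, told subclass edges over named classes, and annotation
literals. Label normalization is trim + collapse internal whitespace +
casefold, the tolerance spreadsheet data entry needs; lookups also accept
CURIEs and full IRIs. Two entities sharing a normalized label are recorded
as a collision and lookups return an *ambiguous* result rather than an
arbitrary winner.

Hierarchy queries use **told subsumption**: transitive closure over
asserted subclass edges, computed by BFS. `owl:Thing` denotes all named
classes; conjunctions intersect per-conjunct closures. This is
deliberately weaker than DL entailment — no reasoner is involved — but
coincides with it for the query forms templates use (named classes, top,
conjunctions) on typical curation ontologies whose subsumptions are
asserted. Complex asserted superclasses (existing restrictions) are loaded
for fidelity but excluded from hierarchy queries. Cycles in told edges are
tolerated (members become mutual descendants) and reported as a load
warning. Tests cross-check the closure against networkx reachability on
random DAGs; the acceptance script uses its own exhaustive search as a
second, library-free oracle.

## Templates and validation lists

Templates are flat YAML/JSON documents validated by a pydantic schema
(violations report the offending document path). Restrictions are
`free_text`, `fixed_list` (values unique after normalization, enforced at
load) or `dynamic_query` (a variable-free Manchester class expression plus
`descendants` / `self_and_descendants`). Exactly one field feeds each
pattern variable; the linter reports unbound variables, dangling field
bindings, duplicate bindings, unused declarations, unknown entity
references and invalid dynamic queries as errors or warnings. Save →
load → save is byte-identical: saving re-renders patterns to canonical
form and emits keys in a fixed order.

Validation lists (the allowed (label, IRI) pairs of a restricted field)
are sorted by normalized label, fall back to the IRI when an entity is
unlabelled, and are deterministic given template + ontology. Lists longer
than 5000 entries are returned whole with a size warning — the cap
reflects spreadsheet-client performance, not correctness, so it never
fails a run.

## Row processing

Per row: validate (mandatory present, restricted values in-list) →
resolve each cell → instantiate each pattern → merge. Resolution order
for entity fields: existing label / CURIE / IRI → reuse; unknown value on
a `creates_new_terms` field → mint, with a per-submission cache keyed on
the normalized label so one label gets one IRI however often it recurs;
unknown value elsewhere → error. Minted terms get a `Declaration` and a
label annotation immediately. A pattern is skipped for a row when any of
its variables comes from an *empty optional* field — emitting a partial
axiom from a half-filled row would fabricate content. Rows applying no
pattern at all are reported as `skipped`.

Modes: `fail-fast` (default) aborts on any row error and produces no
axioms, matching a whole-submission accept/resubmit workflow; `partial`
processes valid rows and reports the rest. Axioms are de-duplicated
structurally (conjunction/disjunction operands are sorted at
construction), each keeping the full list of contributing (row, pattern)
provenance pairs. Error rows contribute zero axioms by construction, and
the output is referentially closed: every IRI not in the source index has
a declaration.

Minting strategies: `random` (UUID local names; reproducible only when
given an explicit RNG, otherwise two runs agree up to renaming of minted
IRIs), `incremental` (zero-padded counter, width default 7, skips
collisions, raises when the id space is exhausted; a JSON state file
persists the counter across runs), `external` (a callable seam where an
external id service would plug in, result collision-checked). With
incremental minting and fixed inputs, two runs are byte-identical
end-to-end because axiom files are written in a stable order (axiom kind,
then lexicographic serialized form).

QC flags duplicate labels (minted vs existing, or two cache entries that
ended up equal via explicit-IRI entry), identical definition literals on
distinct subjects, and self-subclass axioms. Without a DL reasoner, an
unsatisfiable class created by contradictory input cannot be detected;
self-subclass is the trivially checkable case and the QC report says
nothing beyond what it computed.

## Synthetic fixtures

The fixtures module generates everything tests consume, under the reserved
`http://example.org/termforge/toy/` namespace: toy ontologies (chain /
complete tree / random DAG with one guaranteed parent per class plus
extra edges at probability `edge_prob`; every class labelled, a
configurable fraction given definitions), the "Add terms" worked example
(three fields, two patterns, a five-class cell ontology with
`hasNucleation` and the IAO definition property, a three-row submission),
and random submissions with per-row error injection (missing mandatory
cell, unknown restricted value, duplicate new label). Each generator is
deterministic given its seed, and submission generators return a manifest
of expected per-row status and axioms built by direct enumeration —
plain bookkeeping over labels and the incremental id sequence — never by
calling the engine, so the manifest is an independent oracle. The
enumeration covers "Add terms"-shaped templates (one creating field, one
restricted parent, optional `CONSTANT` annotation fields) and requires the
incremental policy so expected IRIs are predictable.

What the fixtures do not emulate: real ontologies' annotation richness
(synonyms, xrefs, deprecation), multi-parent Manchester-level complex
superclasses in the source, imports closure, non-ASCII labels at scale,
and submissions whose cells need fuzzy matching. Passing tests therefore
demonstrate the engine's transformation semantics, not robustness to
arbitrarily messy curation data.

## Sizes and numerical choices

Default test/acceptance problem sizes: 200 random DAGs of ≤100 classes
for hierarchy-oracle equivalence, 50 random submissions of ≤200 rows for
end-to-end equivalence, 5001-class chain for the validation-list cap —
comfortably covering the regime templates are used in while keeping the
whole suite in seconds. There is no floating-point numerics in the core;
"tolerances" here are exact structural equalities. Degenerate inputs are
defined behavior: empty ontology → empty index; zero-row submission →
empty axiom set and a 0/0/0 report; empty axiom set → a valid empty
ontology document.

## Known limitations

- Told subsumption only; no reasoner-backed query answering or
  satisfiability checking.
- Turtle round-trip of generated axioms recovers the emitted subset; the
  functional-syntax reader likewise reads only what the writer emits (it
  is an output/interchange format for this tool, not a general OWL
  parser). Axioms whose subclass/equivalence left-hand side is a complex
  expression round-trip through functional syntax but not through Turtle
  recovery.
- One ontology universe per run: queries evaluate against the union index
  of all imported ontologies.
- Cross-submission label de-duplication is the curator's job; the mint
  cache is per submission.
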