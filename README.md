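# termforge

Template-driven generation of OWL axioms from tabular term submissions.

Bio-ontologies grow by term requests: a curator or domain expert wants a
new cell line, disease or assay term added, usually starting from a
spreadsheet. Encoding each request by hand in OWL is slow and error-prone,
and makes it hard to enforce the ontology design patterns that keep a large
ontology consistent. `termforge` closes that gap: an ontology engineer
writes a **template** once — input fields bound to the variables of one or
more design patterns — and every submitted spreadsheet row is then
validated, resolved against the source ontology, and expanded into OWL
axioms mechanically.

## The model

Design patterns are written in an additive subset of OPPL (Ontology
Pre-Processing Language): typed variable declarations followed by `ADD`
actions over Manchester-syntax axiom templates. For example, a pattern
relating a cell type to its nucleation state:

```
?cell:CLASS,?nucleation:CLASS
BEGIN
ADD ?cell SubClassOf hasNucleation some ?nucleation
END;
```

Binding `?cell` = *blood cell* and `?nucleation` = *anucleate* produces
`SubClassOf(blood_cell, hasNucleation some anucleate)`. Patterns can emit
T-box axioms (`SubClassOf`, `EquivalentTo`), A-box axioms (`?x Type C`) and
annotation assertions (`ADD ?x.IRI definition ?definition`, where a
`CONSTANT` variable carries a literal).

A template binds each spreadsheet column to one pattern variable and states
whether the column is mandatory, whether it accepts free text or is
restricted to existing ontology terms (a fixed list, or a class-expression
query such as *descendants of `owl:Thing`* evaluated by told subsumption —
the transitive closure of asserted subclass axioms), and whether unknown
values should become **new terms**. Values are entered by primary label
(`rdfs:label` by default); a label already in the ontology reuses that
term's IRI, an unknown label on a term-creating field mints a fresh IRI
(random UUID, zero-padded incremental id, or a pluggable external minter),
one IRI per normalized label per submission. All axioms from all rows are
de-duplicated, checked by curator-style QC (duplicate labels, duplicate
definitions, self-subclass), and written to a single OWL file (functional
syntax by default, Turtle optionally) with a JSON processing report.

## Worked example

Generate the bundled "Add terms" example (a small cell ontology, a
three-field template and a three-row CSV) and process it:

```bash
termforge fixtures --kind worked-example --out-dir demo
termforge process -t demo/add_terms.yaml -O demo/toy.ttl \
    -s demo/submission.csv -o demo/new_terms.ofn
```

The submission is:

```
New term,parent,definition
fluffy cell,blood cell,a test definition
spiky cell,cell,a cell with spikes
round cell,blood cell,
```

and the run prints

```
INFO termforge: rows: 3 ok, 0 error, 0 skipped; axioms: 11; new terms: 3; QC issues: 0
```

Each row minted one new class (`TF_0000100`–`TF_0000102`, incremental
policy), asserted it under the parent resolved *by label*, and attached the
definition where one was given — 11 axioms: 3 declarations, 3 label
annotations, 3 subclass axioms, 2 definition annotations (row three left
the optional definition empty, so its annotation pattern was skipped).
The start of `demo/new_terms.ofn`:

```
Ontology(<urn:termforge:generated>
Declaration(Class(<http://example.org/termforge/toy/TF_0000100>))
...
SubClassOf(<http://example.org/termforge/toy/TF_0000100> <http://example.org/termforge/toy/blood_cell>)
...
AnnotationAssertion(<http://purl.obolibrary.org/obo/IAO_0000115> <http://example.org/termforge/toy/TF_0000100> "a test definition")
```

`termforge validate` and `termforge lint` run the row checks and the
template checks without writing anything; `termforge qc` re-checks a
generated axiom file. Exit codes: 0 ok, 2 configuration error,
3 validation/lint failure, 4 processing failure, 5 I/O failure. In the
default fail-fast mode any bad row aborts the whole submission (exit 3,
no OWL written); `--mode partial` processes the valid rows and reports the
rest.

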