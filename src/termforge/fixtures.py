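"""Synthetic ontologies, templates and submissions with known ground truth.

Every generator is deterministic given its spec (including the seed), and
writes the same file formats production code reads, so fixtures are
indistinguishable from user inputs.  Fixture IRIs live under the reserved
``http://example.org/termforge/toy/`` namespace so collisions with real
ontologies are impossible.

The expected-outcome manifests are built by direct enumeration — mimicking
the documented row semantics with plain bookkeeping, never by calling the
engine — so they can serve as an independent oracle in tests.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from rdflib import Graph, Literal as RLiteral, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from . import engine as eng
from . import ontology as onto
from . import patterns as pat
from . import templates as tpl
from .errors import TermforgeError

__all__ = [
    "TOY_NS", "FixtureSpec", "ToyOntologyManifest", "generate_toy_ontology",
    "toy_graph", "index_from_manifest", "WorkedExample",
    "generate_worked_example", "cell_nucleation_pattern",
    "SubmissionManifest", "RowExpectation", "generate_submission",
    "write_submission",
]

TOY_NS = "http://example.org/termforge/toy/"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for synthetic fixture generation.

    ``shape`` is one of ``chain``, ``tree`` (complete, given branching) or
    ``dag`` (one guaranteed parent per class plus random extra edges with
    probability ``edge_prob``).  Error-injection rates are per-row
    probabilities for submission generation.
    """

    seed: int = 0
    n_classes: int = 10
    shape: str = "chain"
    branching: int = 2
    edge_prob: float = 0.1
    label_scheme: str = "toy class {i:04d}"
    definition_fraction: float = 0.5
    n_rows: int = 10
    rate_missing_mandatory: float = 0.0
    rate_unknown_restricted: float = 0.0
    rate_duplicate_new_label: float = 0.0

    def __post_init__(self):
        if self.n_classes < 1:
            raise TermforgeError("n_classes must be >= 1")
        if self.shape not in ("chain", "tree", "dag"):
            raise TermforgeError(f"unknown hierarchy shape {self.shape!r}")
        total = self.rate_missing_mandatory + self.rate_unknown_restricted
        if total > 1.0 + 1e-9:
            raise TermforgeError("error rates sum to more than 1")


@dataclass
class ToyOntologyManifest:
    classes: list[tuple[str, str]]             # (IRI, label)
    edges: list[tuple[str, str]]               # (subclass, superclass)
    definitions: dict[str, str] = dc_field(default_factory=dict)
    object_properties: list[tuple[str, str]] = dc_field(default_factory=list)
    annotation_properties: list[tuple[str, str]] = dc_field(default_factory=list)


def _toy_manifest(spec: FixtureSpec) -> ToyOntologyManifest:
    rng = random.Random(spec.seed)
    classes = [(f"{TOY_NS}C{i:05d}", spec.label_scheme.format(i=i))
               for i in range(spec.n_classes)]
    edges: list[tuple[str, str]] = []
    for i in range(1, spec.n_classes):
        if spec.shape == "chain":
            parents = [i - 1]
        elif spec.shape == "tree":
            parents = [(i - 1) // spec.branching]
        else:
            parents = [rng.randrange(i)]
            for j in range(i):
                if j != parents[0] and rng.random() < spec.edge_prob:
                    parents.append(j)
        for j in sorted(set(parents)):
            edges.append((classes[i][0], classes[j][0]))
    definitions = {
        iri: f"textual definition of {label}"
        for iri, label in classes if rng.random() < spec.definition_fraction}
    return ToyOntologyManifest(classes, edges, definitions)


def toy_graph(manifest: ToyOntologyManifest) -> Graph:
    g = Graph()
    g.bind("toy", TOY_NS)
    g.bind("owl", OWL)
    def_prop = URIRef(onto.IAO_DEFINITION)
    for iri, label in manifest.classes:
        g.add((URIRef(iri), RDF.type, OWL.Class))
        g.add((URIRef(iri), RDFS.label, RLiteral(label)))
    for sub, sup in manifest.edges:
        g.add((URIRef(sub), RDFS.subClassOf, URIRef(sup)))
    for iri, text in sorted(manifest.definitions.items()):
        g.add((URIRef(iri), def_prop, RLiteral(text)))
    for iri, label in manifest.object_properties:
        g.add((URIRef(iri), RDF.type, OWL.ObjectProperty))
        g.add((URIRef(iri), RDFS.label, RLiteral(label)))
    for iri, label in manifest.annotation_properties:
        g.add((URIRef(iri), RDF.type, OWL.AnnotationProperty))
        g.add((URIRef(iri), RDFS.label, RLiteral(label)))
    return g


def generate_toy_ontology(spec: FixtureSpec, path: str | Path,
                          ) -> ToyOntologyManifest:
    """Write a synthetic labelled class hierarchy as Turtle; the returned
    manifest lists every class, label and told edge for oracle checks."""
    manifest = _toy_manifest(spec)
    Path(path).write_text(toy_graph(manifest).serialize(format="turtle"),
                          encoding="utf-8")
    return manifest


def index_from_manifest(manifest: ToyOntologyManifest) -> onto.OntologyIndex:
    """Index built straight from the manifest (fast path for large property
    tests; equivalent to writing + loading the Turtle file)."""
    return onto.build_index(toy_graph(manifest))


# --------------------------------------------------------------------------
# The "Add terms" worked example
# --------------------------------------------------------------------------

_WE_CLASSES = [
    ("cell", "cell", None),
    ("blood_cell", "blood cell", "cell"),
    ("nucleation", "nucleation", None),
    ("anucleate", "anucleate", "nucleation"),
    ("multinucleate", "multinucleate", "nucleation"),
]

ADD_TERMS_PATTERN_1 = (
    "?newTerm:CLASS\n"
    "?parent:CLASS\n"
    "BEGIN\n"
    "ADD ?newTerm subClassOf ?parent\n"
    "END;\n")

ADD_TERMS_PATTERN_2 = (
    "?newTerm:CLASS\n"
    "?definition:CONSTANT\n"
    "BEGIN\n"
    "ADD ?newTerm.IRI definition ?definition\n"
    "END;\n")

CELL_NUCLEATION_PATTERN = (
    "?cell:CLASS,?nucleation:CLASS\n"
    "BEGIN\n"
    "ADD ?cell SubClassOf hasNucleation some ?nucleation\n"
    "END;\n")

_WE_ROWS = [
    {"New term": "fluffy cell", "parent": "blood cell",
     "definition": "a test definition"},
    {"New term": "spiky cell", "parent": "cell",
     "definition": "a cell with spikes"},
    {"New term": "round cell", "parent": "blood cell", "definition": ""},
]

WE_BASE = f"{TOY_NS}TF_"
WE_START = 100


def cell_nucleation_pattern() -> pat.Pattern:
    return pat.parse_pattern(CELL_NUCLEATION_PATTERN, name="cell-nucleation")


@dataclass
class WorkedExample:
    ontology_path: Path
    template_path: Path
    submission_path: Path
    template: tpl.Template
    submission: eng.Submission
    index: onto.OntologyIndex
    manifest: ToyOntologyManifest
    expected_axioms: onto.AxiomSet
    expected_new_terms: list[tuple[str, str]]

    def class_iri(self, label: str) -> str:
        res = onto.label_lookup(self.index, label)
        if not res.found:
            raise TermforgeError(f"no worked-example class labelled {label!r}")
        return res.iri


def _worked_example_manifest() -> ToyOntologyManifest:
    by_key = {key: f"{TOY_NS}{key}" for key, _, _ in _WE_CLASSES}
    classes = [(by_key[k], label) for k, label, _ in _WE_CLASSES]
    edges = [(by_key[k], by_key[parent])
             for k, _, parent in _WE_CLASSES if parent]
    m = ToyOntologyManifest(classes, edges)
    m.object_properties.append((f"{TOY_NS}hasNucleation", "hasNucleation"))
    m.annotation_properties.append((onto.IAO_DEFINITION, "definition"))
    return m


def _worked_example_template() -> tpl.Template:
    return tpl.Template(
        name="Add terms",
        imported_ontologies=("toy.ttl",),
        fields=(
            tpl.Field("New term", "newTerm", tpl.FreeText(),
                      mandatory=True, creates_new_terms=True),
            tpl.Field("parent", "parent",
                      tpl.DynamicQuery("owl:Thing",
                                       onto.QueryMode.DESCENDANTS),
                      mandatory=True),
            tpl.Field("definition", "definition", tpl.FreeText(),
                      mandatory=False),
        ),
        patterns=(
            pat.parse_pattern(ADD_TERMS_PATTERN_1, name="subclass"),
            pat.parse_pattern(ADD_TERMS_PATTERN_2, name="definition"),
        ),
        uri_policy=tpl.UriPolicy("incremental", WE_BASE, width=7,
                                 start=WE_START),
        prefixes={"toy": TOY_NS},
    )


def _expected_add_terms_axioms(
        rows: list[dict[str, str]], index: onto.OntologyIndex,
        base: str = WE_BASE, start: int = WE_START, width: int = 7,
        ) -> tuple[onto.AxiomSet, list[tuple[str, str]]]:
    """Enumerate the axioms the "Add terms" semantics imply for *rows*:
    straight bookkeeping over labels and the incremental id sequence."""
    expected = onto.AxiomSet()
    new_terms: list[tuple[str, str]] = []
    minted: dict[str, str] = {}
    counter = start
    for row in rows:
        label = row["New term"].strip()
        norm = onto.normalize_label(label)
        existing = onto.label_lookup(index, label)
        if existing.found:
            new_iri = existing.iri
        elif norm in minted:
            new_iri = minted[norm]
        else:
            new_iri = f"{base}{counter:0{width}d}"
            counter += 1
            minted[norm] = new_iri
            new_terms.append((new_iri, label))
            expected.add(onto.Declaration(new_iri, onto.EntityKind.CLASS))
            expected.add(onto.AnnotationAssertion(
                new_iri, onto.RDFS_LABEL, onto.OwlLiteral(label)))
        parent = onto.label_lookup(index, row["parent"])
        expected.add(onto.SubClassOf(onto.Named(new_iri),
                                     onto.Named(parent.iri)))
        definition = row.get("definition", "").strip()
        if definition:
            expected.add(onto.AnnotationAssertion(
                new_iri, onto.IAO_DEFINITION, onto.OwlLiteral(definition)))
    return expected, new_terms


def write_submission(rows: list[dict[str, str]], header: list[str],
                     path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=header, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    return path


def generate_worked_example(directory: str | Path,
                            n_rows: int = 3) -> WorkedExample:
    """Materialize the "Add terms" triple (ontology, template, submission)
    under *directory*, with hand-enumerated expected output.

    ``n_rows`` selects a prefix of the three canonical rows (new term /
    existing parent label / textual definition; the third row leaves the
    optional definition empty).
    """
    if not 1 <= n_rows <= len(_WE_ROWS):
        raise TermforgeError(f"n_rows must be in 1..{len(_WE_ROWS)}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = _worked_example_manifest()
    ontology_path = directory / "toy.ttl"
    ontology_path.write_text(toy_graph(manifest).serialize(format="turtle"),
                             encoding="utf-8")
    template = _worked_example_template()
    template_path = tpl.save_template(template, directory / "add_terms.yaml")
    rows = _WE_ROWS[:n_rows]
    submission_path = write_submission(
        rows, ["New term", "parent", "definition"],
        directory / "submission.csv")
    index = onto.load_ontology(ontology_path)
    expected, new_terms = _expected_add_terms_axioms(rows, index)
    return WorkedExample(
        ontology_path=ontology_path, template_path=template_path,
        submission_path=submission_path,
        template=tpl.load_template(template_path),
        submission=eng.read_submission(submission_path),
        index=index, manifest=manifest,
        expected_axioms=expected, expected_new_terms=new_terms)


# --------------------------------------------------------------------------
# Random submissions against an "Add terms"-shaped template
# --------------------------------------------------------------------------

@dataclass
class RowExpectation:
    row: int
    status: str                         # ok | error
    error_field: str | None = None
    axioms: list[onto.Axiom] = dc_field(default_factory=list)


@dataclass
class SubmissionManifest:
    rows: list[RowExpectation]
    new_terms: list[tuple[str, str]]    # (IRI, label), mint order

    def expected_axiomset(self) -> onto.AxiomSet:
        out = onto.AxiomSet()
        for exp in self.rows:
            for ax in exp.axioms:
                out.add(ax, exp.row)
        for iri, label in self.new_terms:
            out.record_new_term(iri, label)
        return out


def generate_submission(t: tpl.Template, index: onto.OntologyIndex,
                        spec: FixtureSpec,
                        ) -> tuple[eng.Submission, SubmissionManifest]:
    """Random rows for an "Add terms"-shaped template plus an expected
    outcome manifest enumerated independently of the engine.

    The template must have one creating free-text field, one restricted
    mandatory field (the parent), optional CONSTANT fields, and an
    incremental URI policy (so expected IRIs are enumerable).
    """
    if t.uri_policy.strategy != "incremental":
        raise TermforgeError(
            "manifest enumeration requires the incremental URI policy")
    kinds = t.variable_kinds()
    creating = [f for f in t.fields if f.creates_new_terms]
    restricted = [f for f in t.fields
                  if not isinstance(f.restriction, tpl.FreeText)
                  and not f.creates_new_terms]
    constants = [f for f in t.fields
                 if kinds.get(f.variable) is pat.VariableType.CONSTANT]
    if len(creating) != 1 or len(restricted) != 1:
        raise TermforgeError(
            "submission generation expects exactly one creating field and "
            "one restricted parent field")
    new_field, parent_field = creating[0], restricted[0]
    parent_list = tpl.build_validation_list(parent_field, index, t.prefixes)
    parent_entries = [(label, iri) for label, iri in parent_list.entries if iri]
    if not parent_entries:
        raise TermforgeError("parent field has an empty validation list")

    rng = random.Random(spec.seed)
    header = [f.name for f in t.fields]
    rows: list[dict[str, str]] = []
    expectations: list[RowExpectation] = []
    minted: dict[str, str] = {}
    mint_order: list[tuple[str, str]] = []
    counter = t.uri_policy.start
    width = t.uri_policy.width
    prior_labels: list[str] = []

    for k in range(1, spec.n_rows + 1):
        row = {name: "" for name in header}
        draw = rng.random()
        parent_label, parent_iri = parent_entries[
            rng.randrange(len(parent_entries))]
        if draw < spec.rate_missing_mandatory:
            # leave the mandatory new-term cell empty
            row[parent_field.name] = parent_label
            rows.append(row)
            expectations.append(RowExpectation(k, "error", new_field.name))
            continue
        if draw < spec.rate_missing_mandatory + spec.rate_unknown_restricted:
            row[new_field.name] = f"generated term {k:04d}"
            row[parent_field.name] = f"no such term {k:04d}"
            rows.append(row)
            expectations.append(RowExpectation(k, "error", parent_field.name))
            continue

        if prior_labels and rng.random() < spec.rate_duplicate_new_label:
            label = prior_labels[rng.randrange(len(prior_labels))]
        else:
            label = f"generated term {k:04d}"
        prior_labels.append(label)
        row[new_field.name] = label
        row[parent_field.name] = parent_label
        exp = RowExpectation(k, "ok")
        norm = onto.normalize_label(label)
        if norm in minted:
            iri = minted[norm]
        else:
            iri = f"{t.uri_policy.base_namespace}{counter:0{width}d}"
            counter += 1
            minted[norm] = iri
            mint_order.append((iri, label))
            exp.axioms.append(onto.Declaration(iri, onto.EntityKind.CLASS))
            exp.axioms.append(onto.AnnotationAssertion(
                iri, t.label_annotation_property, onto.OwlLiteral(label)))
        exp.axioms.append(onto.SubClassOf(onto.Named(iri),
                                          onto.Named(parent_iri)))
        for cf in constants:
            if rng.random() < spec.definition_fraction:
                text = f"synthetic definition for row {k:04d}"
                row[cf.name] = text
                exp.axioms.append(onto.AnnotationAssertion(
                    iri, t.definition_annotation_property,
                    onto.OwlLiteral(text)))
        rows.append(row)
        expectations.append(exp)

    submission = eng.Submission(tuple(header), rows,
                                source=f"<generated seed={spec.seed}>")
    return submission, SubmissionManifest(expectations, mint_order)
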