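"""Ontology loading, indexing, told-subsumption queries and axiom I/O.

The source ontology is read with :mod:`rdflib` into an :class:`OntologyIndex`
holding the label maps, the *told* (asserted) subclass graph over named
classes, and annotation assertions.  Hierarchy queries (``descendants``,
``evaluate_dl_query``) are answered by transitive closure over told edges —
deliberately weaker than full DL entailment, but exact for the query forms
templates use (named classes, ``owl:Thing``, conjunctions).

Generated axioms are plain frozen dataclasses.  The default output format is
OWL functional-style syntax, written with a stable ordering so identical
inputs yield byte-identical files; Turtle is available as an alternative.
Both formats round-trip through :func:`load_axioms`.
"""

from __future__ import annotations

import enum
import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import BNode, Graph, Literal as RLiteral, Namespace, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS, SKOS, XSD

from . import patterns as pat
from .errors import AmbiguousLabelError, OntologyError, UnknownEntityError

__all__ = [
    "OWL_THING", "DEFAULT_PREFIXES", "DEFAULT_LABEL_PROPERTIES",
    "normalize_label", "EntityKind", "Named", "SomeValues", "OnlyValues",
    "IntersectionOf", "UnionOf", "ComplementOf", "OwlLiteral",
    "SubClassOf", "EquivalentClasses", "AnnotationAssertion",
    "ClassAssertion", "Declaration", "AxiomSet",
    "Resolution", "ResolutionStatus", "QueryMode", "DLQuery",
    "OntologyIndex", "load_ontology", "build_index", "label_lookup",
    "descendants", "evaluate_dl_query", "resolve_named_ref",
    "serialize_axioms", "load_axioms",
]

OWL_THING = str(OWL.Thing)
RDFS_LABEL = str(RDFS.label)
IAO_DEFINITION = "http://purl.obolibrary.org/obo/IAO_0000115"

DEFAULT_PREFIXES: dict[str, str] = {
    "owl": str(OWL),
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "xsd": str(XSD),
    "skos": str(SKOS),
    "obo": "http://purl.obolibrary.org/obo/",
}

#: Annotation-property priority list used to pick an entity's primary label.
DEFAULT_LABEL_PROPERTIES: tuple[str, ...] = (RDFS_LABEL, str(SKOS.prefLabel))


def normalize_label(text: str) -> str:
    """Trim, collapse internal whitespace, casefold."""
    return " ".join(text.split()).casefold()


def expand_curie(ref: str, prefixes: dict[str, str]) -> str | None:
    """Expand ``prefix:local`` against *prefixes*; None if not a known CURIE."""
    if ":" not in ref or "://" in ref:
        return None
    prefix, local = ref.split(":", 1)
    base = prefixes.get(prefix)
    return base + local if base else None


# --------------------------------------------------------------------------
# Ground (variable-free) class expressions and axioms
# --------------------------------------------------------------------------

class EntityKind(enum.Enum):
    CLASS = "Class"
    OBJECT_PROPERTY = "ObjectProperty"
    DATA_PROPERTY = "DataProperty"
    ANNOTATION_PROPERTY = "AnnotationProperty"
    NAMED_INDIVIDUAL = "NamedIndividual"


@dataclass(frozen=True)
class Named:
    iri: str


@dataclass(frozen=True)
class SomeValues:
    prop: str
    filler: "ClassExpr"


@dataclass(frozen=True)
class OnlyValues:
    prop: str
    filler: "ClassExpr"


@dataclass(frozen=True)
class IntersectionOf:
    operands: tuple["ClassExpr", ...]


@dataclass(frozen=True)
class UnionOf:
    operands: tuple["ClassExpr", ...]


@dataclass(frozen=True)
class ComplementOf:
    operand: "ClassExpr"


ClassExpr = Named | SomeValues | OnlyValues | IntersectionOf | UnionOf | ComplementOf


def intersection_of(operands) -> ClassExpr:
    ops = tuple(sorted(set(operands), key=render_expr))
    return ops[0] if len(ops) == 1 else IntersectionOf(ops)


def union_of(operands) -> ClassExpr:
    ops = tuple(sorted(set(operands), key=render_expr))
    return ops[0] if len(ops) == 1 else UnionOf(ops)


@dataclass(frozen=True)
class OwlLiteral:
    text: str
    lang: str | None = None
    datatype: str | None = None


@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpr
    sup: ClassExpr


@dataclass(frozen=True)
class EquivalentClasses:
    lhs: ClassExpr
    rhs: ClassExpr


@dataclass(frozen=True)
class AnnotationAssertion:
    subject: str
    prop: str
    value: OwlLiteral


@dataclass(frozen=True)
class ClassAssertion:
    cls: ClassExpr
    individual: str


@dataclass(frozen=True)
class Declaration:
    iri: str
    kind: EntityKind


Axiom = SubClassOf | EquivalentClasses | AnnotationAssertion | ClassAssertion | Declaration


class AxiomSet:
    """Ordered, de-duplicated axiom collection with provenance.

    ``provenance`` maps each axiom to the list of ``(row, pattern_name)``
    pairs that produced it; structurally equal axioms are stored once but
    keep every contributing pair.  ``new_terms`` records the IRIs minted
    while the set was built, with their labels.
    """

    def __init__(self) -> None:
        self._axioms: dict[Axiom, list[tuple[int, str]]] = {}
        self.new_terms: list[tuple[str, str]] = []

    def add(self, axiom: Axiom, row: int = -1, pattern: str = "") -> None:
        provs = self._axioms.setdefault(axiom, [])
        entry = (row, pattern)
        if entry not in provs:
            provs.append(entry)

    def record_new_term(self, iri: str, label: str) -> None:
        if (iri, label) not in self.new_terms:
            self.new_terms.append((iri, label))

    @property
    def axioms(self) -> list[Axiom]:
        return list(self._axioms)

    def provenance(self, axiom: Axiom) -> list[tuple[int, str]]:
        return list(self._axioms.get(axiom, []))

    def __len__(self) -> int:
        return len(self._axioms)

    def __iter__(self):
        return iter(self._axioms)

    def __contains__(self, axiom: Axiom) -> bool:
        return axiom in self._axioms

    def __eq__(self, other) -> bool:
        if not isinstance(other, AxiomSet):
            return NotImplemented
        return set(self._axioms) == set(other._axioms)

    def referenced_iris(self) -> set[str]:
        out: set[str] = set()
        for ax in self._axioms:
            out |= _axiom_iris(ax)
        return out

    def check_closure(self, index: "OntologyIndex | None" = None) -> list[str]:
        """Referential-closure problems: IRIs used but neither declared here
        nor present in the source index."""
        declared = {ax.iri for ax in self._axioms if isinstance(ax, Declaration)}
        known = set() if index is None else index.all_entities()
        problems = []
        for iri in sorted(self.referenced_iris() - declared - known):
            if not iri.startswith(str(OWL)) and not iri.startswith(str(RDFS)):
                problems.append(f"undeclared IRI {iri}")
        return problems


def _expr_iris(expr: ClassExpr) -> set[str]:
    if isinstance(expr, Named):
        return {expr.iri}
    if isinstance(expr, (SomeValues, OnlyValues)):
        return {expr.prop} | _expr_iris(expr.filler)
    if isinstance(expr, (IntersectionOf, UnionOf)):
        out: set[str] = set()
        for op in expr.operands:
            out |= _expr_iris(op)
        return out
    return _expr_iris(expr.operand)


def _axiom_iris(ax: Axiom) -> set[str]:
    if isinstance(ax, SubClassOf):
        return _expr_iris(ax.sub) | _expr_iris(ax.sup)
    if isinstance(ax, EquivalentClasses):
        return _expr_iris(ax.lhs) | _expr_iris(ax.rhs)
    if isinstance(ax, AnnotationAssertion):
        return {ax.subject, ax.prop}
    if isinstance(ax, ClassAssertion):
        return {ax.individual} | _expr_iris(ax.cls)
    return {ax.iri}


# --------------------------------------------------------------------------
# Index
# --------------------------------------------------------------------------

class ResolutionStatus(enum.Enum):
    FOUND = "found"
    NOT_FOUND = "not-found"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Resolution:
    status: ResolutionStatus
    iri: str | None = None
    candidates: tuple[str, ...] = ()

    @property
    def found(self) -> bool:
        return self.status is ResolutionStatus.FOUND


class QueryMode(enum.Enum):
    DESCENDANTS = "descendants"
    SELF_AND_DESCENDANTS = "self_and_descendants"


@dataclass(frozen=True)
class DLQuery:
    """A restricted, variable-free class-expression query: a named class,
    ``owl:Thing``, or a conjunction of named classes, evaluated by told
    subsumption."""

    expr: pat.ClassExpression
    mode: QueryMode = QueryMode.DESCENDANTS


@dataclass
class OntologyIndex:
    classes: set[str] = field(default_factory=set)
    object_properties: set[str] = field(default_factory=set)
    data_properties: set[str] = field(default_factory=set)
    annotation_properties: set[str] = field(default_factory=set)
    individuals: set[str] = field(default_factory=set)
    label_of: dict[str, str] = field(default_factory=dict)
    iri_of_label: dict[str, str] = field(default_factory=dict)
    label_collisions: dict[str, tuple[str, ...]] = field(default_factory=dict)
    told_subclass_edges: set[tuple[str, str]] = field(default_factory=set)
    complex_superclasses: list[tuple[str, ClassExpr]] = field(default_factory=list)
    annotations: set[tuple[str, str, str]] = field(default_factory=set)
    prefixes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PREFIXES))
    warnings: list[str] = field(default_factory=list)

    def all_entities(self) -> set[str]:
        return (self.classes | self.object_properties | self.data_properties
                | self.annotation_properties | self.individuals)

    # children adjacency, rebuilt lazily after edge mutation
    def _children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {}
        for sub, sup in self.told_subclass_edges:
            ch.setdefault(sup, []).append(sub)
        return ch


def build_index(graph: Graph,
                label_properties: tuple[str, ...] = DEFAULT_LABEL_PROPERTIES,
                extra_prefixes: dict[str, str] | None = None) -> OntologyIndex:
    """Build an :class:`OntologyIndex` from an rdflib graph."""
    idx = OntologyIndex()
    for prefix, ns in graph.namespaces():
        if prefix and not prefix.startswith("default"):
            idx.prefixes.setdefault(prefix, str(ns))
    if extra_prefixes:
        idx.prefixes.update(extra_prefixes)

    type_targets = {
        OWL.Class: idx.classes,
        OWL.ObjectProperty: idx.object_properties,
        OWL.DatatypeProperty: idx.data_properties,
        OWL.AnnotationProperty: idx.annotation_properties,
        OWL.NamedIndividual: idx.individuals,
    }
    for rdf_type, target in type_targets.items():
        for s in graph.subjects(RDF.type, rdf_type):
            if isinstance(s, URIRef):
                target.add(str(s))

    for s, o in graph.subject_objects(RDFS.subClassOf):
        if not isinstance(s, URIRef):
            continue
        if isinstance(o, URIRef):
            idx.classes.add(str(s))
            idx.classes.add(str(o))
            idx.told_subclass_edges.add((str(s), str(o)))
        elif isinstance(o, BNode):
            try:
                expr = _expr_from_node(graph, o)
            except OntologyError:
                idx.warnings.append(
                    f"unparseable complex superclass of {s}")
                continue
            idx.complex_superclasses.append((str(s), expr))

    # annotation assertions: any (URIRef, URIRef, Literal) triple
    for s, p, o in graph:
        if isinstance(s, URIRef) and isinstance(p, URIRef) \
                and isinstance(o, RLiteral):
            idx.annotations.add((str(s), str(p), str(o)))

    # primary labels: property priority, ties broken lexicographically
    entities = idx.all_entities()
    for iri in entities:
        for prop in label_properties:
            values = sorted(
                str(o) for o in graph.objects(URIRef(iri), URIRef(prop))
                if isinstance(o, RLiteral))
            if values:
                idx.label_of[iri] = values[0]
                break

    by_norm: dict[str, set[str]] = {}
    for iri, label in idx.label_of.items():
        by_norm.setdefault(normalize_label(label), set()).add(iri)
    for norm, iris in by_norm.items():
        if len(iris) == 1:
            idx.iri_of_label[norm] = next(iter(iris))
        else:
            idx.label_collisions[norm] = tuple(sorted(iris))
            idx.warnings.append(
                f"label collision: {norm!r} names {len(iris)} entities")

    for cycle_member in _cycle_members(idx.told_subclass_edges):
        idx.warnings.append(f"subclass cycle involves {cycle_member}")
        break  # one warning per index is enough
    return idx


def _cycle_members(edges: set[tuple[str, str]]) -> list[str]:
    # Kahn's algorithm leftover = members of some cycle
    nodes = {n for e in edges for n in e}
    out_deg = {n: 0 for n in nodes}
    preds: dict[str, list[str]] = {n: [] for n in nodes}
    for sub, sup in edges:
        out_deg[sub] += 1
        preds[sup].append(sub)
    queue = deque(n for n, d in out_deg.items() if d == 0)
    seen = 0
    while queue:
        n = queue.popleft()
        seen += 1
        for p in preds[n]:
            out_deg[p] -= 1
            if out_deg[p] == 0:
                queue.append(p)
    return sorted(n for n, d in out_deg.items() if d > 0) if seen < len(nodes) else []


_FORMAT_BY_EXT = {
    ".ttl": "turtle", ".turtle": "turtle", ".nt": "nt", ".n3": "n3",
    ".owl": "xml", ".rdf": "xml", ".xml": "xml", ".ofn": "ofn",
    ".jsonld": "json-ld",
}


def load_ontology(path: str | Path, fmt: str | None = None,
                  label_properties: tuple[str, ...] = DEFAULT_LABEL_PROPERTIES,
                  extra_prefixes: dict[str, str] | None = None) -> OntologyIndex:
    """Load an OWL file into an :class:`OntologyIndex`.

    Format is auto-detected from the extension (``.ttl``, ``.owl``/``.rdf``,
    ``.nt``, ``.ofn``...) unless *fmt* overrides it.  Functional-syntax files
    are restricted to the subset this package itself writes.
    """
    path = Path(path)
    if not path.exists():
        raise OntologyError(f"ontology file not found: {path}")
    use_fmt = fmt or _FORMAT_BY_EXT.get(path.suffix.lower())
    if use_fmt is None:
        raise OntologyError(
            f"cannot determine serialization of {path}; pass fmt=")
    if use_fmt == "ofn":
        graph = _axioms_to_graph(load_axioms(path, fmt="ofn"))
    else:
        graph = Graph()
        try:
            graph.parse(path, format=use_fmt)
        except Exception as exc:  # rdflib raises many parser types
            raise OntologyError(f"failed to parse {path}: {exc}") from exc
    return build_index(graph, label_properties, extra_prefixes)


# --------------------------------------------------------------------------
# Lookup and hierarchy queries
# --------------------------------------------------------------------------

def label_lookup(index: OntologyIndex, value: str) -> Resolution:
    """Resolve a label, CURIE or full IRI to an entity IRI.

    Normalization for labels: trim, collapse internal whitespace,
    case-insensitive.  Never raises — ambiguity and absence are result
    states.
    """
    text = value.strip()
    if not text:
        return Resolution(ResolutionStatus.NOT_FOUND)
    candidate = text[1:-1] if text.startswith("<") and text.endswith(">") else text
    if "://" in candidate and candidate in index.all_entities():
        return Resolution(ResolutionStatus.FOUND, candidate)
    expanded = expand_curie(candidate, index.prefixes)
    if expanded and expanded in index.all_entities():
        return Resolution(ResolutionStatus.FOUND, expanded)
    norm = normalize_label(text)
    if norm in index.label_collisions:
        return Resolution(ResolutionStatus.AMBIGUOUS,
                          candidates=index.label_collisions[norm])
    iri = index.iri_of_label.get(norm)
    if iri is not None:
        return Resolution(ResolutionStatus.FOUND, iri)
    return Resolution(ResolutionStatus.NOT_FOUND)


def descendants(index: OntologyIndex, root: str,
                mode: QueryMode = QueryMode.DESCENDANTS) -> set[str]:
    """Told descendants of *root*: transitive closure over asserted subclass
    edges.  ``owl:Thing`` yields every named class.  Cycles are tolerated —
    members of a cycle are mutual descendants."""
    if root == OWL_THING:
        result = set(index.classes)
        return result
    if root not in index.classes:
        raise UnknownEntityError(root, f"unknown class IRI: {root}")
    children = index._children()
    seen: set[str] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children.get(node, ()):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    if mode is QueryMode.SELF_AND_DESCENDANTS:
        seen.add(root)
    else:
        # root stays excluded unless it reaches itself through a cycle
        if root not in seen:
            seen.discard(root)
    return seen


def resolve_named_ref(index: OntologyIndex, ref: pat.NamedRef,
                      extra_prefixes: dict[str, str] | None = None) -> str:
    """Resolve a pattern-level entity reference to a known IRI.

    Quoted labels resolve through the label index only; bare names try the
    label index first, then CURIE expansion; full IRIs must be known.
    Unresolvable references are errors — patterns never mint entities.
    """
    prefixes = dict(index.prefixes)
    if extra_prefixes:
        prefixes.update(extra_prefixes)
    known = index.all_entities()
    text = ref.ref
    if ref.quoted:
        res = label_lookup(index, text)
        if res.status is ResolutionStatus.AMBIGUOUS:
            raise AmbiguousLabelError(text, res.candidates)
        if not res.found:
            raise UnknownEntityError(text)
        return res.iri
    if "://" in text:
        if text in known or text == OWL_THING:
            return text
        raise UnknownEntityError(text)
    norm = normalize_label(text)
    if norm in index.label_collisions:
        raise AmbiguousLabelError(text, index.label_collisions[norm])
    iri = index.iri_of_label.get(norm)
    if iri is not None:
        return iri
    expanded = expand_curie(text, prefixes)
    if expanded is not None:
        if expanded in known or expanded == OWL_THING:
            return expanded
    raise UnknownEntityError(text)


def evaluate_dl_query(index: OntologyIndex, q: DLQuery,
                      extra_prefixes: dict[str, str] | None = None) -> set[str]:
    """Evaluate a restricted DL query by told subsumption.

    Supported forms: a named class (descendants per mode), ``owl:Thing``
    (all named classes), and conjunctions of named classes (intersection of
    the per-conjunct results).
    """
    expr = q.expr
    if isinstance(expr, pat.NamedRef):
        root = resolve_named_ref(index, expr, extra_prefixes)
        return descendants(index, root, q.mode)
    if isinstance(expr, pat.And):
        results = None
        for op in expr.operands:
            if not isinstance(op, pat.NamedRef):
                raise OntologyError(
                    "DL queries support only named classes and conjunctions "
                    f"of named classes; got {type(op).__name__}")
            part = descendants(index, resolve_named_ref(index, op, extra_prefixes),
                               q.mode)
            results = part if results is None else results & part
        return results or set()
    raise OntologyError(
        "DL queries support only named classes and conjunctions of named "
        f"classes; got {type(expr).__name__}")


# --------------------------------------------------------------------------
# Functional-style syntax writer / reader
# --------------------------------------------------------------------------

_KIND_ORDER = {Declaration: 0, SubClassOf: 1, EquivalentClasses: 2,
               ClassAssertion: 3, AnnotationAssertion: 4}

DEFAULT_OUTPUT_ONTOLOGY_IRI = "urn:termforge:generated"


def render_expr(expr: ClassExpr) -> str:
    if isinstance(expr, Named):
        return f"<{expr.iri}>"
    if isinstance(expr, SomeValues):
        return f"ObjectSomeValuesFrom(<{expr.prop}> {render_expr(expr.filler)})"
    if isinstance(expr, OnlyValues):
        return f"ObjectAllValuesFrom(<{expr.prop}> {render_expr(expr.filler)})"
    if isinstance(expr, IntersectionOf):
        inner = " ".join(render_expr(o) for o in expr.operands)
        return f"ObjectIntersectionOf({inner})"
    if isinstance(expr, UnionOf):
        inner = " ".join(render_expr(o) for o in expr.operands)
        return f"ObjectUnionOf({inner})"
    if isinstance(expr, ComplementOf):
        return f"ObjectComplementOf({render_expr(expr.operand)})"
    raise TypeError(f"unknown expression {expr!r}")


def _render_literal(lit: OwlLiteral) -> str:
    esc = lit.text.replace("\\", "\\\\").replace('"', '\\"')
    out = f'"{esc}"'
    if lit.lang:
        out += f"@{lit.lang}"
    elif lit.datatype:
        out += f"^^<{lit.datatype}>"
    return out


def render_axiom(ax: Axiom) -> str:
    if isinstance(ax, Declaration):
        return f"Declaration({ax.kind.value}(<{ax.iri}>))"
    if isinstance(ax, SubClassOf):
        return f"SubClassOf({render_expr(ax.sub)} {render_expr(ax.sup)})"
    if isinstance(ax, EquivalentClasses):
        return (f"EquivalentClasses({render_expr(ax.lhs)} "
                f"{render_expr(ax.rhs)})")
    if isinstance(ax, ClassAssertion):
        return (f"ClassAssertion({render_expr(ax.cls)} <{ax.individual}>)")
    if isinstance(ax, AnnotationAssertion):
        return (f"AnnotationAssertion(<{ax.prop}> <{ax.subject}> "
                f"{_render_literal(ax.value)})")
    raise TypeError(f"unknown axiom {ax!r}")


def sorted_axioms(axioms) -> list[Axiom]:
    return sorted(axioms,
                  key=lambda a: (_KIND_ORDER[type(a)], render_axiom(a)))


def serialize_axioms(axset: AxiomSet, path: str | Path, fmt: str = "ofn",
                     ontology_iri: str = DEFAULT_OUTPUT_ONTOLOGY_IRI) -> Path:
    """Write an axiom set to *path* with deterministic axiom ordering
    (by axiom kind, then lexicographically by serialized form).

    ``fmt`` is ``"ofn"`` (functional-style syntax, default) or ``"turtle"``.
    """
    path = Path(path)
    ordered = sorted_axioms(axset.axioms)
    try:
        if fmt == "ofn":
            lines = [f"Ontology(<{ontology_iri}>"]
            lines += [render_axiom(ax) for ax in ordered]
            lines.append(")")
            path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        elif fmt in ("turtle", "ttl"):
            graph = _axioms_to_graph(ordered, ontology_iri)
            path.write_text(graph.serialize(format="turtle"), encoding="utf-8")
        else:
            raise OntologyError(f"unsupported output format {fmt!r}")
    except OSError as exc:
        raise OntologyError(f"cannot write {path}: {exc}") from exc
    return path


def _axioms_to_graph(axioms, ontology_iri: str = DEFAULT_OUTPUT_ONTOLOGY_IRI) -> Graph:
    g = Graph()
    g.add((URIRef(ontology_iri), RDF.type, OWL.Ontology))
    kind_types = {
        EntityKind.CLASS: OWL.Class,
        EntityKind.OBJECT_PROPERTY: OWL.ObjectProperty,
        EntityKind.DATA_PROPERTY: OWL.DatatypeProperty,
        EntityKind.ANNOTATION_PROPERTY: OWL.AnnotationProperty,
        EntityKind.NAMED_INDIVIDUAL: OWL.NamedIndividual,
    }
    for ax in axioms:
        if isinstance(ax, Declaration):
            g.add((URIRef(ax.iri), RDF.type, kind_types[ax.kind]))
        elif isinstance(ax, SubClassOf):
            g.add((_expr_to_node(g, ax.sub), RDFS.subClassOf,
                   _expr_to_node(g, ax.sup)))
        elif isinstance(ax, EquivalentClasses):
            g.add((_expr_to_node(g, ax.lhs), OWL.equivalentClass,
                   _expr_to_node(g, ax.rhs)))
        elif isinstance(ax, ClassAssertion):
            g.add((URIRef(ax.individual), RDF.type, _expr_to_node(g, ax.cls)))
        elif isinstance(ax, AnnotationAssertion):
            lit = RLiteral(
                ax.value.text, lang=ax.value.lang,
                datatype=URIRef(ax.value.datatype) if ax.value.datatype else None)
            g.add((URIRef(ax.subject), URIRef(ax.prop), lit))
    return g


def _expr_to_node(g: Graph, expr: ClassExpr):
    if isinstance(expr, Named):
        return URIRef(expr.iri)
    node = BNode()
    if isinstance(expr, (SomeValues, OnlyValues)):
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, URIRef(expr.prop)))
        pred = OWL.someValuesFrom if isinstance(expr, SomeValues) \
            else OWL.allValuesFrom
        g.add((node, pred, _expr_to_node(g, expr.filler)))
    elif isinstance(expr, (IntersectionOf, UnionOf)):
        g.add((node, RDF.type, OWL.Class))
        members = [_expr_to_node(g, o) for o in expr.operands]
        lst = BNode()
        Collection(g, lst, members)
        pred = OWL.intersectionOf if isinstance(expr, IntersectionOf) \
            else OWL.unionOf
        g.add((node, pred, lst))
    elif isinstance(expr, ComplementOf):
        g.add((node, RDF.type, OWL.Class))
        g.add((node, OWL.complementOf, _expr_to_node(g, expr.operand)))
    else:
        raise TypeError(f"unknown expression {expr!r}")
    return node


def _expr_from_node(g: Graph, node) -> ClassExpr:
    if isinstance(node, URIRef):
        return Named(str(node))
    if not isinstance(node, BNode):
        raise OntologyError(f"unexpected class-expression node {node!r}")
    prop = g.value(node, OWL.onProperty)
    if prop is not None:
        some = g.value(node, OWL.someValuesFrom)
        if some is not None:
            return SomeValues(str(prop), _expr_from_node(g, some))
        only = g.value(node, OWL.allValuesFrom)
        if only is not None:
            return OnlyValues(str(prop), _expr_from_node(g, only))
        raise OntologyError("restriction without a supported filler")
    for pred, builder in ((OWL.intersectionOf, intersection_of),
                          (OWL.unionOf, union_of)):
        lst = g.value(node, pred)
        if lst is not None:
            members = [_expr_from_node(g, m) for m in Collection(g, lst)]
            return builder(members)
    comp = g.value(node, OWL.complementOf)
    if comp is not None:
        return ComplementOf(_expr_from_node(g, comp))
    raise OntologyError("unsupported anonymous class expression")


def axioms_from_graph(g: Graph) -> AxiomSet:
    """Recover the axiom subset this package emits from an RDF graph."""
    out = AxiomSet()
    kind_by_type = {
        OWL.Class: EntityKind.CLASS,
        OWL.ObjectProperty: EntityKind.OBJECT_PROPERTY,
        OWL.DatatypeProperty: EntityKind.DATA_PROPERTY,
        OWL.AnnotationProperty: EntityKind.ANNOTATION_PROPERTY,
        OWL.NamedIndividual: EntityKind.NAMED_INDIVIDUAL,
    }
    for s, p, o in g:
        if p == RDF.type and isinstance(s, URIRef):
            if o in kind_by_type:
                out.add(Declaration(str(s), kind_by_type[o]))
            elif o != OWL.Ontology and isinstance(o, (URIRef, BNode)):
                if isinstance(o, URIRef) and str(o).startswith(str(OWL)):
                    continue
                out.add(ClassAssertion(_expr_from_node(g, o), str(s)))
        elif p == RDFS.subClassOf and isinstance(s, URIRef):
            out.add(SubClassOf(Named(str(s)), _expr_from_node(g, o)))
        elif p == OWL.equivalentClass and isinstance(s, URIRef):
            out.add(EquivalentClasses(Named(str(s)), _expr_from_node(g, o)))
        elif isinstance(s, URIRef) and isinstance(o, RLiteral):
            out.add(AnnotationAssertion(
                str(s), str(p),
                OwlLiteral(str(o), lang=o.language,
                           datatype=str(o.datatype) if o.datatype else None)))
    return out


# ---- functional-syntax reader (subset) ----

_OFN_TOKEN = re.compile(
    r"""\s*(?:
        (?P<iri><[^<>\s]+>)
      | (?P<lit>"(?:[^"\\]|\\.)*"(?:@[A-Za-z0-9\-]+|\^\^<[^<>\s]+>)?)
      | (?P<name>[A-Za-z][A-Za-z0-9]*)
      | (?P<paren>[()])
    )""", re.VERBOSE)


def _ofn_tokens(text: str):
    pos = 0
    while pos < len(text):
        m = _OFN_TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise OntologyError(
                    f"unexpected content in functional-syntax file near "
                    f"{text[pos:pos+30]!r}")
            break
        pos = m.end()
        if m.group("iri"):
            yield ("IRI", m.group("iri")[1:-1])
        elif m.group("lit"):
            yield ("LIT", m.group("lit"))
        elif m.group("name"):
            yield ("NAME", m.group("name"))
        else:
            yield ("PAREN", m.group("paren"))


def _parse_ofn_literal(raw: str) -> OwlLiteral:
    m = re.match(r'"((?:[^"\\]|\\.)*)"(?:@([A-Za-z0-9\-]+)|\^\^<([^<>\s]+)>)?$',
                 raw)
    if m is None:
        raise OntologyError(f"malformed literal {raw!r}")
    text = re.sub(r"\\(.)", r"\1", m.group(1))
    return OwlLiteral(text, lang=m.group(2), datatype=m.group(3))


def _ofn_parse_form(toks: list, i: int):
    """Parse NAME ( args... ) starting at i; returns (node, next_i) where
    node is ('form', name, args) | ('iri', s) | ('lit', OwlLiteral)."""
    kind, value = toks[i]
    if kind == "IRI":
        return ("iri", value), i + 1
    if kind == "LIT":
        return ("lit", _parse_ofn_literal(value)), i + 1
    if kind != "NAME":
        raise OntologyError(f"unexpected token {value!r}")
    if i + 1 >= len(toks) or toks[i + 1] != ("PAREN", "("):
        raise OntologyError(f"expected '(' after {value}")
    args = []
    j = i + 2
    while j < len(toks) and toks[j] != ("PAREN", ")"):
        arg, j = _ofn_parse_form(toks, j)
        args.append(arg)
    if j >= len(toks):
        raise OntologyError(f"unterminated {value}(...)")
    return ("form", value, args), j + 1


def _ofn_expr(node) -> ClassExpr:
    if node[0] == "iri":
        return Named(node[1])
    if node[0] != "form":
        raise OntologyError("literal in class-expression position")
    _, name, args = node
    if name == "ObjectSomeValuesFrom":
        return SomeValues(_ofn_iri(args[0]), _ofn_expr(args[1]))
    if name == "ObjectAllValuesFrom":
        return OnlyValues(_ofn_iri(args[0]), _ofn_expr(args[1]))
    if name == "ObjectIntersectionOf":
        return IntersectionOf(tuple(_ofn_expr(a) for a in args))
    if name == "ObjectUnionOf":
        return UnionOf(tuple(_ofn_expr(a) for a in args))
    if name == "ObjectComplementOf":
        return ComplementOf(_ofn_expr(args[0]))
    raise OntologyError(f"unsupported class-expression form {name}")


def _ofn_iri(node) -> str:
    if node[0] != "iri":
        raise OntologyError("expected an IRI")
    return node[1]


_ENTITY_KINDS = {k.value: k for k in EntityKind}


def load_axioms(path: str | Path, fmt: str | None = None) -> AxiomSet:
    """Read an axiom file previously written by :func:`serialize_axioms`."""
    path = Path(path)
    use_fmt = fmt or _FORMAT_BY_EXT.get(path.suffix.lower()) or "ofn"
    if use_fmt in ("turtle", "ttl", "xml", "nt", "n3"):
        g = Graph()
        g.parse(path, format="turtle" if use_fmt == "ttl" else use_fmt)
        return axioms_from_graph(g)
    text = path.read_text(encoding="utf-8")
    toks = list(_ofn_tokens(text))
    node, i = _ofn_parse_form(toks, 0)
    if i != len(toks):
        raise OntologyError("trailing content after Ontology(...)")
    if node[0] != "form" or node[1] != "Ontology":
        raise OntologyError("functional-syntax file must contain Ontology(...)")
    out = AxiomSet()
    body = node[2]
    if body and body[0][0] == "iri":
        body = body[1:]
    for form in body:
        if form[0] != "form":
            raise OntologyError("unexpected top-level token in Ontology(...)")
        _, name, args = form
        if name == "Declaration":
            inner = args[0]
            if inner[0] != "form" or inner[1] not in _ENTITY_KINDS:
                raise OntologyError("malformed Declaration")
            out.add(Declaration(_ofn_iri(inner[2][0]),
                                _ENTITY_KINDS[inner[1]]))
        elif name == "SubClassOf":
            out.add(SubClassOf(_ofn_expr(args[0]), _ofn_expr(args[1])))
        elif name == "EquivalentClasses":
            out.add(EquivalentClasses(_ofn_expr(args[0]), _ofn_expr(args[1])))
        elif name == "ClassAssertion":
            out.add(ClassAssertion(_ofn_expr(args[0]), _ofn_iri(args[1])))
        elif name == "AnnotationAssertion":
            lit = args[2]
            if lit[0] != "lit":
                raise OntologyError("annotation value must be a literal")
            out.add(AnnotationAssertion(_ofn_iri(args[1]), _ofn_iri(args[0]),
                                        lit[1]))
        else:
            raise OntologyError(f"unsupported axiom form {name}")
    return out
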