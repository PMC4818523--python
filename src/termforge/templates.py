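"""Template definitions: fields bound to pattern variables, restrictions,
URI minting policy, and the client-facing validation lists.

A template is a flat YAML (or JSON) document::

    name: Add terms
    ontologies: [toy.ttl]
    prefixes:
      EX: "http://example.org/termforge/toy/"
    fields:
      - name: New term
        variable: newTerm
        restriction: free_text
        mandatory: true
        creates_new_terms: true
      - name: parent
        variable: parent
        restriction: {type: dynamic_query, query: "owl:Thing", mode: descendants}
        mandatory: true
    patterns:
      - name: subclass
        oppl: |
          ?newTerm:CLASS
          ?parent:CLASS
          BEGIN
          ADD ?newTerm SubClassOf ?parent
          END;
    uri_policy:
      strategy: incremental
      base_namespace: "http://example.org/termforge/toy/TF_"
      width: 7
      start: 1

Patterns are parsed at load time; ``save_template`` emits a canonical form
(patterns re-rendered, stable key order) so save→load→save is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal as TLiteral, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field as PField, ValidationError

from . import ontology as onto
from . import patterns as pat
from .errors import (
    AmbiguousLabelError, PatternError, TemplateError, UnknownEntityError,
)

__all__ = [
    "FreeText", "FixedList", "DynamicQuery", "Restriction",
    "Field", "UriPolicy", "Template", "LintIssue", "ValidationList",
    "load_template", "loads_template", "save_template", "lint_template",
    "build_validation_list", "merge_indices", "resolve_annotation_property",
    "VALIDATION_LIST_CAP",
]

#: Above this many entries a validation list carries a size warning —
#: spreadsheet clients degrade with very large in-cell validations.
VALIDATION_LIST_CAP = 5000


# --------------------------------------------------------------------------
# Domain model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FreeText:
    pass


@dataclass(frozen=True)
class FixedList:
    values: tuple[str, ...]

    def __post_init__(self):
        seen: set[str] = set()
        for v in self.values:
            norm = onto.normalize_label(v)
            if norm in seen:
                raise TemplateError(
                    f"fixed list contains duplicate value {v!r} "
                    "(after normalization)")
            seen.add(norm)


@dataclass(frozen=True)
class DynamicQuery:
    query: str                     # Manchester-syntax class expression text
    mode: onto.QueryMode = onto.QueryMode.DESCENDANTS

    def to_dl_query(self) -> onto.DLQuery:
        return onto.DLQuery(pat.parse_class_expression(self.query), self.mode)


Restriction = Union[FreeText, FixedList, DynamicQuery]


@dataclass(frozen=True)
class Field:
    name: str
    variable: str
    restriction: Restriction = FreeText()
    mandatory: bool = False
    creates_new_terms: bool = False


@dataclass(frozen=True)
class UriPolicy:
    strategy: str = "random"               # random | incremental | external
    base_namespace: str = "http://example.org/termforge/"
    width: int = 7                         # zero-pad width (incremental)
    start: int = 1                         # first counter value (incremental)
    state_file: str | None = None          # persists the counter across runs


@dataclass
class Template:
    name: str
    fields: tuple[Field, ...]
    patterns: tuple[pat.Pattern, ...]
    imported_ontologies: tuple[str, ...] = ()
    uri_policy: UriPolicy = dc_field(default_factory=UriPolicy)
    prefixes: dict[str, str] = dc_field(default_factory=dict)
    label_annotation_property: str = onto.RDFS_LABEL
    definition_annotation_property: str = onto.IAO_DEFINITION
    #: bare annotation-property names in patterns resolve through this map
    #: when the label index cannot resolve them
    annotation_property_map: dict[str, str] = dc_field(default_factory=dict)
    annotation_language: str | None = None

    def __post_init__(self):
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TemplateError(f"duplicate field names: {', '.join(dup)}")
        defaults = {"definition": self.definition_annotation_property,
                    "label": self.label_annotation_property}
        for key, iri in defaults.items():
            self.annotation_property_map.setdefault(key, iri)

    def field_for_variable(self, variable: str) -> Field | None:
        for f in self.fields:
            if f.variable == variable:
                return f
        return None

    def variable_kinds(self) -> dict[str, pat.VariableType]:
        """Variable kind per name across all patterns (first declaration
        wins; conflicting redeclarations are a lint error)."""
        kinds: dict[str, pat.VariableType] = {}
        for p in self.patterns:
            for decl in p.variables:
                kinds.setdefault(decl.name, decl.kind)
        return kinds


@dataclass(frozen=True)
class LintIssue:
    level: str       # "error" | "warning" | "info"
    code: str
    message: str

    def __str__(self) -> str:
        return f"[{self.level}] {self.code}: {self.message}"


@dataclass
class ValidationList:
    entries: list[tuple[str, str | None]]   # (label, IRI or None for custom)
    warnings: list[str] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def contains(self, index: onto.OntologyIndex, value: str) -> bool:
        """Membership by normalized label, or by CURIE/IRI resolving to a
        listed entity."""
        norm = onto.normalize_label(value)
        iris = {iri for _, iri in self.entries if iri}
        for label, iri in self.entries:
            if onto.normalize_label(label) == norm:
                return True
        res = onto.label_lookup(index, value)
        return res.found and res.iri in iris


# --------------------------------------------------------------------------
# File schema (pydantic) and load/save
# --------------------------------------------------------------------------

class _RestrictionDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    type: TLiteral["free_text", "fixed_list", "dynamic_query"]
    values: list[str] | None = None
    query: str | None = None
    mode: TLiteral["descendants", "self_and_descendants"] = "descendants"


class _FieldDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    variable: str
    restriction: TLiteral["free_text"] | _RestrictionDoc = "free_text"
    mandatory: bool = False
    creates_new_terms: bool = False


class _PatternDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    oppl: str


class _UriPolicyDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    strategy: TLiteral["random", "incremental", "external"] = "random"
    base_namespace: str
    width: int = PField(default=7, ge=1, le=18)
    start: int = PField(default=1, ge=0)
    state_file: str | None = None


class _TemplateDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    ontologies: list[str] = []
    prefixes: dict[str, str] = {}
    fields: list[_FieldDoc] = PField(min_length=1)
    patterns: list[_PatternDoc] = PField(min_length=1)
    uri_policy: _UriPolicyDoc | None = None
    label_annotation_property: str = onto.RDFS_LABEL
    definition_annotation_property: str = onto.IAO_DEFINITION
    annotation_properties: dict[str, str] = {}
    annotation_language: str | None = None


def _restriction_from_doc(doc) -> Restriction:
    if doc == "free_text":
        return FreeText()
    if doc.type == "free_text":
        return FreeText()
    if doc.type == "fixed_list":
        if not doc.values:
            raise TemplateError("fixed_list restriction requires 'values'")
        return FixedList(tuple(doc.values))
    if not doc.query:
        raise TemplateError("dynamic_query restriction requires 'query'")
    try:
        pat.parse_class_expression(doc.query)
    except PatternError as exc:
        raise TemplateError(f"invalid dynamic query {doc.query!r}: {exc}") from exc
    return DynamicQuery(doc.query, onto.QueryMode(doc.mode))


def loads_template(text: str, name_hint: str = "<string>") -> Template:
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise TemplateError(f"cannot parse template {name_hint}: {exc}") from exc
    if not isinstance(raw, dict):
        raise TemplateError(f"template {name_hint} must be a mapping")
    try:
        doc = _TemplateDoc.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors())
        raise TemplateError(f"template schema violation ({name_hint}): {locs}") from exc

    parsed_patterns = []
    for pdoc in doc.patterns:
        try:
            parsed_patterns.append(pat.parse_pattern(pdoc.oppl, name=pdoc.name))
        except PatternError as exc:
            raise TemplateError(
                f"pattern {pdoc.name!r} failed to parse: {exc}") from exc

    fields = tuple(
        Field(name=f.name, variable=f.variable,
              restriction=_restriction_from_doc(f.restriction),
              mandatory=f.mandatory, creates_new_terms=f.creates_new_terms)
        for f in doc.fields)
    policy = UriPolicy() if doc.uri_policy is None else UriPolicy(
        strategy=doc.uri_policy.strategy,
        base_namespace=doc.uri_policy.base_namespace,
        width=doc.uri_policy.width, start=doc.uri_policy.start,
        state_file=doc.uri_policy.state_file)
    return Template(
        name=doc.name, fields=fields, patterns=tuple(parsed_patterns),
        imported_ontologies=tuple(doc.ontologies),
        uri_policy=policy, prefixes=dict(doc.prefixes),
        label_annotation_property=doc.label_annotation_property,
        definition_annotation_property=doc.definition_annotation_property,
        annotation_property_map=dict(doc.annotation_properties),
        annotation_language=doc.annotation_language)


def load_template(path: str | Path) -> Template:
    path = Path(path)
    if not path.exists():
        raise TemplateError(f"template file not found: {path}")
    return loads_template(path.read_text(encoding="utf-8"), str(path))


def _restriction_to_doc(r: Restriction):
    if isinstance(r, FreeText):
        return "free_text"
    if isinstance(r, FixedList):
        return {"type": "fixed_list", "values": list(r.values)}
    return {"type": "dynamic_query", "query": r.query, "mode": r.mode.value}


def template_to_dict(t: Template) -> dict:
    """Canonical dictionary form (stable key order, patterns re-rendered)."""
    out: dict = {"name": t.name}
    if t.imported_ontologies:
        out["ontologies"] = list(t.imported_ontologies)
    if t.prefixes:
        out["prefixes"] = dict(sorted(t.prefixes.items()))
    out["fields"] = [
        {"name": f.name, "variable": f.variable,
         "restriction": _restriction_to_doc(f.restriction),
         "mandatory": f.mandatory, "creates_new_terms": f.creates_new_terms}
        for f in t.fields]
    out["patterns"] = [{"name": p.name, "oppl": pat.render_pattern(p) + "\n"}
                       for p in t.patterns]
    out["uri_policy"] = {
        "strategy": t.uri_policy.strategy,
        "base_namespace": t.uri_policy.base_namespace,
        "width": t.uri_policy.width,
        "start": t.uri_policy.start,
    }
    if t.uri_policy.state_file:
        out["uri_policy"]["state_file"] = t.uri_policy.state_file
    out["label_annotation_property"] = t.label_annotation_property
    out["definition_annotation_property"] = t.definition_annotation_property
    extra = {k: v for k, v in sorted(t.annotation_property_map.items())
             if k not in ("definition", "label")}
    if extra:
        out["annotation_properties"] = extra
    if t.annotation_language:
        out["annotation_language"] = t.annotation_language
    return out


def save_template(t: Template, path: str | Path) -> Path:
    path = Path(path)
    text = yaml.safe_dump(template_to_dict(t), sort_keys=False,
                          allow_unicode=True, default_flow_style=False,
                          width=100)
    path.write_text(text, encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# Index merging, annotation-property resolution
# --------------------------------------------------------------------------

def merge_indices(indices: list[onto.OntologyIndex]) -> onto.OntologyIndex:
    """Union index over several imported ontologies; label collisions across
    sources are recorded like intra-ontology collisions.  Always returns a
    fresh index, so mutating the result never touches the inputs."""
    merged = onto.OntologyIndex()
    for idx in indices:
        merged.classes |= idx.classes
        merged.object_properties |= idx.object_properties
        merged.data_properties |= idx.data_properties
        merged.annotation_properties |= idx.annotation_properties
        merged.individuals |= idx.individuals
        merged.told_subclass_edges |= idx.told_subclass_edges
        merged.complex_superclasses.extend(idx.complex_superclasses)
        merged.annotations |= idx.annotations
        merged.prefixes.update(idx.prefixes)
        merged.warnings.extend(idx.warnings)
        merged.label_of.update(idx.label_of)
    by_norm: dict[str, set[str]] = {}
    for iri, label in merged.label_of.items():
        by_norm.setdefault(onto.normalize_label(label), set()).add(iri)
    for norm, iris in by_norm.items():
        if len(iris) == 1:
            merged.iri_of_label[norm] = next(iter(iris))
        else:
            merged.label_collisions[norm] = tuple(sorted(iris))
    return merged


def resolve_annotation_property(t: Template, index: onto.OntologyIndex,
                                ref: pat.NamedRef) -> str:
    """Resolve an annotation-property reference from a pattern.

    Order: label index / CURIE / IRI, then the template's named-property
    map (``definition`` → the configured textual-definition property,
    ``label`` → the label property)."""
    try:
        return onto.resolve_named_ref(index, ref, t.prefixes)
    except UnknownEntityError:
        mapped = t.annotation_property_map.get(onto.normalize_label(ref.ref))
        if mapped is not None:
            return mapped
        raise


# --------------------------------------------------------------------------
# Linting
# --------------------------------------------------------------------------

def _entity_refs_in_pattern(p: pat.Pattern):
    """Yield (ref, is_annotation_property) for every NamedRef in actions."""

    def walk(expr):
        if isinstance(expr, pat.NamedRef):
            yield expr, False
        elif isinstance(expr, (pat.Some, pat.Only)):
            if isinstance(expr.prop, pat.NamedRef):
                yield expr.prop, False
            yield from walk(expr.filler)
        elif isinstance(expr, (pat.And, pat.Or)):
            for op in expr.operands:
                yield from walk(op)
        elif isinstance(expr, pat.Not):
            yield from walk(expr.operand)

    for action in p.actions:
        if isinstance(action, pat.SubClassOfT):
            yield from walk(action.sub)
            yield from walk(action.sup)
        elif isinstance(action, pat.EquivalentToT):
            yield from walk(action.lhs)
            yield from walk(action.rhs)
        elif isinstance(action, pat.AnnotationT):
            yield action.prop, True
        elif isinstance(action, pat.ClassAssertionT):
            yield from walk(action.type_expr)


def lint_template(t: Template,
                  index: onto.OntologyIndex | None = None) -> list[LintIssue]:
    """Static checks linking fields, pattern variables and the ontology.

    *index* is the union index of the template's imported ontologies; when
    None, entity-reference checks are skipped.
    """
    issues: list[LintIssue] = []
    kinds = t.variable_kinds()

    for p in t.patterns:
        for decl in p.variables:
            if kinds[decl.name] is not decl.kind:
                issues.append(LintIssue(
                    "error", "conflicting-variable-kind",
                    f"variable ?{decl.name} declared as {decl.kind.name} in "
                    f"pattern {p.name!r} but as {kinds[decl.name].name} "
                    "elsewhere"))

    bound_by: dict[str, list[str]] = {}
    for f in t.fields:
        bound_by.setdefault(f.variable, []).append(f.name)
    for var, field_names in bound_by.items():
        if len(field_names) > 1:
            issues.append(LintIssue(
                "error", "duplicate-binding",
                f"variable ?{var} is bound by several fields: "
                f"{', '.join(field_names)}"))
        if var not in kinds:
            issues.append(LintIssue(
                "error", "dangling-binding",
                f"field {field_names[0]!r} is bound to variable ?{var}, "
                "which no pattern declares"))

    all_free: set[str] = set()
    for p in t.patterns:
        free = pat.free_variables(p)
        all_free |= free
        for name in sorted(pat.unused_variables(p)):
            issues.append(LintIssue(
                "warning", "unused-variable",
                f"pattern {p.name!r} declares ?{name} but never uses it"))
    for name in sorted(all_free - set(bound_by)):
        issues.append(LintIssue(
            "error", "unbound-variable",
            f"no field is bound to pattern variable ?{name}"))

    for f in t.fields:
        kind = kinds.get(f.variable)
        if f.creates_new_terms:
            if not isinstance(f.restriction, FreeText):
                issues.append(LintIssue(
                    "error", "creating-field-restricted",
                    f"field {f.name!r} creates new terms but is not free text"))
            if kind is not None and kind not in (
                    pat.VariableType.CLASS, pat.VariableType.INDIVIDUAL):
                issues.append(LintIssue(
                    "error", "creating-field-kind",
                    f"field {f.name!r} creates new terms but ?{f.variable} "
                    f"is {kind.name}, not CLASS or INDIVIDUAL"))
        if kind is pat.VariableType.CONSTANT and f.mandatory:
            issues.append(LintIssue(
                "info", "mandatory-constant",
                f"mandatory field {f.name!r} feeds CONSTANT ?{f.variable} "
                "used only as an annotation value"))
        if kind is pat.VariableType.CONSTANT and not isinstance(
                f.restriction, FreeText):
            issues.append(LintIssue(
                "warning", "restricted-constant",
                f"field {f.name!r} restricts a CONSTANT variable"))

    if index is not None:
        for p in t.patterns:
            for ref, is_ann in _entity_refs_in_pattern(p):
                try:
                    if is_ann:
                        resolve_annotation_property(t, index, ref)
                    else:
                        onto.resolve_named_ref(index, ref, t.prefixes)
                except UnknownEntityError:
                    issues.append(LintIssue(
                        "error", "unknown-entity",
                        f"pattern {p.name!r} references {ref.ref!r}, which "
                        "resolves to nothing in the imported ontologies"))
                except AmbiguousLabelError as exc:
                    issues.append(LintIssue(
                        "error", "ambiguous-entity", str(exc)))
        for f in t.fields:
            if isinstance(f.restriction, DynamicQuery):
                try:
                    onto.evaluate_dl_query(index, f.restriction.to_dl_query(),
                                           t.prefixes)
                except (UnknownEntityError, AmbiguousLabelError) as exc:
                    issues.append(LintIssue(
                        "error", "invalid-dynamic-query",
                        f"field {f.name!r}: {exc}"))
    return issues


# --------------------------------------------------------------------------
# Validation lists
# --------------------------------------------------------------------------

def build_validation_list(f: Field, index: onto.OntologyIndex,
                          prefixes: dict[str, str] | None = None,
                          cap: int = VALIDATION_LIST_CAP) -> ValidationList:
    """Allowed (label, IRI) entries for a restricted field, sorted by label.

    Entities without labels fall back to their IRI as the display label.
    Lists longer than *cap* are returned whole with a size warning — the
    cap protects client-side autocomplete, it is not a correctness rule.
    """
    if isinstance(f.restriction, FreeText):
        raise TemplateError(
            f"field {f.name!r} is free text; it has no validation list")
    warnings: list[str] = []
    if isinstance(f.restriction, FixedList):
        entries = []
        for value in f.restriction.values:
            res = onto.label_lookup(index, value)
            entries.append((value, res.iri if res.found else None))
    else:
        iris = onto.evaluate_dl_query(index, f.restriction.to_dl_query(),
                                      prefixes)
        entries = [(index.label_of.get(iri, iri), iri) for iri in iris]
    entries.sort(key=lambda e: (onto.normalize_label(e[0]), e[1] or ""))
    if len(entries) > cap:
        warnings.append(
            f"validation list for field {f.name!r} has {len(entries)} "
            f"entries, above the recommended cap of {cap}")
    return ValidationList(entries, warnings)
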