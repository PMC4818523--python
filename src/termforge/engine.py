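"""Submission processing: validate rows, bind cells to pattern variables,
mint IRIs for new terms, instantiate patterns, QC.

The pipeline mirrors a curation workflow: each spreadsheet row supplies one
value per template field; restricted fields must name an existing term
(by primary label, CURIE or IRI); free-text fields flagged
``creates_new_terms`` mint a fresh IRI for any label the source ontology
does not know, with one IRI per normalized label per submission.  Every
pattern is instantiated per row unless one of its variables comes from an
empty optional field, in which case that pattern is skipped for the row.
Axioms from all rows are merged into a single de-duplicated
:class:`~termforge.ontology.AxiomSet` together with Declaration and label
axioms for the minted terms.
"""

from __future__ import annotations

import csv
import json
import random
import uuid
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from . import ontology as onto
from . import patterns as pat
from . import templates as tpl
from .errors import (
    AmbiguousLabelError, MintingError, ProcessingError, SubmissionError,
    TemplateError, UnknownEntityError,
)

__all__ = [
    "Submission", "read_submission", "BoundValue", "Binding",
    "RowIssue", "RowResult", "ProcessingReport", "QCIssue",
    "Minter", "RandomMinter", "IncrementalMinter", "ExternalMinter",
    "make_minter", "mint_uri", "validate_submission", "resolve_cell",
    "instantiate", "process_submission", "qc_axiomset",
]


# --------------------------------------------------------------------------
# Submissions
# --------------------------------------------------------------------------

@dataclass
class Submission:
    header: tuple[str, ...]
    rows: list[dict[str, str]]        # field name -> raw cell text
    source: str = "<memory>"
    submitter: str | None = None

    def __post_init__(self):
        padded = []
        for row in self.rows:
            padded.append({name: row.get(name, "") for name in self.header})
        self.rows = padded


def read_submission(path: str | Path, delimiter: str | None = None) -> Submission:
    """Read a CSV/TSV submission; first row is the header of field names.

    Delimiter defaults by extension (``.tsv`` → tab, else comma).
    """
    path = Path(path)
    if not path.exists():
        raise SubmissionError(f"submission file not found: {path}")
    delim = delimiter or ("\t" if path.suffix.lower() == ".tsv" else ",")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise SubmissionError(f"{path} is empty (no header row)")
        header = tuple(h.strip() for h in header)
        rows = []
        for raw in reader:
            if not any(cell.strip() for cell in raw):
                continue
            raw = list(raw) + [""] * (len(header) - len(raw))
            rows.append({name: raw[i] for i, name in enumerate(header)})
    return Submission(header, rows, source=str(path))


def check_header(t: tpl.Template, s: Submission) -> None:
    expected = {f.name for f in t.fields}
    got = set(s.header)
    if expected != got:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        parts = []
        if missing:
            parts.append(f"missing columns: {', '.join(missing)}")
        if extra:
            parts.append(f"unexpected columns: {', '.join(extra)}")
        raise SubmissionError(
            f"submission header does not match template fields "
            f"({'; '.join(parts)})")


# --------------------------------------------------------------------------
# Minting
# --------------------------------------------------------------------------

class Minter:
    """Mints fresh IRIs under a base namespace.  Implementations must never
    return an IRI present in *known* (source ontology + prior mints)."""

    def mint(self, label: str, known: set[str]) -> str:
        raise NotImplementedError

    def persist(self) -> None:
        """Persist any counter state; no-op by default."""


class RandomMinter(Minter):
    """UUID-based local names.  An explicit ``rng`` makes minting
    reproducible; by default IRIs vary run to run (outputs are then equal
    only up to renaming of minted IRIs)."""

    MAX_RETRIES = 64

    def __init__(self, base_namespace: str, rng: random.Random | None = None):
        self.base_namespace = base_namespace
        self._rng = rng

    def mint(self, label: str, known: set[str]) -> str:
        for _ in range(self.MAX_RETRIES):
            if self._rng is not None:
                u = uuid.UUID(int=self._rng.getrandbits(128), version=4)
            else:
                u = uuid.uuid4()
            iri = f"{self.base_namespace}{u.hex}"
            if iri not in known:
                return iri
        raise MintingError("random minter exhausted retries")


class IncrementalMinter(Minter):
    """Zero-padded incremental local ids; the counter can be persisted to a
    JSON state file so ids keep increasing across runs."""

    def __init__(self, base_namespace: str, width: int = 7, start: int = 1,
                 state_file: str | Path | None = None):
        self.base_namespace = base_namespace
        self.width = width
        self.state_file = Path(state_file) if state_file else None
        self.counter = start
        if self.state_file and self.state_file.exists():
            state = json.loads(self.state_file.read_text(encoding="utf-8"))
            self.counter = max(self.counter, int(state["next"]))

    def mint(self, label: str, known: set[str]) -> str:
        while True:
            if self.counter >= 10 ** self.width:
                raise MintingError(
                    f"incremental id space exhausted (width {self.width})")
            iri = f"{self.base_namespace}{self.counter:0{self.width}d}"
            self.counter += 1
            if iri not in known:
                return iri

    def persist(self) -> None:
        if self.state_file:
            self.state_file.write_text(
                json.dumps({"next": self.counter}) + "\n", encoding="utf-8")


class ExternalMinter(Minter):
    """Delegates to a pluggable callable ``label -> IRI`` (the seam where an
    external id service would plug in)."""

    def __init__(self, mint_fn):
        self._mint_fn = mint_fn

    def mint(self, label: str, known: set[str]) -> str:
        try:
            iri = self._mint_fn(label)
        except Exception as exc:
            raise MintingError(f"external minter failed: {exc}") from exc
        if not isinstance(iri, str) or "://" not in iri and ":" not in iri:
            raise MintingError(f"external minter returned invalid IRI {iri!r}")
        if iri in known:
            raise MintingError(f"external minter returned known IRI {iri}")
        return iri


def make_minter(policy: tpl.UriPolicy, rng: random.Random | None = None,
                external_fn=None) -> Minter:
    if policy.strategy == "incremental":
        return IncrementalMinter(policy.base_namespace, policy.width,
                                 policy.start, policy.state_file)
    if policy.strategy == "external":
        if external_fn is None:
            raise MintingError(
                "uri_policy strategy 'external' requires a minter callable")
        return ExternalMinter(external_fn)
    return RandomMinter(policy.base_namespace, rng)


def mint_uri(minter: Minter, known: set[str], label: str = "") -> str:
    """Mint one fresh IRI, guaranteed absent from *known*; the caller adds
    the result to *known* (this helper does so too for convenience)."""
    iri = minter.mint(label, known)
    known.add(iri)
    return iri


# --------------------------------------------------------------------------
# Binding and per-row results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundValue:
    """An entity binding: the IRI plus whether it was minted this run."""
    iri: str
    is_new: bool = False


@dataclass
class Binding:
    row: int
    values: dict[str, "BoundValue | str"] = dc_field(default_factory=dict)
    skipped_patterns: list[str] = dc_field(default_factory=list)

    def bind(self, variable: str, value: "BoundValue | str") -> None:
        if variable in self.values:
            raise ProcessingError(
                f"variable ?{variable} bound twice in row {self.row}")
        self.values[variable] = value


@dataclass(frozen=True)
class RowIssue:
    row: int                 # 1-based data row (header excluded)
    field: str | None
    message: str

    def __str__(self) -> str:
        where = f"row {self.row}"
        if self.field:
            where += f", field {self.field!r}"
        return f"{where}: {self.message}"


@dataclass
class RowResult:
    row: int
    status: str                             # ok | skipped | error
    messages: list[str] = dc_field(default_factory=list)
    patterns_skipped: list[str] = dc_field(default_factory=list)


@dataclass(frozen=True)
class QCIssue:
    code: str
    message: str
    subjects: tuple[str, ...] = ()

    def __str__(self) -> str:
        return f"{self.code}: {self.message}"


@dataclass
class ProcessingReport:
    rows: list[RowResult] = dc_field(default_factory=list)
    axioms_generated: int = 0
    new_terms_minted: int = 0
    qc_issues: list[QCIssue] = dc_field(default_factory=list)
    warnings: list[str] = dc_field(default_factory=list)
    mode: str = "fail-fast"
    aborted: bool = False

    @property
    def rows_processed(self) -> int:
        return len(self.rows)

    @property
    def rows_ok(self) -> int:
        return sum(1 for r in self.rows if r.status == "ok")

    @property
    def rows_error(self) -> int:
        return sum(1 for r in self.rows if r.status == "error")

    @property
    def rows_skipped(self) -> int:
        return sum(1 for r in self.rows if r.status == "skipped")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "aborted": self.aborted,
            "counts": {
                "rows_processed": self.rows_processed,
                "rows_ok": self.rows_ok,
                "rows_error": self.rows_error,
                "rows_skipped": self.rows_skipped,
                "axioms_generated": self.axioms_generated,
                "new_terms_minted": self.new_terms_minted,
            },
            "rows": [
                {"row": r.row, "status": r.status, "messages": r.messages,
                 "patterns_skipped": r.patterns_skipped}
                for r in self.rows],
            "qc_issues": [
                {"code": q.code, "message": q.message,
                 "subjects": list(q.subjects)}
                for q in self.qc_issues],
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def validation_lists(t: tpl.Template,
                     index: onto.OntologyIndex) -> dict[str, tpl.ValidationList]:
    return {
        f.name: tpl.build_validation_list(f, index, t.prefixes)
        for f in t.fields if not isinstance(f.restriction, tpl.FreeText)}


def validate_submission(t: tpl.Template, s: Submission,
                        index: onto.OntologyIndex,
                        lists: dict[str, tpl.ValidationList] | None = None,
                        ) -> list[RowIssue]:
    """Side-effect-free per-row validation.

    A row fails when a mandatory field is empty or a restricted field's
    value is not in the field's validation list (by normalized label,
    CURIE or IRI).
    """
    check_header(t, s)
    if lists is None:
        lists = validation_lists(t, index)
    issues: list[RowIssue] = []
    for rowno, row in enumerate(s.rows, start=1):
        for f in t.fields:
            value = row.get(f.name, "").strip()
            if not value:
                if f.mandatory:
                    issues.append(RowIssue(
                        rowno, f.name,
                        f"mandatory field {f.name!r} is empty"))
                continue
            vlist = lists.get(f.name)
            if vlist is not None and not vlist.contains(index, value):
                issues.append(RowIssue(
                    rowno, f.name,
                    f"value {value!r} is not in the allowed list for "
                    f"field {f.name!r}"))
    return issues


# --------------------------------------------------------------------------
# Cell resolution and pattern instantiation
# --------------------------------------------------------------------------

def resolve_cell(value: str, f: tpl.Field, index: onto.OntologyIndex,
                 minter: Minter, mint_cache: dict[str, str],
                 known: set[str], axset: onto.AxiomSet,
                 t: tpl.Template, kind: pat.VariableType,
                 row: int = -1) -> BoundValue:
    """Resolve one entity-field cell to a bound IRI.

    Existing labels/CURIEs/IRIs reuse the existing IRI; unknown labels on a
    creating field mint (one IRI per normalized label per submission, via
    *mint_cache*) and add Declaration + label axioms; unknown values on a
    non-creating field are errors.
    """
    text = value.strip()
    res = onto.label_lookup(index, text)
    if res.status is onto.ResolutionStatus.AMBIGUOUS:
        raise AmbiguousLabelError(text, res.candidates)
    if res.found:
        return BoundValue(res.iri, is_new=False)
    if not f.creates_new_terms:
        raise UnknownEntityError(
            text, f"value {text!r} does not name a known term and field "
            f"{f.name!r} does not create new terms")
    norm = onto.normalize_label(text)
    cached = mint_cache.get(norm)
    if cached is not None:
        return BoundValue(cached, is_new=True)
    iri = mint_uri(minter, known, text)
    mint_cache[norm] = iri
    entity_kind = (onto.EntityKind.NAMED_INDIVIDUAL
                   if kind is pat.VariableType.INDIVIDUAL
                   else onto.EntityKind.CLASS)
    axset.add(onto.Declaration(iri, entity_kind), row, "<new-term>")
    axset.add(onto.AnnotationAssertion(
        iri, t.label_annotation_property,
        onto.OwlLiteral(text, lang=t.annotation_language)), row, "<new-term>")
    axset.record_new_term(iri, text)
    return BoundValue(iri, is_new=True)


def _ground_expr(expr: pat.ClassExpression, binding: Binding,
                 index: onto.OntologyIndex, t: tpl.Template) -> onto.ClassExpr:
    if isinstance(expr, pat.VarRef):
        value = binding.values.get(expr.name)
        if value is None:
            raise ProcessingError(
                f"variable ?{expr.name} is unbound in row {binding.row}")
        if not isinstance(value, BoundValue):
            raise ProcessingError(
                f"CONSTANT ?{expr.name} used where an entity is required")
        return onto.Named(value.iri)
    if isinstance(expr, pat.NamedRef):
        return onto.Named(onto.resolve_named_ref(index, expr, t.prefixes))
    if isinstance(expr, (pat.Some, pat.Only)):
        if isinstance(expr.prop, pat.VarRef):
            prop_val = binding.values.get(expr.prop.name)
            if not isinstance(prop_val, BoundValue):
                raise ProcessingError(
                    f"property variable ?{expr.prop.name} is unbound or "
                    "bound to a literal")
            prop = prop_val.iri
        else:
            prop = onto.resolve_named_ref(index, expr.prop, t.prefixes)
        filler = _ground_expr(expr.filler, binding, index, t)
        cls = onto.SomeValues if isinstance(expr, pat.Some) else onto.OnlyValues
        return cls(prop, filler)
    if isinstance(expr, pat.And):
        return onto.intersection_of(
            _ground_expr(op, binding, index, t) for op in expr.operands)
    if isinstance(expr, pat.Or):
        return onto.union_of(
            _ground_expr(op, binding, index, t) for op in expr.operands)
    if isinstance(expr, pat.Not):
        return onto.ComplementOf(_ground_expr(expr.operand, binding, index, t))
    raise TypeError(f"unknown expression {expr!r}")


def instantiate(p: pat.Pattern, binding: Binding, t: tpl.Template,
                index: onto.OntologyIndex) -> list[onto.Axiom]:
    """Instantiate every ADD action of *p* under *binding*; one axiom per
    action, with every variable replaced by its bound value."""
    missing = sorted(n for n in pat.free_variables(p)
                     if n not in binding.values)
    if missing:
        raise ProcessingError(
            f"pattern {p.name!r} has unbound variables in row "
            f"{binding.row}: " + ", ".join(f"?{n}" for n in missing))
    out: list[onto.Axiom] = []
    for action in p.actions:
        if isinstance(action, pat.SubClassOfT):
            out.append(onto.SubClassOf(
                _ground_expr(action.sub, binding, index, t),
                _ground_expr(action.sup, binding, index, t)))
        elif isinstance(action, pat.EquivalentToT):
            out.append(onto.EquivalentClasses(
                _ground_expr(action.lhs, binding, index, t),
                _ground_expr(action.rhs, binding, index, t)))
        elif isinstance(action, pat.AnnotationT):
            subject = binding.values.get(action.subject.name)
            if not isinstance(subject, BoundValue):
                raise ProcessingError(
                    f"annotation subject ?{action.subject.name} is unbound "
                    "or bound to a literal")
            prop = tpl.resolve_annotation_property(t, index, action.prop)
            if isinstance(action.value, pat.VarRef):
                raw = binding.values.get(action.value.name)
                if not isinstance(raw, str):
                    raise ProcessingError(
                        f"annotation value ?{action.value.name} must be "
                        "bound to a literal")
                text = raw
            else:
                text = action.value.text
            out.append(onto.AnnotationAssertion(
                subject.iri, prop,
                onto.OwlLiteral(text, lang=t.annotation_language)))
        elif isinstance(action, pat.ClassAssertionT):
            ind = binding.values.get(action.individual.name)
            if not isinstance(ind, BoundValue):
                raise ProcessingError(
                    f"class-assertion subject ?{action.individual.name} is "
                    "unbound or bound to a literal")
            out.append(onto.ClassAssertion(
                _ground_expr(action.type_expr, binding, index, t), ind.iri))
        else:
            raise TypeError(f"unknown action {action!r}")
    return out


# --------------------------------------------------------------------------
# Whole-submission processing
# --------------------------------------------------------------------------

def process_submission(t: tpl.Template, s: Submission,
                       index: onto.OntologyIndex,
                       mode: str = "fail-fast",
                       minter: Minter | None = None,
                       rng: random.Random | None = None,
                       run_qc: bool = True,
                       ) -> tuple[onto.AxiomSet, ProcessingReport]:
    """Run the full per-row pipeline and collect one axiom set.

    ``mode="fail-fast"`` (default): any row error aborts — the returned
    axiom set is empty and ``report.aborted`` is True.  ``mode="partial"``:
    error rows are reported and contribute nothing; valid rows are
    processed.
    """
    if mode not in ("fail-fast", "partial"):
        raise ProcessingError(f"unknown mode {mode!r}")
    lint_errors = [i for i in tpl.lint_template(t, index) if i.level == "error"]
    if lint_errors:
        raise TemplateError(
            "template does not lint cleanly: "
            + "; ".join(str(i) for i in lint_errors))
    check_header(t, s)

    report = ProcessingReport(mode=mode)
    lists = validation_lists(t, index)
    for vlist in lists.values():
        report.warnings.extend(vlist.warnings)

    row_issues = validate_submission(t, s, index, lists)
    issues_by_row: dict[int, list[RowIssue]] = {}
    for issue in row_issues:
        issues_by_row.setdefault(issue.row, []).append(issue)

    minter = minter or make_minter(t.uri_policy, rng)
    kinds = t.variable_kinds()
    fields_by_var = {f.variable: f for f in t.fields}

    axset = onto.AxiomSet()
    known = set(index.all_entities())
    mint_cache: dict[str, str] = {}

    def fail_row(rowno: int, messages: list[str]) -> RowResult:
        return RowResult(rowno, "error", messages)

    results: list[RowResult] = []
    had_error = False
    for rowno, row in enumerate(s.rows, start=1):
        if rowno in issues_by_row:
            results.append(fail_row(
                rowno, [str(i) for i in issues_by_row[rowno]]))
            had_error = True
            continue
        binding = Binding(rowno)
        row_messages: list[str] = []
        empty_optional_vars: set[str] = set()
        try:
            for f in t.fields:
                value = row.get(f.name, "").strip()
                kind = kinds.get(f.variable)
                if not value:
                    empty_optional_vars.add(f.variable)
                    continue
                if kind is pat.VariableType.CONSTANT:
                    binding.bind(f.variable, value)
                else:
                    binding.bind(f.variable, resolve_cell(
                        value, f, index, minter, mint_cache, known, axset,
                        t, kind or pat.VariableType.CLASS, rowno))
        except (UnknownEntityError, AmbiguousLabelError, MintingError,
                ProcessingError) as exc:
            results.append(fail_row(rowno, [str(exc)]))
            had_error = True
            continue

        applied = 0
        row_failed = False
        for p in t.patterns:
            free = pat.free_variables(p)
            if free & empty_optional_vars:
                binding.skipped_patterns.append(p.name)
                continue
            try:
                for axiom in instantiate(p, binding, t, index):
                    axset.add(axiom, rowno, p.name)
                applied += 1
            except (UnknownEntityError, AmbiguousLabelError,
                    ProcessingError) as exc:
                results.append(fail_row(rowno, [str(exc)]))
                had_error = True
                row_failed = True
                break
        if row_failed:
            continue
        status = "ok" if applied else "skipped"
        results.append(RowResult(rowno, status, row_messages,
                                 binding.skipped_patterns))

    report.rows = results
    if had_error and mode == "fail-fast":
        report.aborted = True
        empty = onto.AxiomSet()
        report.axioms_generated = 0
        report.new_terms_minted = 0
        return empty, report

    minter.persist()
    report.axioms_generated = len(axset)
    report.new_terms_minted = len(axset.new_terms)
    if run_qc:
        report.qc_issues = qc_axiomset(
            axset, index, definition_property=t.definition_annotation_property)
    return axset, report


# --------------------------------------------------------------------------
# QC
# --------------------------------------------------------------------------

def qc_axiomset(axset: onto.AxiomSet, index: onto.OntologyIndex,
                definition_property: str = onto.IAO_DEFINITION) -> list[QCIssue]:
    """Curator-style checks on a generated axiom set.

    Flags (i) minted labels that duplicate an existing ontology label or
    another minted label, (ii) distinct subjects sharing an identical
    definition literal, (iii) self-subclass axioms.  Pure report — nothing
    is mutated.
    """
    issues: list[QCIssue] = []

    minted_by_norm: dict[str, list[tuple[str, str]]] = {}
    for iri, label in axset.new_terms:
        minted_by_norm.setdefault(onto.normalize_label(label), []).append(
            (iri, label))
    for norm, terms in sorted(minted_by_norm.items()):
        existing = index.iri_of_label.get(norm)
        collisions = index.label_collisions.get(norm, ())
        if existing or collisions:
            others = tuple(sorted(
                set(([existing] if existing else []) + list(collisions))))
            issues.append(QCIssue(
                "duplicate-label",
                f"minted label {terms[0][1]!r} duplicates an existing "
                f"ontology label", tuple(t[0] for t in terms) + others))
        if len(terms) > 1:
            issues.append(QCIssue(
                "duplicate-label",
                f"label {terms[0][1]!r} was minted for several IRIs",
                tuple(sorted(t[0] for t in terms))))

    by_definition: dict[str, set[str]] = {}
    for ax in axset:
        if isinstance(ax, onto.AnnotationAssertion) \
                and ax.prop == definition_property:
            by_definition.setdefault(ax.value.text, set()).add(ax.subject)
    for text, subjects in sorted(by_definition.items()):
        if len(subjects) > 1:
            issues.append(QCIssue(
                "duplicate-definition",
                f"{len(subjects)} distinct terms share the definition "
                f"{text!r}", tuple(sorted(subjects))))

    for ax in axset:
        if isinstance(ax, onto.SubClassOf) \
                and isinstance(ax.sub, onto.Named) \
                and isinstance(ax.sup, onto.Named) \
                and ax.sub.iri == ax.sup.iri:
            issues.append(QCIssue(
                "self-subclass",
                f"class is asserted as a subclass of itself: {ax.sub.iri}",
                (ax.sub.iri,)))
    return issues
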