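"""Parser, renderer and analysis for the OPPL-subset pattern language.

An ontology design pattern is written as a block of typed variable
declarations followed by ``BEGIN ... END;`` containing one or more ``ADD``
actions over Manchester-syntax axiom templates::

    ?cell:CLASS, ?nucleation:CLASS
    BEGIN
    ADD ?cell SubClassOf hasNucleation some ?nucleation
    END;

Only the additive subset of OPPL is supported: ``ADD`` actions producing
subclass axioms, equivalence axioms, class (instance) assertions and
annotation assertions (the ``?x.IRI property ?value`` form).  ``REMOVE`` and
``SELECT`` are rejected with :class:`~termforge.errors.UnsupportedConstructError`.

Keywords are case-insensitive (``SubClassOf`` and ``subClassOf`` are the
same keyword); variable names are case-sensitive.  Whitespace and line
breaks are insignificant between tokens; actions may be separated by
newlines or ``;``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

from .errors import (
    DuplicateDeclarationError,
    PatternSyntaxError,
    UndeclaredVariableError,
    UnsupportedConstructError,
)

__all__ = [
    "VariableType", "VariableDecl", "NamedRef", "VarRef", "Literal",
    "Some", "Only", "And", "Or", "Not",
    "SubClassOfT", "EquivalentToT", "AnnotationT", "ClassAssertionT",
    "Pattern", "parse_pattern", "parse_class_expression", "render_pattern",
    "render_expression", "free_variables",
]


class VariableType(enum.Enum):
    """Kind of a pattern variable.

    ``CONSTANT`` variables bind to literals; every other kind binds to an
    entity IRI.
    """

    CLASS = "CLASS"
    OBJECT_PROPERTY = "OBJECTPROPERTY"
    DATA_PROPERTY = "DATAPROPERTY"
    ANNOTATION_PROPERTY = "ANNOTATIONPROPERTY"
    INDIVIDUAL = "INDIVIDUAL"
    CONSTANT = "CONSTANT"

    @property
    def binds_literal(self) -> bool:
        return self is VariableType.CONSTANT


# Accepted spellings (upper-cased, punctuation stripped) per variable type.
_TYPE_ALIASES = {
    "CLASS": VariableType.CLASS,
    "OBJECTPROPERTY": VariableType.OBJECT_PROPERTY,
    "DATAPROPERTY": VariableType.DATA_PROPERTY,
    "ANNOTATIONPROPERTY": VariableType.ANNOTATION_PROPERTY,
    "INDIVIDUAL": VariableType.INDIVIDUAL,
    "CONSTANT": VariableType.CONSTANT,
}

_CANONICAL_TYPE_NAME = {
    VariableType.CLASS: "CLASS",
    VariableType.OBJECT_PROPERTY: "OBJECTPROPERTY",
    VariableType.DATA_PROPERTY: "DATAPROPERTY",
    VariableType.ANNOTATION_PROPERTY: "ANNOTATIONPROPERTY",
    VariableType.INDIVIDUAL: "INDIVIDUAL",
    VariableType.CONSTANT: "CONSTANT",
}


@dataclass(frozen=True)
class VariableDecl:
    name: str          # stored without the leading "?"
    kind: VariableType


# --------------------------------------------------------------------------
# Class-expression template AST
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NamedRef:
    """Reference to an existing entity: CURIE, full IRI, bare identifier or
    a single-quoted label ('blood cell')."""

    ref: str
    quoted: bool = False  # True when written as a quoted label


@dataclass(frozen=True)
class VarRef:
    name: str


@dataclass(frozen=True)
class Literal:
    """A double-quoted literal value inside a pattern."""

    text: str


@dataclass(frozen=True)
class Some:
    prop: "NamedRef | VarRef"
    filler: "ClassExpression"


@dataclass(frozen=True)
class Only:
    prop: "NamedRef | VarRef"
    filler: "ClassExpression"


@dataclass(frozen=True)
class And:
    operands: tuple["ClassExpression", ...]

    def __post_init__(self):
        if len(self.operands) < 2:
            raise ValueError("And requires >= 2 operands")


@dataclass(frozen=True)
class Or:
    operands: tuple["ClassExpression", ...]

    def __post_init__(self):
        if len(self.operands) < 2:
            raise ValueError("Or requires >= 2 operands")


@dataclass(frozen=True)
class Not:
    operand: "ClassExpression"


ClassExpression = NamedRef | VarRef | Some | Only | And | Or | Not


# --------------------------------------------------------------------------
# Axiom templates and the pattern container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubClassOfT:
    sub: ClassExpression
    sup: ClassExpression


@dataclass(frozen=True)
class EquivalentToT:
    lhs: ClassExpression
    rhs: ClassExpression


@dataclass(frozen=True)
class AnnotationT:
    """``ADD ?subject.IRI property value`` — an annotation assertion on the
    IRI bound to *subject*; value is a CONSTANT variable or quoted literal."""

    subject: VarRef
    prop: NamedRef
    value: "VarRef | Literal"


@dataclass(frozen=True)
class ClassAssertionT:
    """``ADD ?individual Type <class expression>`` — an A-box assertion."""

    individual: VarRef
    type_expr: ClassExpression


AxiomTemplate = SubClassOfT | EquivalentToT | AnnotationT | ClassAssertionT


@dataclass(frozen=True)
class Pattern:
    name: str
    variables: tuple[VariableDecl, ...]
    actions: tuple[AxiomTemplate, ...]

    def declared(self) -> dict[str, VariableType]:
        return {v.name: v.kind for v in self.variables}

    def variable_kind(self, name: str) -> VariableType:
        kinds = self.declared()
        if name not in kinds:
            raise UndeclaredVariableError(name)
        return kinds[name]


# --------------------------------------------------------------------------
# Tokenizer
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Tok:
    kind: str      # VAR, NAME, IRI, SQSTR, DQSTR, PUNCT, EOF
    value: str
    line: int
    col: int


_TOKEN_RE = re.compile(
    r"""
      (?P<ws>\s+)
    | (?P<comment>//[^\n]*)
    | (?P<var>\?[A-Za-z_][A-Za-z0-9_]*(?P<iri_suffix>\.IRI)?)
    | (?P<iri><[^<>\s]+>)
    | (?P<sqstr>'(?:[^'\\]|\\.)*')
    | (?P<dqstr>"(?:[^"\\]|\\.)*")
    | (?P<name>[A-Za-z_][A-Za-z0-9_\-.]*(?::[A-Za-z0-9_\-.]+)?)
    | (?P<punct>[,;:()])
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[_Tok]:
    toks: list[_Tok] = []
    line, col, pos = 1, 1, 0
    n = len(text)
    while pos < n:
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise PatternSyntaxError(
                f"unexpected character {text[pos]!r}", line, col)
        start_line, start_col = line, col
        lexeme = m.group(0)
        newlines = lexeme.count("\n")
        if newlines:
            line += newlines
            col = len(lexeme) - lexeme.rfind("\n")
        else:
            col += len(lexeme)
        pos = m.end()
        if m.lastgroup in ("ws", "comment") or (m.group("ws") or m.group("comment")):
            continue
        if m.group("var"):
            toks.append(_Tok("VAR", m.group("var"), start_line, start_col))
        elif m.group("iri"):
            toks.append(_Tok("IRI", lexeme[1:-1], start_line, start_col))
        elif m.group("sqstr"):
            body = re.sub(r"\\(.)", r"\1", lexeme[1:-1])
            toks.append(_Tok("SQSTR", body, start_line, start_col))
        elif m.group("dqstr"):
            body = re.sub(r"\\(.)", r"\1", lexeme[1:-1])
            toks.append(_Tok("DQSTR", body, start_line, start_col))
        elif m.group("name"):
            toks.append(_Tok("NAME", lexeme, start_line, start_col))
        else:
            toks.append(_Tok("PUNCT", lexeme, start_line, start_col))
    toks.append(_Tok("EOF", "", line, col))
    return toks


_KEYWORDS = {
    "begin", "end", "add", "subclassof", "equivalentto", "some", "only",
    "and", "or", "not", "type", "instanceof",
}
_REJECTED_ACTIONS = {"remove", "select"}


def _is_kw(tok: _Tok, kw: str) -> bool:
    return tok.kind == "NAME" and tok.value.lower() == kw


# --------------------------------------------------------------------------
# Recursive-descent parser
# --------------------------------------------------------------------------

class _Parser:
    def __init__(self, toks: list[_Tok]):
        self.toks = toks
        self.i = 0

    @property
    def cur(self) -> _Tok:
        return self.toks[self.i]

    def advance(self) -> _Tok:
        tok = self.cur
        if tok.kind != "EOF":
            self.i += 1
        return tok

    def fail(self, message: str, *expected: str):
        tok = self.cur
        raise PatternSyntaxError(message, tok.line, tok.col, expected)

    def expect_kw(self, kw: str):
        if not _is_kw(self.cur, kw):
            self.fail(f"found {self.cur.value!r}", kw.upper())
        self.advance()

    def expect_punct(self, p: str):
        if not (self.cur.kind == "PUNCT" and self.cur.value == p):
            self.fail(f"found {self.cur.value!r}", repr(p))
        self.advance()

    # ---- declarations ----

    def parse_declarations(self) -> tuple[VariableDecl, ...]:
        decls: list[VariableDecl] = []
        seen: set[str] = set()
        while not _is_kw(self.cur, "begin"):
            if self.cur.kind == "EOF":
                self.fail("unexpected end of pattern", "BEGIN",
                          "variable declaration")
            if self.cur.kind != "VAR":
                self.fail(f"found {self.cur.value!r}",
                          "variable declaration (?name:TYPE)", "BEGIN")
            var = self.advance()
            if var.value.endswith(".IRI"):
                self.fail("'.IRI' is not allowed in a declaration",
                          "variable declaration (?name:TYPE)")
            name = var.value[1:]
            self.expect_punct(":")
            if self.cur.kind != "NAME":
                self.fail(f"found {self.cur.value!r}", "variable type name")
            type_tok = self.advance()
            key = re.sub(r"[^A-Za-z]", "", type_tok.value).upper()
            if key not in _TYPE_ALIASES:
                raise PatternSyntaxError(
                    f"unknown variable type {type_tok.value!r}",
                    type_tok.line, type_tok.col,
                    tuple(sorted(set(_CANONICAL_TYPE_NAME.values()))))
            if name in seen:
                raise DuplicateDeclarationError(name)
            seen.add(name)
            decls.append(VariableDecl(name, _TYPE_ALIASES[key]))
            if self.cur.kind == "PUNCT" and self.cur.value in (",", ";"):
                self.advance()
        return tuple(decls)

    # ---- actions ----

    def parse_actions(self) -> tuple[AxiomTemplate, ...]:
        actions: list[AxiomTemplate] = []
        while True:
            while self.cur.kind == "PUNCT" and self.cur.value == ";":
                self.advance()
            if _is_kw(self.cur, "end"):
                break
            if self.cur.kind == "EOF":
                self.fail("unexpected end of pattern", "ADD", "END")
            if self.cur.kind == "NAME" and \
                    self.cur.value.lower() in _REJECTED_ACTIONS:
                raise UnsupportedConstructError(
                    f"unsupported OPPL construct {self.cur.value.upper()!r}: "
                    "only ADD actions are supported")
            self.expect_kw("add")
            actions.append(self.parse_axiom())
        self.expect_kw("end")
        return tuple(actions)

    def parse_axiom(self) -> AxiomTemplate:
        # Annotation form: ?var.IRI <property> <value>
        if self.cur.kind == "VAR" and self.cur.value.endswith(".IRI"):
            var = self.advance()
            subject = VarRef(var.value[1:-4])
            prop = self.parse_property_ref()
            value = self.parse_annotation_value()
            return AnnotationT(subject, prop, value)
        lhs = self.parse_expression()
        if _is_kw(self.cur, "subclassof"):
            self.advance()
            return SubClassOfT(lhs, self.parse_expression())
        if _is_kw(self.cur, "equivalentto"):
            self.advance()
            return EquivalentToT(lhs, self.parse_expression())
        if _is_kw(self.cur, "type") or _is_kw(self.cur, "instanceof"):
            if not isinstance(lhs, VarRef):
                self.fail("class-assertion subject must be a variable",
                          "?variable")
            self.advance()
            return ClassAssertionT(lhs, self.parse_expression())
        self.fail(f"found {self.cur.value!r}",
                  "SubClassOf", "EquivalentTo", "Type")

    def parse_property_ref(self) -> NamedRef:
        tok = self.cur
        if tok.kind == "NAME" and tok.value.lower() not in _KEYWORDS:
            self.advance()
            return NamedRef(tok.value)
        if tok.kind == "IRI":
            self.advance()
            return NamedRef(tok.value)
        if tok.kind == "SQSTR":
            self.advance()
            return NamedRef(tok.value, quoted=True)
        self.fail(f"found {tok.value!r}", "annotation property reference")

    def parse_annotation_value(self) -> VarRef | Literal:
        tok = self.cur
        if tok.kind == "VAR":
            if tok.value.endswith(".IRI"):
                self.fail("'.IRI' cannot appear in value position",
                          "?variable", "quoted literal")
            self.advance()
            return VarRef(tok.value[1:])
        if tok.kind == "DQSTR":
            self.advance()
            return Literal(tok.value)
        self.fail(f"found {tok.value!r}", "?variable", "quoted literal")

    # ---- class expressions (Manchester precedence: or < and < unary) ----

    def parse_expression(self) -> ClassExpression:
        operands = [self.parse_and_expression()]
        while _is_kw(self.cur, "or"):
            self.advance()
            operands.append(self.parse_and_expression())
        return operands[0] if len(operands) == 1 else Or(tuple(operands))

    def parse_and_expression(self) -> ClassExpression:
        operands = [self.parse_unary()]
        while _is_kw(self.cur, "and"):
            self.advance()
            operands.append(self.parse_unary())
        return operands[0] if len(operands) == 1 else And(tuple(operands))

    def parse_unary(self) -> ClassExpression:
        if _is_kw(self.cur, "not"):
            self.advance()
            return Not(self.parse_unary())
        primary = self.parse_primary()
        if _is_kw(self.cur, "some") or _is_kw(self.cur, "only"):
            quant = self.advance().value.lower()
            if not isinstance(primary, (NamedRef, VarRef)):
                self.fail("property position requires a name or variable",
                          "property reference")
            filler = self.parse_unary()
            return Some(primary, filler) if quant == "some" \
                else Only(primary, filler)
        return primary

    def parse_primary(self) -> ClassExpression:
        tok = self.cur
        if tok.kind == "PUNCT" and tok.value == "(":
            self.advance()
            inner = self.parse_expression()
            self.expect_punct(")")
            return inner
        if tok.kind == "VAR":
            if tok.value.endswith(".IRI"):
                self.fail("'.IRI' only allowed as annotation subject",
                          "?variable")
            self.advance()
            return VarRef(tok.value[1:])
        if tok.kind == "IRI":
            self.advance()
            return NamedRef(tok.value)
        if tok.kind == "SQSTR":
            self.advance()
            return NamedRef(tok.value, quoted=True)
        if tok.kind == "NAME" and tok.value.lower() not in _KEYWORDS:
            self.advance()
            return NamedRef(tok.value)
        self.fail(f"found {tok.value!r}",
                  "entity name", "?variable", "'('", "NOT")


def parse_pattern(text: str, name: str = "pattern") -> Pattern:
    """Parse pattern source text into a :class:`Pattern`.

    Raises :class:`~termforge.errors.PatternSyntaxError` with position
    information on malformed input, :class:`UndeclaredVariableError` /
    :class:`DuplicateDeclarationError` for variable discipline violations,
    and :class:`UnsupportedConstructError` for REMOVE/SELECT.
    """
    if not text or not text.strip():
        raise PatternSyntaxError("empty pattern source", 1, 1,
                                 ("variable declaration", "BEGIN"))
    parser = _Parser(_tokenize(text))
    variables = parser.parse_declarations()
    parser.expect_kw("begin")
    actions = parser.parse_actions()
    if parser.cur.kind == "PUNCT" and parser.cur.value == ";":
        parser.advance()
    if parser.cur.kind != "EOF":
        parser.fail(f"trailing content {parser.cur.value!r}", "end of input")
    if not actions:
        raise PatternSyntaxError("pattern has no actions", 1, 1, ("ADD",))
    pattern = Pattern(name, variables, actions)
    _check_variable_discipline(pattern)
    return pattern


def parse_class_expression(text: str) -> ClassExpression:
    """Parse a stand-alone Manchester-syntax class expression (used for
    dynamic-query restrictions in templates).  Variables are not allowed."""
    parser = _Parser(_tokenize(text))
    expr = parser.parse_expression()
    if parser.cur.kind != "EOF":
        parser.fail(f"trailing content {parser.cur.value!r}", "end of input")
    for var in sorted(_collect_vars_expr(expr)):
        raise UndeclaredVariableError(var)
    return expr


def _collect_vars_expr(expr: ClassExpression) -> set[str]:
    if isinstance(expr, VarRef):
        return {expr.name}
    if isinstance(expr, (Some, Only)):
        out = _collect_vars_expr(expr.filler)
        if isinstance(expr.prop, VarRef):
            out |= {expr.prop.name}
        return out
    if isinstance(expr, (And, Or)):
        out: set[str] = set()
        for op in expr.operands:
            out |= _collect_vars_expr(op)
        return out
    if isinstance(expr, Not):
        return _collect_vars_expr(expr.operand)
    return set()


def _collect_vars_action(action: AxiomTemplate) -> set[str]:
    if isinstance(action, SubClassOfT):
        return _collect_vars_expr(action.sub) | _collect_vars_expr(action.sup)
    if isinstance(action, EquivalentToT):
        return _collect_vars_expr(action.lhs) | _collect_vars_expr(action.rhs)
    if isinstance(action, AnnotationT):
        out = {action.subject.name}
        if isinstance(action.value, VarRef):
            out.add(action.value.name)
        return out
    if isinstance(action, ClassAssertionT):
        return {action.individual.name} | _collect_vars_expr(action.type_expr)
    raise TypeError(f"unknown action {action!r}")


def _check_variable_discipline(p: Pattern) -> None:
    declared = p.declared()
    for action in p.actions:
        for name in sorted(_collect_vars_action(action)):
            if name not in declared:
                raise UndeclaredVariableError(name)
        if isinstance(action, AnnotationT):
            kind = declared[action.subject.name]
            if kind not in (VariableType.CLASS, VariableType.INDIVIDUAL):
                raise PatternSyntaxError(
                    f"annotation subject ?{action.subject.name} must be a "
                    f"CLASS or INDIVIDUAL variable, not {kind.name}", 1, 1)
            if isinstance(action.value, VarRef):
                vkind = declared[action.value.name]
                if vkind is not VariableType.CONSTANT:
                    raise PatternSyntaxError(
                        f"annotation value ?{action.value.name} must be a "
                        f"CONSTANT variable, not {vkind.name}", 1, 1)


# --------------------------------------------------------------------------
# Analysis
# --------------------------------------------------------------------------

def free_variables(p: Pattern) -> set[str]:
    """Declared variable names actually referenced in the pattern's actions.

    Declarations never used by any action are *not* included; template
    linting reports those as unused.
    """
    used: set[str] = set()
    for action in p.actions:
        used |= _collect_vars_action(action)
    return used


def unused_variables(p: Pattern) -> set[str]:
    return set(p.declared()) - free_variables(p)


# --------------------------------------------------------------------------
# Canonical renderer
# --------------------------------------------------------------------------

_NAME_OK_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_\-.]*(?::[A-Za-z0-9_\-.]+)?$")


def _render_named(ref: NamedRef) -> str:
    if ref.quoted:
        return "'" + ref.ref.replace("\\", "\\\\").replace("'", "\\'") + "'"
    if _NAME_OK_RE.match(ref.ref) and ref.ref.lower() not in _KEYWORDS:
        return ref.ref
    return f"<{ref.ref}>"


def render_expression(expr: ClassExpression) -> str:
    """Canonical Manchester-syntax text for a class expression.

    Nested boolean operands and quantifier fillers are parenthesised so the
    output reparses unambiguously to the same AST.
    """
    if isinstance(expr, NamedRef):
        return _render_named(expr)
    if isinstance(expr, VarRef):
        return f"?{expr.name}"
    if isinstance(expr, (Some, Only)):
        kw = "some" if isinstance(expr, Some) else "only"
        prop = _render_named(expr.prop) if isinstance(expr.prop, NamedRef) \
            else f"?{expr.prop.name}"
        return f"{prop} {kw} {_render_operand(expr.filler)}"
    if isinstance(expr, And):
        return " and ".join(_render_operand(o) for o in expr.operands)
    if isinstance(expr, Or):
        return " or ".join(_render_operand(o) for o in expr.operands)
    if isinstance(expr, Not):
        return f"not {_render_operand(expr.operand)}"
    raise TypeError(f"unknown expression {expr!r}")


def _render_operand(expr: ClassExpression) -> str:
    # Anything compound is parenthesised in operand/filler position.
    if isinstance(expr, (NamedRef, VarRef)):
        return render_expression(expr)
    return f"({render_expression(expr)})"


def _render_action(action: AxiomTemplate) -> str:
    if isinstance(action, SubClassOfT):
        return (f"ADD {render_expression(action.sub)} SubClassOf "
                f"{render_expression(action.sup)}")
    if isinstance(action, EquivalentToT):
        return (f"ADD {render_expression(action.lhs)} EquivalentTo "
                f"{render_expression(action.rhs)}")
    if isinstance(action, AnnotationT):
        if isinstance(action.value, VarRef):
            value = f"?{action.value.name}"
        else:
            esc = action.value.text.replace("\\", "\\\\").replace('"', '\\"')
            value = f'"{esc}"'
        return (f"ADD ?{action.subject.name}.IRI "
                f"{_render_named(action.prop)} {value}")
    if isinstance(action, ClassAssertionT):
        return (f"ADD ?{action.individual.name} Type "
                f"{render_expression(action.type_expr)}")
    raise TypeError(f"unknown action {action!r}")


def render_pattern(p: Pattern) -> str:
    """Canonical source text; ``parse_pattern(render_pattern(p))`` equals
    ``p`` structurally (up to the pattern name, which lives outside the
    source)."""
    lines = [f"?{v.name}:{_CANONICAL_TYPE_NAME[v.kind]}" for v in p.variables]
    lines.append("BEGIN")
    lines.extend(_render_action(a) for a in p.actions)
    lines.append("END;")
    return "\n".join(lines)
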