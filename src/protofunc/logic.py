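"""Propositional core of the protein specification-rule language.

Protein specification rules are written as premises of a small
predicate-logic fragment: atoms apply a fixed vocabulary of protein
predicates (structure, folding, function, sequence, binding,
interaction, complex formation) to protein and ligand symbols, and are
combined with negation, conjunction, disjunction and implication.
Rule variables (e.g. ``Px``, ``Py``, ``Ly``) are implicitly universally
quantified and are instantiated ("grounded") with the concrete protein
and ligand constants extracted from text.

The concrete syntax is ASCII: ``~`` for negation, ``&`` for
conjunction, ``|`` for disjunction, ``->`` for implication (the Unicode
glyphs are accepted as synonyms).  Precedence is ``~`` > ``&`` > ``|``
> ``->``; implication is right-associative; parentheses override.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PROTEIN",
    "LIGAND",
    "SIGNATURES",
    "ConstantSymbol",
    "Variable",
    "Formula",
    "Atom",
    "Not",
    "And",
    "Or",
    "Imp",
    "Falsum",
    "FALSE",
    "SpecificationRule",
    "Substitution",
    "LogicError",
    "ParseError",
    "SortError",
    "parse_formula",
    "parse_atom",
    "parse_rule_file",
    "serialize",
    "apply_substitution",
    "formula_variables",
    "formula_constants",
    "is_ground",
    "match_instance",
    "ground_rules",
    "admissible_substitutions",
    "subformula_closure",
    "immediate_subformulas",
]

# ---------------------------------------------------------------------------
# Sorts and predicate signatures
# ---------------------------------------------------------------------------

PROTEIN = "protein"
LIGAND = "ligand"

#: Fixed arity/sort signature of every predicate in the vocabulary:
#: ST structure, FD folding, F function, AAS amino-acid sequence,
#: CBND covalent protein-ligand bond, PPI protein-protein interaction,
#: NCBND non-covalent protein-protein bond, PCF protein complex of functions.
SIGNATURES: dict[str, tuple[str, ...]] = {
    "ST": (PROTEIN,),
    "FD": (PROTEIN,),
    "F": (PROTEIN,),
    "AAS": (PROTEIN,),
    "CBND": (PROTEIN, LIGAND),
    "PPI": (PROTEIN, PROTEIN),
    "NCBND": (PROTEIN, PROTEIN),
    "PCF": (PROTEIN, PROTEIN),
}


class LogicError(ValueError):
    """Base class for errors raised by the logic layer."""


class ParseError(LogicError):
    """Syntax error in the rule DSL; carries a character position."""

    def __init__(self, message: str, position: int, line: int | None = None):
        loc = f" (line {line})" if line is not None else ""
        super().__init__(f"{message} at position {position}{loc}")
        self.position = position
        self.line = line


class SortError(LogicError):
    """A symbol is used with an inconsistent or wrong sort."""


# ---------------------------------------------------------------------------
# Terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class ConstantSymbol:
    """A concrete protein or ligand name extracted from text."""

    name: str
    sort: str = PROTEIN

    def __post_init__(self) -> None:
        if not self.name:
            raise LogicError("constant name must be non-empty")
        if self.sort not in (PROTEIN, LIGAND):
            raise SortError(f"unknown sort {self.sort!r}")


@dataclass(frozen=True, order=True)
class Variable:
    """A universally quantified rule variable (``Px``, ``Ly``...)."""

    name: str
    sort: str = PROTEIN

    def __post_init__(self) -> None:
        if not self.name:
            raise LogicError("variable name must be non-empty")
        if self.sort not in (PROTEIN, LIGAND):
            raise SortError(f"unknown sort {self.sort!r}")


Term = ConstantSymbol | Variable


# ---------------------------------------------------------------------------
# Formulas
# ---------------------------------------------------------------------------


class Formula:
    """Base class; all nodes are frozen dataclasses with structural equality."""

    __slots__ = ()


@dataclass(frozen=True)
class Atom(Formula):
    predicate: str
    args: tuple[Term, ...]

    def __post_init__(self) -> None:
        sig = SIGNATURES.get(self.predicate)
        if sig is None:
            raise LogicError(f"unknown predicate {self.predicate!r}")
        if len(self.args) != len(sig):
            raise LogicError(
                f"{self.predicate} expects {len(sig)} argument(s), got {len(self.args)}"
            )
        for term, want in zip(self.args, sig):
            if term.sort != want:
                raise SortError(
                    f"{self.predicate} argument {term.name!r} has sort "
                    f"{term.sort!r}, expected {want!r}"
                )


@dataclass(frozen=True)
class Not(Formula):
    operand: Formula


@dataclass(frozen=True)
class And(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Or(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Imp(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Falsum(Formula):
    """The always-false constant (used by the Contradiction rule)."""


FALSE = Falsum()


def immediate_subformulas(f: Formula) -> tuple[Formula, ...]:
    if isinstance(f, (And, Or, Imp)):
        return (f.left, f.right)
    if isinstance(f, Not):
        return (f.operand,)
    return ()


def subformula_closure(formulas: Iterable[Formula]) -> frozenset[Formula]:
    """Smallest superset of *formulas* closed under immediate subformulas."""
    seen: set[Formula] = set()
    stack = list(formulas)
    while stack:
        f = stack.pop()
        if f in seen:
            continue
        seen.add(f)
        stack.extend(immediate_subformulas(f))
    return frozenset(seen)


def formula_variables(f: Formula) -> frozenset[Variable]:
    out: set[Variable] = set()
    for g in subformula_closure([f]):
        if isinstance(g, Atom):
            out.update(t for t in g.args if isinstance(t, Variable))
    return frozenset(out)


def formula_constants(f: Formula) -> frozenset[ConstantSymbol]:
    out: set[ConstantSymbol] = set()
    for g in subformula_closure([f]):
        if isinstance(g, Atom):
            out.update(t for t in g.args if isinstance(t, ConstantSymbol))
    return frozenset(out)


def is_ground(f: Formula) -> bool:
    return not formula_variables(f)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_PREC = {Imp: 1, Or: 2, And: 3, Not: 4}


def serialize(f: Formula) -> str:
    """Canonical ASCII form; ``parse_formula`` round-trips it.

    Nested implications are parenthesised explicitly (the customary way
    the premises are printed), e.g. ``FD(Px) -> (ST(Px) -> F(Px))``.
    """
    if isinstance(f, Atom):
        return f"{f.predicate}({', '.join(t.name for t in f.args)})"
    if isinstance(f, Falsum):
        return "False"
    if isinstance(f, Not):
        return "~" + _wrap(f.operand, minimum=4)
    if isinstance(f, And):
        return _wrap(f.left, 3) + " & " + _wrap(f.right, 4)
    if isinstance(f, Or):
        return _wrap(f.left, 2) + " | " + _wrap(f.right, 3)
    if isinstance(f, Imp):
        return _wrap(f.left, 2) + " -> " + _wrap(f.right, 2)
    raise TypeError(f"not a formula: {f!r}")


def _wrap(f: Formula, minimum: int) -> str:
    s = serialize(f)
    if _PREC.get(type(f), 5) < minimum:
        return "(" + s + ")"
    return s


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<arrow>->|→)|(?P<and>&|∧)|(?P<or>\||∨)|(?P<not>~|¬)"
    r"|(?P<lpar>\()|(?P<rpar>\))|(?P<comma>,)|(?P<name>[A-Za-z_][A-Za-z0-9_]*))"
)


def _tokenize(text: str, line: int | None) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ParseError(f"unexpected character {stripped[0]!r}", pos, line)
        kind = m.lastgroup
        assert kind is not None
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    """Recursive-descent parser for the rule DSL.

    *default_kind* controls how bare argument names are interpreted:
    ``"variable"`` for rule files, ``"constant"`` for ground input.  The
    sort of a new symbol comes from the predicate-signature slot it first
    occupies; reuse with a conflicting sort is an error.
    """

    def __init__(
        self,
        text: str,
        *,
        default_kind: str = "variable",
        symbols: Mapping[str, Term] | None = None,
        line: int | None = None,
    ):
        self.tokens = _tokenize(text, line)
        self.i = 0
        self.default_kind = default_kind
        self.symbols: dict[str, Term] = dict(symbols or {})
        self.line = line

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.i]

    def next(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str) -> tuple[str, str, int]:
        tok = self.next()
        if tok[0] != kind:
            raise ParseError(f"expected {kind!r}, found {tok[1]!r}", tok[2], self.line)
        return tok

    # grammar: imp := or ('->' imp)? ; or := and ('|' and)* ;
    #          and := neg ('&' neg)* ; neg := '~' neg | primary
    def parse(self) -> Formula:
        f = self.implication()
        tok = self.peek()
        if tok[0] != "eof":
            raise ParseError(f"trailing input {tok[1]!r}", tok[2], self.line)
        return f

    def implication(self) -> Formula:
        left = self.disjunction()
        if self.peek()[0] == "arrow":
            self.next()
            return Imp(left, self.implication())
        return left

    def disjunction(self) -> Formula:
        f = self.conjunction()
        while self.peek()[0] == "or":
            self.next()
            f = Or(f, self.conjunction())
        return f

    def conjunction(self) -> Formula:
        f = self.negation()
        while self.peek()[0] == "and":
            self.next()
            f = And(f, self.negation())
        return f

    def negation(self) -> Formula:
        if self.peek()[0] == "not":
            self.next()
            return Not(self.negation())
        return self.primary()

    def primary(self) -> Formula:
        tok = self.next()
        if tok[0] == "lpar":
            f = self.implication()
            self.expect("rpar")
            return f
        if tok[0] == "name":
            if tok[1] == "False":
                return FALSE
            return self.atom(tok)
        raise ParseError(f"unexpected token {tok[1]!r}", tok[2], self.line)

    def atom(self, name_tok: tuple[str, str, int]) -> Atom:
        predicate = name_tok[1]
        if predicate not in SIGNATURES:
            raise ParseError(f"unknown predicate {predicate!r}", name_tok[2], self.line)
        self.expect("lpar")
        sig = SIGNATURES[predicate]
        args: list[Term] = []
        for slot, want_sort in enumerate(sig):
            if slot:
                self.expect("comma")
            tok = self.expect("name")
            args.append(self._term(tok, want_sort))
        self.expect("rpar")
        return Atom(predicate, tuple(args))

    def _term(self, tok: tuple[str, str, int], want_sort: str) -> Term:
        name = tok[1]
        sym = self.symbols.get(name)
        if sym is None:
            cls = Variable if self.default_kind == "variable" else ConstantSymbol
            sym = cls(name, want_sort)
            self.symbols[name] = sym
        elif sym.sort != want_sort:
            raise SortError(
                f"symbol {name!r} used with sort {want_sort!r} but declared "
                f"{sym.sort!r}"
            )
        return sym


def parse_formula(
    text: str,
    *,
    default_kind: str = "variable",
    symbols: Mapping[str, Term] | None = None,
) -> Formula:
    """Parse a single DSL formula.

    By default bare argument names become :class:`Variable` (rule-file
    convention); pass ``default_kind="constant"`` for ground input, or
    pre-declare names via *symbols*.
    """
    return _Parser(text, default_kind=default_kind, symbols=symbols).parse()


def parse_atom(text: str, *, symbols: Mapping[str, Term] | None = None) -> Atom:
    """Parse a ground atom such as ``FD(P53)``; arguments become constants."""
    f = parse_formula(text, default_kind="constant", symbols=symbols)
    if not isinstance(f, Atom):
        raise LogicError(f"expected an atom, got {serialize(f)!r}")
    return f


# ---------------------------------------------------------------------------
# Specification rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecificationRule:
    """A named premise of the rule base, e.g. ``R1: FD(Px) -> (ST(Px) -> F(Px))``."""

    id: str
    formula: Formula
    note: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise LogicError("rule id must be non-empty")


_RULE_LINE_RE = re.compile(r"^\s*(?P<id>[A-Za-z_][A-Za-z0-9_]*)\s*:\s*(?P<body>.+)$")


def parse_rule_file(text: str) -> list[SpecificationRule]:
    """Parse a rule file: one ``ID: formula`` per line, ``#`` comments.

    Rules are returned in file order; duplicate ids are an error.
    """
    rules: list[SpecificationRule] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _RULE_LINE_RE.match(line)
        if m is None:
            raise ParseError("expected 'ID: formula'", 0, lineno)
        rid = m.group("id")
        if rid in seen:
            raise LogicError(f"duplicate rule id {rid!r} at line {lineno}")
        seen.add(rid)
        formula = _Parser(m.group("body"), default_kind="variable", line=lineno).parse()
        rules.append(SpecificationRule(rid, formula))
    return rules


# ---------------------------------------------------------------------------
# Substitution and grounding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Substitution:
    """A sort-respecting assignment of rule variables to constants.

    With ``injective=True`` (the default used for grounding) distinct
    variables must map to distinct constants, which rules out degenerate
    self-instantiations of two-protein premises.
    """

    mapping: Mapping[Variable, ConstantSymbol]
    injective: bool = True

    def __post_init__(self) -> None:
        mapping = dict(self.mapping)
        object.__setattr__(self, "mapping", mapping)
        for var, const in mapping.items():
            if var.sort != const.sort:
                raise SortError(
                    f"variable {var.name!r} ({var.sort}) cannot map to "
                    f"constant {const.name!r} ({const.sort})"
                )
        if self.injective:
            targets = list(mapping.values())
            if len(set(targets)) != len(targets):
                raise LogicError("injective substitution maps two variables to one constant")

    def __hash__(self) -> int:
        return hash((frozenset(self.mapping.items()), self.injective))


def apply_substitution(f: Formula, s: Substitution) -> Formula:
    """Replace every variable in *f* per *s*; result must be ground."""
    if isinstance(f, Atom):
        new_args: list[Term] = []
        for t in f.args:
            if isinstance(t, Variable):
                if t not in s.mapping:
                    raise LogicError(f"unbound variable {t.name!r}")
                new_args.append(s.mapping[t])
            else:
                new_args.append(t)
        return Atom(f.predicate, tuple(new_args))
    if isinstance(f, Not):
        return Not(apply_substitution(f.operand, s))
    if isinstance(f, And):
        return And(apply_substitution(f.left, s), apply_substitution(f.right, s))
    if isinstance(f, Or):
        return Or(apply_substitution(f.left, s), apply_substitution(f.right, s))
    if isinstance(f, Imp):
        return Imp(apply_substitution(f.left, s), apply_substitution(f.right, s))
    return f


def admissible_substitutions(
    f: Formula,
    constants: Iterable[ConstantSymbol],
    *,
    injective: bool = True,
) -> list[Substitution]:
    """All sort-respecting (optionally injective) substitutions for *f*'s
    variables over *constants*, in deterministic lexicographic order."""
    variables = sorted(formula_variables(f))
    pools = []
    by_sort: dict[str, list[ConstantSymbol]] = {PROTEIN: [], LIGAND: []}
    for c in sorted(set(constants)):
        by_sort[c.sort].append(c)
    for v in variables:
        pools.append(by_sort[v.sort])
    out: list[Substitution] = []
    for combo in itertools.product(*pools):
        if injective and len(set(combo)) != len(combo):
            continue
        out.append(Substitution(dict(zip(variables, combo)), injective=injective))
    return out


def ground_rules(
    rules: Sequence[SpecificationRule],
    constants: Iterable[ConstantSymbol],
    *,
    injective: bool = True,
) -> list[tuple[str, Formula]]:
    """Instantiate every rule over *constants*.

    Returns ``(rule id, ground formula)`` pairs, ordered by rule-file
    order then lexicographic constant order.  A rule whose variables
    cannot all be bound (e.g. a ligand rule with no ligand constants)
    simply contributes no instances.
    """
    constants = list(constants)
    out: list[tuple[str, Formula]] = []
    for rule in rules:
        for sub in admissible_substitutions(rule.formula, constants, injective=injective):
            out.append((rule.id, apply_substitution(rule.formula, sub)))
    return out


# ---------------------------------------------------------------------------
# Instance matching (rule schema vs ground formula)
# ---------------------------------------------------------------------------


def match_instance(pattern: Formula, target: Formula) -> dict[Variable, ConstantSymbol] | None:
    """Match a rule schema against a ground formula, modulo commutativity
    of ``&`` and ``|``.

    Rule premises are universally quantified, so a conjunction written in
    either order names the same premise; the strictly directional
    inference-rule patterns do *not* go through this routine.  Returns a
    witnessing substitution mapping or ``None``.
    """

    def go(pat: Formula, tgt: Formula, binding: dict[Variable, ConstantSymbol]):
        if isinstance(pat, Atom):
            if not isinstance(tgt, Atom) or pat.predicate != tgt.predicate:
                return
            b = dict(binding)
            for pt, tt in zip(pat.args, tgt.args):
                if isinstance(pt, Variable):
                    if not isinstance(tt, ConstantSymbol) or pt.sort != tt.sort:
                        return
                    if b.setdefault(pt, tt) != tt:
                        return
                elif pt != tt:
                    return
            yield b
        elif isinstance(pat, Falsum):
            if isinstance(tgt, Falsum):
                yield dict(binding)
        elif isinstance(pat, Not):
            if isinstance(tgt, Not):
                yield from go(pat.operand, tgt.operand, binding)
        elif isinstance(pat, Imp):
            if isinstance(tgt, Imp):
                for b in go(pat.left, tgt.left, binding):
                    yield from go(pat.right, tgt.right, b)
        elif isinstance(pat, (And, Or)):
            if type(pat) is type(tgt):
                for pl, pr in ((pat.left, pat.right), (pat.right, pat.left)):
                    for b in go(pl, tgt.left, binding):
                        yield from go(pr, tgt.right, b)

    for b in go(pattern, target, {}):
        return b
    return None
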