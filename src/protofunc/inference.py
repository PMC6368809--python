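"""Forward-chaining inference engine and natural-deduction proof checker.

Given ground atoms extracted from text ("given premises") and grounded
protein specification rules, the engine repeatedly applies the ten
standard propositional inference rules (Modus Ponens, Modus Tollens,
Simplification, Conjunction, Disjunctive Syllogism, Disjunctive
Amplification, Contradiction, Conditional Proof, Proof by Cases, Law of
Syllogism) until a fixpoint.  A newly derived formula is only admitted
if it lies in the finite subformula-closure universe of the input, which
guarantees termination; every derivation is recorded as a line-numbered
proof that the checker can replay.

A brute-force truth-table entailment oracle is provided for soundness
checking; it is deliberately independent of the chaining code path.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .logic import (
    FALSE,
    And,
    Atom,
    Falsum,
    Formula,
    Imp,
    LogicError,
    Not,
    Or,
    SpecificationRule,
    Substitution,
    apply_substitution,
    formula_constants,
    is_ground,
    match_instance,
    parse_formula,
    serialize,
    subformula_closure,
)

__all__ = [
    "INFERENCE_RULES",
    "Justification",
    "ProofLine",
    "Proof",
    "DerivationResult",
    "apply_inference_rule",
    "forward_chain",
    "derive_function_atoms",
    "check_proof",
    "validate_lines",
    "entails_bruteforce",
    "proof_to_json",
    "proof_from_json",
]

GIVEN = "given"
SPECIFICATION_RULE = "specification_rule"
INFERENCE_RULE = "inference_rule"

#: Canonical rule names and their premise arities.
INFERENCE_RULES: dict[str, int] = {
    "ModusTollens": 2,
    "ModusPonens": 2,
    "Simplification": 1,
    "Conjunction": 2,
    "DisjunctiveSyllogism": 2,
    "DisjunctiveAmplification": 1,
    "Contradiction": 1,
    "ConditionalProof": 2,
    "ProofByCases": 2,
    "LawOfSyllogism": 2,
}

_NAME_ALIASES = {name.lower(): name for name in INFERENCE_RULES}


def _canonical_rule_name(name: str) -> str:
    key = "".join(ch for ch in name.lower() if ch.isalnum())
    if key in _NAME_ALIASES:
        return _NAME_ALIASES[key]
    raise LogicError(f"unknown inference rule {name!r}")


# ---------------------------------------------------------------------------
# Proof data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Justification:
    """Why a proof line holds.

    ``kind`` is ``given``, ``specification_rule`` (with the rule id in
    ``rule_name``) or ``inference_rule`` (with the inference-rule name and
    the 1-based ``antecedents`` it was applied to).
    """

    kind: str
    rule_name: str = ""
    antecedents: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (GIVEN, SPECIFICATION_RULE, INFERENCE_RULE):
            raise LogicError(f"unknown justification kind {self.kind!r}")


@dataclass(frozen=True)
class ProofLine:
    index: int  # 1-based, consecutive
    formula: Formula
    justification: Justification


@dataclass(frozen=True)
class Proof:
    lines: tuple[ProofLine, ...]

    @property
    def conclusion(self) -> Formula:
        return self.lines[-1].formula

    def __len__(self) -> int:
        return len(self.lines)


@dataclass(frozen=True)
class DerivationResult:
    """Everything the forward chainer established."""

    derived: frozenset[Formula]
    proofs: Mapping[Formula, Proof]
    iterations: int


# ---------------------------------------------------------------------------
# The ten inference rules
# ---------------------------------------------------------------------------


def _rule_conclusions(
    name: str, premises: Sequence[Formula], universe: Iterable[Formula] | None
) -> list[Formula]:
    """All conclusions the named rule licenses from *premises* (syntactic
    pattern matching; empty list when the pattern does not fit)."""
    if name == "ModusPonens":
        p, imp = premises
        if isinstance(imp, Imp) and imp.left == p:
            return [imp.right]
    elif name == "ModusTollens":
        nq, imp = premises
        if isinstance(imp, Imp) and isinstance(nq, Not) and nq.operand == imp.right:
            return [Not(imp.left)]
    elif name == "Simplification":
        (conj,) = premises
        if isinstance(conj, And):
            # both conjuncts, as separate applications
            return [conj.left, conj.right]
    elif name == "Conjunction":
        p, q = premises
        return [And(p, q)]
    elif name == "DisjunctiveSyllogism":
        disj, np_ = premises
        if isinstance(disj, Or) and isinstance(np_, Not) and np_.operand == disj.left:
            return [disj.right]
    elif name == "DisjunctiveAmplification":
        (p,) = premises
        if universe is None:
            return []
        return [Or(p, q) for q in universe]
    elif name == "Contradiction":
        (imp,) = premises
        if (
            isinstance(imp, Imp)
            and isinstance(imp.left, Not)
            and isinstance(imp.right, Falsum)
        ):
            return [imp.left.operand]
    elif name == "ConditionalProof":
        conj, imp = premises
        if (
            isinstance(conj, And)
            and isinstance(imp, Imp)
            and isinstance(imp.right, Imp)
            and imp.left == conj.left
            and imp.right.left == conj.right
        ):
            return [imp.right.right]
    elif name == "ProofByCases":
        a, b = premises
        if isinstance(a, Imp) and isinstance(b, Imp) and a.right == b.right:
            return [Imp(Or(a.left, b.left), a.right)]
    elif name == "LawOfSyllogism":
        a, b = premises
        if isinstance(a, Imp) and isinstance(b, Imp) and a.right == b.left:
            return [Imp(a.left, b.right)]
    return []


def apply_inference_rule(
    rule_name: str,
    premises: Sequence[Formula],
    target: Formula | None = None,
) -> Formula | None:
    """Apply one inference rule to ground premises.

    Returns the conclusion when the premises match the rule's syntactic
    pattern, else ``None``.  For rules with more than one admissible
    conclusion (Simplification's two conjuncts, Disjunctive
    Amplification's free second disjunct) pass the candidate conclusion
    as *target*: it is returned iff the rule licenses it.  Without a
    target, Simplification returns the left conjunct and Disjunctive
    Amplification returns ``None`` (its conclusion is underdetermined).
    """
    name = _canonical_rule_name(rule_name)
    arity = INFERENCE_RULES[name]
    if len(premises) != arity:
        raise LogicError(f"{name} takes {arity} premise(s), got {len(premises)}")
    if target is not None:
        universe: list[Formula] | None = None
        if name == "DisjunctiveAmplification" and isinstance(target, Or):
            universe = [target.right]
        if target in _rule_conclusions(name, premises, universe):
            return target
        return None
    conclusions = _rule_conclusions(name, premises, None)
    return conclusions[0] if conclusions else None


# ---------------------------------------------------------------------------
# Forward chaining
# ---------------------------------------------------------------------------

_RULE_ORDER = list(INFERENCE_RULES)


def forward_chain(
    given: Iterable[Formula],
    rules: Sequence[tuple[str, Formula]],
    max_iterations: int = 100,
) -> DerivationResult:
    """Saturate the given premises and grounded rules under the ten
    inference rules.

    Conclusions are restricted to the subformula closure of the input
    (plus the ``False`` constant), which bounds the otherwise generative
    Conjunction / Disjunctive Amplification rules and forces a fixpoint
    in at most ``|universe|`` iterations.  Derivations are deterministic
    for a fixed input order; the first proof found for a formula wins.
    """
    given = list(given)
    if max_iterations < 1:
        raise LogicError("max_iterations must be >= 1")
    for f in given:
        if not is_ground(f):
            raise LogicError(f"given premise not ground: {serialize(f)}")
    for _, f in rules:
        if not is_ground(f):
            raise LogicError(f"rule instance not ground: {serialize(f)}")

    universe = set(subformula_closure(list(given) + [f for _, f in rules]))
    universe.add(FALSE)
    # Disjunctive Amplification's second disjunct ranges over the universe;
    # only universe disjunctions can be admitted, so index them by left arm.
    ors_by_left: dict[Formula, list[Formula]] = {}
    for f in sorted_universe(universe):
        if isinstance(f, Or):
            ors_by_left.setdefault(f.left, []).append(f)

    log: list[ProofLine] = []
    index_of: dict[Formula, int] = {}  # formula -> 1-based line index

    def add(formula: Formula, justification: Justification) -> None:
        if formula in index_of:
            return
        line = ProofLine(len(log) + 1, formula, justification)
        log.append(line)
        index_of[formula] = line.index

    for f in given:
        add(f, Justification(GIVEN, "given"))
    for rid, f in rules:
        add(f, Justification(SPECIFICATION_RULE, rid))

    iterations = 0
    changed = True
    while changed and iterations < max_iterations:
        iterations += 1
        changed = False
        snapshot = list(log)  # lines existing at pass start
        for name in _RULE_ORDER:
            arity = INFERENCE_RULES[name]
            if arity == 1:
                tuples = ((line,) for line in snapshot)
            else:
                tuples = itertools.product(snapshot, snapshot)
            for prem_lines in tuples:
                prems = [pl.formula for pl in prem_lines]
                if name == "DisjunctiveAmplification":
                    conclusions = ors_by_left.get(prems[0], [])
                else:
                    conclusions = _rule_conclusions(name, prems, None)
                for conclusion in conclusions:
                    if conclusion not in universe or conclusion in index_of:
                        continue
                    add(
                        conclusion,
                        Justification(
                            INFERENCE_RULE,
                            name,
                            tuple(pl.index for pl in prem_lines),
                        ),
                    )
                    changed = True

    derived = frozenset(index_of)
    proofs = {f: _extract_proof(log, index_of[f]) for f in derived}
    return DerivationResult(derived=derived, proofs=proofs, iterations=iterations)


def sorted_universe(universe: set[Formula]) -> list[Formula]:
    return sorted(universe, key=serialize)


def _extract_proof(log: Sequence[ProofLine], goal_index: int) -> Proof:
    """Slice the ancestor closure of one line out of the global log and
    renumber it into a standalone proof."""
    needed: set[int] = set()
    stack = [goal_index]
    while stack:
        i = stack.pop()
        if i in needed:
            continue
        needed.add(i)
        stack.extend(log[i - 1].justification.antecedents)
    ordered = sorted(needed)
    renumber = {old: new for new, old in enumerate(ordered, start=1)}
    lines = []
    for old in ordered:
        src = log[old - 1]
        j = src.justification
        lines.append(
            ProofLine(
                renumber[old],
                src.formula,
                replace(j, antecedents=tuple(renumber[a] for a in j.antecedents)),
            )
        )
    return Proof(tuple(lines))


def derive_function_atoms(
    given: Iterable[Formula],
    rules: Sequence[tuple[str, Formula]],
    max_iterations: int = 100,
) -> dict[Atom, Proof]:
    """Forward-chain and keep only newly derived function atoms ``F(..)``.

    Function atoms already among the given premises are excluded — they
    are explicit knowledge, not inferences.
    """
    given = list(given)
    result = forward_chain(given, rules, max_iterations=max_iterations)
    given_set = set(given)
    out: dict[Atom, Proof] = {}
    for f in sorted_universe(set(result.derived)):
        if isinstance(f, Atom) and f.predicate == "F" and f not in given_set:
            out[f] = result.proofs[f]
    return out


# ---------------------------------------------------------------------------
# Proof checking
# ---------------------------------------------------------------------------


def _line_valid(
    line: ProofLine,
    earlier: Sequence[ProofLine],
    given: set[Formula],
    rules_by_id: Mapping[str, SpecificationRule],
) -> bool:
    j = line.justification
    if j.kind == GIVEN:
        return line.formula in given
    if j.kind == SPECIFICATION_RULE:
        rule = rules_by_id.get(j.rule_name)
        if rule is None:
            return False
        return match_instance(rule.formula, line.formula) is not None
    # inference rule
    if any(a < 1 or a >= line.index for a in j.antecedents):
        return False
    try:
        name = _canonical_rule_name(j.rule_name)
    except LogicError:
        return False
    if len(j.antecedents) != INFERENCE_RULES[name]:
        return False
    prems = [earlier[a - 1].formula for a in j.antecedents]
    # antecedent citations are unordered in the printed derivations
    orders = [prems] if len(prems) == 1 else [prems, prems[::-1]]
    return any(
        apply_inference_rule(name, order, target=line.formula) is not None
        for order in orders
    )


def validate_lines(
    proof: Proof,
    given: Iterable[Formula],
    rules: Sequence[SpecificationRule],
) -> list[bool]:
    """Per-line verdicts for a proof (independent of later lines)."""
    given_set = set(given)
    rules_by_id = {r.id: r for r in rules}
    verdicts = []
    for i, line in enumerate(proof.lines):
        if line.index != i + 1:
            verdicts.append(False)
            continue
        verdicts.append(_line_valid(line, proof.lines[:i], given_set, rules_by_id))
    return verdicts


def check_proof(
    proof: Proof,
    given: Iterable[Formula],
    rules: Sequence[SpecificationRule],
) -> tuple[bool, int | None]:
    """Replay a derivation line by line.

    A line is valid if it is a given premise, a ground instance of a
    named specification rule, or the conclusion of a named inference rule
    applied to earlier lines.  Returns ``(True, None)`` or ``(False,
    first failing 1-based line index)``.
    """
    if not proof.lines:
        raise LogicError("empty proof")
    verdicts = validate_lines(proof, given, rules)
    for i, ok in enumerate(verdicts, start=1):
        if not ok:
            return False, i
    return True, None


# ---------------------------------------------------------------------------
# Truth-table entailment oracle
# ---------------------------------------------------------------------------


def entails_bruteforce(
    premises: Iterable[Formula],
    goal: Formula,
    max_atoms: int = 16,
) -> bool:
    """Classical entailment by exhaustive truth-table enumeration.

    Every atom is treated as an independent proposition; ``False`` is the
    always-false constant.  Raises when more than *max_atoms* distinct
    ground atoms occur (the table has ``2**n`` rows).
    """
    premises = list(premises)
    atoms = sorted(
        {
            f
            for g in premises + [goal]
            for f in subformula_closure([g])
            if isinstance(f, Atom)
        },
        key=serialize,
    )
    n = len(atoms)
    if n > max_atoms:
        raise LogicError(f"{n} atoms exceed the cap of {max_atoms}")
    index = {a: i for i, a in enumerate(atoms)}
    rows = 1 << n
    # column j of `table` is the truth value of atom j in each assignment
    bits = np.arange(rows, dtype=np.uint32)
    table = ((bits[:, None] >> np.arange(max(n, 1))) & 1).astype(bool)[:, :n]

    def ev(f: Formula) -> np.ndarray:
        if isinstance(f, Atom):
            return table[:, index[f]]
        if isinstance(f, Falsum):
            return np.zeros(rows, dtype=bool)
        if isinstance(f, Not):
            return ~ev(f.operand)
        if isinstance(f, And):
            return ev(f.left) & ev(f.right)
        if isinstance(f, Or):
            return ev(f.left) | ev(f.right)
        if isinstance(f, Imp):
            return ~ev(f.left) | ev(f.right)
        raise TypeError(f"not a formula: {f!r}")

    sat = np.ones(rows, dtype=bool)
    for p in premises:
        sat &= ev(p)
    return bool(ev(goal)[sat].all())


# ---------------------------------------------------------------------------
# Proof (de)serialization — JSON lines
# ---------------------------------------------------------------------------


def proof_to_json(proof: Proof) -> str:
    """One JSON object per line: {index, formula, kind, rule, antecedents}."""
    out = []
    for line in proof.lines:
        j = line.justification
        out.append(
            json.dumps(
                {
                    "index": line.index,
                    "formula": serialize(line.formula),
                    "kind": j.kind,
                    "rule": j.rule_name,
                    "antecedents": list(j.antecedents),
                }
            )
        )
    return "\n".join(out) + "\n"


def proof_from_json(text: str) -> Proof:
    lines = []
    for raw in text.splitlines():
        raw = raw.strip()
        if not raw:
            continue
        obj = json.loads(raw)
        formula = parse_formula(obj["formula"], default_kind="constant")
        lines.append(
            ProofLine(
                int(obj["index"]),
                formula,
                Justification(
                    obj["kind"], obj.get("rule", ""), tuple(obj.get("antecedents", []))
                ),
            )
        )
    return Proof(tuple(lines))
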