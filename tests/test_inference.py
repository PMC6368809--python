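"""Inference-rule application, forward chaining, proof checking and the
truth-table entailment oracle."""

import dataclasses

import numpy as np
import pytest

import protofunc as pf
from protofunc.inference import (
    INFERENCE_RULES,
    DerivationResult,
    Justification,
    Proof,
    ProofLine,
    apply_inference_rule,
    check_proof,
    derive_function_atoms,
    entails_bruteforce,
    forward_chain,
    proof_from_json,
    proof_to_json,
    validate_lines,
)
from protofunc.logic import (
    FALSE,
    LIGAND,
    PROTEIN,
    And,
    Atom,
    ConstantSymbol,
    Imp,
    LogicError,
    Not,
    Or,
    Substitution,
    Variable,
    apply_substitution,
    ground_rules,
    serialize,
    subformula_closure,
)

A = ConstantSymbol("A", PROTEIN)
B = ConstantSymbol("B", PROTEIN)
ATP = ConstantSymbol("ATP", LIGAND)

FD_A, ST_A, F_A, AAS_A = (Atom(p, (A,)) for p in ("FD", "ST", "F", "AAS"))
FD_B, ST_B, F_B, AAS_B = (Atom(p, (B,)) for p in ("FD", "ST", "F", "AAS"))


# ---------------------------------------------------------------------------
# The ten inference rules
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "name, premises, conclusion",
    [
        ("ModusPonens", [FD_A, Imp(FD_A, ST_A)], ST_A),
        ("ModusTollens", [Not(ST_A), Imp(FD_A, ST_A)], Not(FD_A)),
        ("Simplification", [And(FD_A, ST_A)], FD_A),
        ("Conjunction", [FD_A, ST_A], And(FD_A, ST_A)),
        ("DisjunctiveSyllogism", [Or(FD_A, ST_A), Not(FD_A)], ST_A),
        ("Contradiction", [Imp(Not(FD_A), FALSE)], FD_A),
        (
            "ConditionalProof",
            [And(FD_A, ST_A), Imp(FD_A, Imp(ST_A, F_A))],
            F_A,
        ),
        (
            "ProofByCases",
            [Imp(FD_A, F_A), Imp(ST_A, F_A)],
            Imp(Or(FD_A, ST_A), F_A),
        ),
        (
            "LawOfSyllogism",
            [Imp(FD_A, ST_A), Imp(ST_A, F_A)],
            Imp(FD_A, F_A),
        ),
    ],
)
def test_inference_rule_patterns(name, premises, conclusion):
    assert apply_inference_rule(name, premises) == conclusion
    # and the rule confirms its own conclusion as a target
    assert apply_inference_rule(name, premises, target=conclusion) == conclusion


def test_simplification_yields_both_conjuncts_via_target():
    conj = And(FD_A, ST_A)
    assert apply_inference_rule("Simplification", [conj], target=ST_A) == ST_A
    assert apply_inference_rule("Simplification", [conj], target=FD_A) == FD_A
    assert apply_inference_rule("Simplification", [conj], target=F_A) is None


def test_disjunctive_amplification_needs_target():
    assert apply_inference_rule("DisjunctiveAmplification", [FD_A]) is None
    target = Or(FD_A, ST_A)
    assert apply_inference_rule("DisjunctiveAmplification", [FD_A], target=target) == target
    # the premise must be the left disjunct, as the pattern is printed
    assert (
        apply_inference_rule("DisjunctiveAmplification", [ST_A], target=target) is None
    )


def test_modus_ponens_pattern_mismatch():
    assert apply_inference_rule("ModusPonens", [ST_A, Imp(FD_A, F_A)]) is None


def test_unknown_rule_and_wrong_arity():
    with pytest.raises(LogicError):
        apply_inference_rule("Abduction", [FD_A])
    with pytest.raises(LogicError):
        apply_inference_rule("ModusPonens", [FD_A])


def test_rule_names_accept_spaced_spelling():
    assert (
        apply_inference_rule("Modus Ponens", [FD_A, Imp(FD_A, ST_A)]) == ST_A
    )
    assert (
        apply_inference_rule("conditional proof", [And(FD_A, ST_A), Imp(FD_A, Imp(ST_A, F_A))])
        == F_A
    )


# ---------------------------------------------------------------------------
# Forward chaining
# ---------------------------------------------------------------------------


def _grounded(rules, constants):
    return ground_rules(rules, constants, injective=True)


def test_forward_chain_folding_structure_yields_function(rules):
    result = forward_chain([FD_A, ST_A], _grounded(rules, {A}))
    assert F_A in result.derived


def test_forward_chain_empty_given_derives_no_atoms(rules):
    grounded = _grounded(rules, {A, B})
    result = forward_chain([], grounded)
    rule_formulas = {f for _, f in grounded}
    assert rule_formulas <= result.derived
    # no new atomic facts can appear without given premises
    derived_atoms = {f for f in result.derived if isinstance(f, Atom)}
    assert derived_atoms == set()


def test_forward_chain_structure_alone_yields_function(rules):
    result = forward_chain([ST_A], _grounded(rules, {A}))
    assert F_A in result.derived


def test_forward_chain_rejects_non_ground(rules):
    px = Variable("Px", PROTEIN)
    with pytest.raises(LogicError):
        forward_chain([Atom("ST", (px,))], _grounded(rules, {A}))


def test_forward_chain_deterministic(rules):
    given = [AAS_A, AAS_B]
    r1 = forward_chain(given, _grounded(rules, {A, B}))
    r2 = forward_chain(given, _grounded(rules, {A, B}))
    assert r1.derived == r2.derived
    assert r1.iterations == r2.iterations
    assert {f: p.lines for f, p in r1.proofs.items()} == {
        f: p.lines for f, p in r2.proofs.items()
    }


def test_forward_chain_monotone_in_given(rules):
    grounded = _grounded(rules, {A, B})
    small = forward_chain([AAS_A], grounded)
    large = forward_chain([AAS_A, AAS_B], grounded)
    assert small.derived <= large.derived


def test_forward_chain_iterations_bounded_by_universe(rules):
    given = [AAS_A, AAS_B]
    grounded = _grounded(rules, {A, B})
    universe = subformula_closure(list(given) + [f for _, f in grounded])
    result = forward_chain(given, grounded)
    assert result.iterations <= len(universe)


def test_forward_chain_proofs_replay(rules):
    given = [AAS_A, AAS_B]
    grounded = _grounded(rules, {A, B})
    result = forward_chain(given, grounded)
    for formula, proof in result.proofs.items():
        assert proof.conclusion == formula
        ok, bad = check_proof(proof, given, rules)
        assert ok, f"{serialize(formula)} failed at line {bad}"


# ---------------------------------------------------------------------------
# Function-atom restriction
# ---------------------------------------------------------------------------


def test_derive_function_atoms_sequence_pair(rules):
    derived = derive_function_atoms([AAS_A, AAS_B], _grounded(rules, {A, B}))
    assert set(derived) == {F_A, F_B}
    for atom, proof in derived.items():
        ok, _ = check_proof(proof, [AAS_A, AAS_B], rules)
        assert ok and proof.conclusion == atom


def test_derive_function_atoms_binding_transfer(rules):
    given = [Atom("NCBND", (A, B)), F_A]
    derived = derive_function_atoms(given, _grounded(rules, {A, B}))
    # F(A) is given (explicit), only F(B) is an inference
    assert set(derived) == {F_B}


def test_derive_function_atoms_interaction_alone_gives_disjunction_only(rules):
    given = [Atom("PPI", (A, B))]
    result = forward_chain(given, _grounded(rules, {A, B}))
    assert Or(F_A, F_B) in result.derived
    derived = derive_function_atoms(given, _grounded(rules, {A, B}))
    assert derived == {}


# ---------------------------------------------------------------------------
# Proof checking
# ---------------------------------------------------------------------------


def test_worked_example_proofs_validate(rules, examples):
    expected_lengths = {"example1": 5, "example2": 13, "example3": 5, "example4": 9}
    for eid, fx in examples.items():
        assert len(fx.proof) == expected_lengths[eid]
        ok, bad = check_proof(fx.proof, list(fx.given), rules)
        assert ok, f"{eid} failed at line {bad}"


def test_tampered_antecedents_detected(rules, examples):
    fx = examples["example1"]
    lines = list(fx.proof.lines)
    last = lines[-1]
    lines[-1] = ProofLine(
        last.index,
        last.formula,
        dataclasses.replace(last.justification, antecedents=(2, 4)),
    )
    ok, bad = check_proof(Proof(tuple(lines)), list(fx.given), rules)
    assert not ok and bad == 5


def test_alien_given_premise_detected(rules, examples):
    fx = examples["example3"]
    # claiming an extra given premise that was never given
    lines = list(fx.proof.lines)
    lines[0] = ProofLine(1, FD_B, Justification("given", "given"))
    ok, bad = check_proof(Proof(tuple(lines)), list(fx.given), rules)
    assert not ok and bad == 1


def test_wrong_specification_rule_id_detected(rules, examples):
    fx = examples["example3"]
    lines = list(fx.proof.lines)
    line2 = lines[1]
    lines[1] = ProofLine(2, line2.formula, Justification("specification_rule", "R3"))
    ok, bad = check_proof(Proof(tuple(lines)), list(fx.given), rules)
    assert not ok and bad == 2


def test_validate_lines_reports_per_line(rules, examples):
    fx = examples["example2"]
    assert validate_lines(fx.proof, list(fx.given), rules) == [True] * 13


def test_proof_json_roundtrip(rules, examples):
    fx = examples["example4"]
    text = proof_to_json(fx.proof)
    again = proof_from_json(text)
    assert again.lines == fx.proof.lines
    ok, _ = check_proof(again, list(fx.given), rules)
    assert ok


# ---------------------------------------------------------------------------
# Truth-table oracle
# ---------------------------------------------------------------------------


def test_entailment_folding_structure_function(rules):
    r1 = apply_substitution(rules[0].formula, Substitution({Variable("Px", PROTEIN): A}))
    assert entails_bruteforce([FD_A, ST_A, r1], F_A)


def test_entailment_tautology_from_empty():
    assert entails_bruteforce([], Or(FD_A, Not(FD_A)))


def test_entailment_countermodel():
    assert not entails_bruteforce([FD_A], F_A)


def test_entailment_atom_cap():
    atoms = [Atom("F", (ConstantSymbol(f"P{i}", PROTEIN),)) for i in range(17)]
    big = atoms[0]
    for a in atoms[1:]:
        big = And(big, a)
    with pytest.raises(LogicError, match="cap"):
        entails_bruteforce([big], atoms[0])


def test_entailment_false_constant_unsatisfiable():
    # a false premise entails anything
    assert entails_bruteforce([FALSE], F_A)


# ---------------------------------------------------------------------------
# Soundness spot-check (the full 500-instance sweep runs in the
# acceptance suite)
# ---------------------------------------------------------------------------


def _random_instance(rng, rules):
    n_rules = int(rng.integers(2, 7))
    picked = [rules[i] for i in sorted(rng.choice(len(rules), n_rules, replace=False))]
    grounded = ground_rules(picked, {A, B, ATP}, injective=True)
    atoms = sorted(
        {
            f
            for _, g in grounded
            for f in subformula_closure([g])
            if isinstance(f, Atom)
        },
        key=serialize,
    )
    n_given = int(rng.integers(0, min(5, len(atoms)) + 1)) if atoms else 0
    given = (
        [atoms[i] for i in sorted(rng.choice(len(atoms), n_given, replace=False))]
        if n_given
        else []
    )
    return given, grounded


def test_soundness_random_spot_check(rules):
    rng = np.random.default_rng(17)
    for _ in range(60):
        given, grounded = _random_instance(rng, rules)
        result = forward_chain(given, grounded)
        premises = list(given) + [f for _, f in grounded]
        for derived in result.derived:
            assert entails_bruteforce(premises, derived), serialize(derived)
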