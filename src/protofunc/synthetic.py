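"""Synthetic corpora with planted co-occurrence structure, plus the four
worked-example derivations used throughout the tests.

The corpus generator emulates the only features of biomedical text the
extraction rules are sensitive to — dictionary terms, protein/ligand
names, pronoun connectors and disconnectors at the sentence level — and
deliberately nothing else (no realistic grammar, no named-entity
ambiguity).  Planted pairs co-occur at a configured per-sentence rate
through fixed sentence templates; background terms occur independently.
Everything is fully determined by the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .extraction import Document, Lexicon, LexiconEntry, _parse_template
from .inference import (
    GIVEN,
    INFERENCE_RULE,
    SPECIFICATION_RULE,
    Justification,
    Proof,
    ProofLine,
)
from .logic import (
    PROTEIN,
    And,
    Atom,
    ConstantSymbol,
    Formula,
    Imp,
)

__all__ = [
    "PlantedPair",
    "CorpusSpec",
    "GroundTruth",
    "generate_corpus",
    "ExampleFixture",
    "worked_example_fixtures",
    "background_lexicon",
    "corpus_spec_from_json",
]


# ---------------------------------------------------------------------------
# Corpus generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedPair:
    """A term pair planted to co-occur at *rate* per sentence.

    ``connector`` selects the sentence template: ``pronoun`` links the
    mentions with "which" (semantically related), ``disconnector`` with
    "whereas" (unrelated), ``none`` with a bare "and".  ``anchor``
    optionally names a constant placed next to the first term so that a
    predicate template binds to it (nearest-name binding).
    """

    a: str
    b: str
    rate: float
    connector: str = "pronoun"
    anchor: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("rate must be in [0, 1]")
        if self.connector not in ("pronoun", "disconnector", "none"):
            raise ValueError(f"unknown connector {self.connector!r}")


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic corpus."""

    lexicon: Lexicon
    n_documents: int = 100
    sentences_per_document: tuple[int, int] = (3, 8)
    planted_pairs: tuple[PlantedPair, ...] = ()
    background_rates: Mapping[str, float] = field(default_factory=dict)
    doc_protein_ids: tuple[str, ...] = ()
    seed: int = 17

    def __post_init__(self) -> None:
        known = {e.entry_id for e in self.lexicon.entries} | {
            c.name for c in self.lexicon.constants.values()
        }
        if not known:
            raise ValueError("vocabulary is empty")
        for pp in self.planted_pairs:
            for term in (pp.a, pp.b):
                if term not in known:
                    raise ValueError(f"planted pair references unknown term {term!r}")
        for term, rate in self.background_rates.items():
            if term not in known:
                raise ValueError(f"background rate references unknown term {term!r}")
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, for checking recovery."""

    pair_labels: dict[frozenset[str], str] = field(default_factory=dict)
    intended_given_atoms: dict[str, set[Atom]] = field(default_factory=dict)
    intended_categories: dict[str, set[str]] = field(default_factory=dict)


def _surface(lexicon: Lexicon, term_id: str) -> str:
    for e in lexicon.entries:
        if e.entry_id == term_id:
            return e.surface_patterns[0]
    for c in lexicon.constants.values():
        if c.name == term_id:
            return c.name
    raise ValueError(f"unknown term {term_id!r}")


_TEMPLATES = {
    "pronoun": "the {a}{anchor} , which involves {b} .",
    "disconnector": "the {a}{anchor} was measured whereas {b} was measured .",
    "none": "the {a}{anchor} and {b} were measured .",
}


def generate_corpus(spec: CorpusSpec) -> tuple[list[Document], GroundTruth]:
    """Generate a seeded corpus realising *spec*.

    Per sentence, planted pairs fire independently in order (at most one
    renders the sentence); otherwise each background term is included
    independently at its rate.  Marginal and joint frequencies therefore
    converge to the spec rates as the corpus grows.
    """
    rng = np.random.default_rng(spec.seed)
    lex = spec.lexicon
    protein_ids = spec.doc_protein_ids or tuple(
        sorted(c.name for c in lex.constants.values() if c.sort == PROTEIN)
    )
    truth = GroundTruth()
    for pp in spec.planted_pairs:
        label = {"pronoun": "related", "disconnector": "unrelated", "none": "undetermined"}[
            pp.connector
        ]
        truth.pair_labels[frozenset((pp.a, pp.b))] = label
        if pp.connector == "pronoun" and pp.anchor is not None:
            entry = next((e for e in lex.entries if e.entry_id == pp.a), None)
            if entry is not None and entry.template is not None:
                anchor_const = lex.constants[pp.anchor.lower()]
                atom = Atom(entry.template.predicate, (anchor_const,))
                truth.intended_given_atoms.setdefault(pp.b, set()).add(atom)
            elif entry is not None and entry.category is not None:
                truth.intended_categories.setdefault(pp.b, set()).add(entry.category)
        elif pp.connector == "pronoun":
            entry = next((e for e in lex.entries if e.entry_id == pp.a), None)
            if entry is not None and entry.category is not None:
                truth.intended_categories.setdefault(pp.b, set()).add(entry.category)

    background = sorted(spec.background_rates.items())
    docs: list[Document] = []
    lo, hi = spec.sentences_per_document
    for d in range(spec.n_documents):
        n_sent = int(rng.integers(lo, hi + 1))
        sentences: list[str] = []
        for _ in range(n_sent):
            draws = rng.random(len(spec.planted_pairs)) if spec.planted_pairs else []
            planted = None
            for pp, u in zip(spec.planted_pairs, draws):
                if u < pp.rate:
                    planted = pp
                    break
            if planted is not None:
                anchor = f" of {planted.anchor}" if planted.anchor else ""
                sentences.append(
                    _TEMPLATES[planted.connector].format(
                        a=_surface(lex, planted.a), anchor=anchor, b=_surface(lex, planted.b)
                    )
                )
                continue
            included = [
                term for (term, rate), u in zip(background, rng.random(len(background)))
                if u < rate
            ] if background else []
            if included:
                body = " and ".join(_surface(lex, t) for t in included)
                sentences.append(f"we measured {body} in the assay .")
            else:
                sentences.append("the experiment was repeated under identical conditions .")
        docs.append(Document(f"doc{d:05d}", protein_ids, " ".join(sentences)))
    return docs, truth


def corpus_spec_from_json(path_text: str, lexicon: Lexicon) -> CorpusSpec:
    """Build a CorpusSpec from a JSON description (used by the CLI)."""
    obj = json.loads(path_text)
    return CorpusSpec(
        lexicon=lexicon,
        n_documents=obj.get("n_documents", 100),
        sentences_per_document=tuple(obj.get("sentences_per_document", (3, 8))),
        planted_pairs=tuple(
            PlantedPair(
                p["a"], p["b"], p["rate"], p.get("connector", "pronoun"), p.get("anchor")
            )
            for p in obj.get("planted_pairs", [])
        ),
        background_rates=obj.get("background_rates", {}),
        doc_protein_ids=tuple(obj.get("doc_protein_ids", ())),
        seed=obj.get("seed", 17),
    )


def background_lexicon(n_terms: int) -> Lexicon:
    """A lexicon of *n_terms* generic single-token category terms
    (``term00``…), used for Z-score calibration corpora."""
    lex = Lexicon()
    for i in range(n_terms):
        lex.entries.append(
            LexiconEntry(f"t{i:02d}", (f"term{i:02d}",), category=f"CAT:{i:04d}")
        )
    return lex


# ---------------------------------------------------------------------------
# Worked-example derivations
# ---------------------------------------------------------------------------

_PX = ConstantSymbol("Px", PROTEIN)
_PY = ConstantSymbol("Py", PROTEIN)


def _atom(pred: str, *args: ConstantSymbol) -> Atom:
    return Atom(pred, args)


def _given(i: int, f: Formula) -> ProofLine:
    return ProofLine(i, f, Justification(GIVEN, "given"))


def _prem(i: int, f: Formula, rid: str) -> ProofLine:
    return ProofLine(i, f, Justification(SPECIFICATION_RULE, rid))


def _inf(i: int, f: Formula, rule: str, *ants: int) -> ProofLine:
    return ProofLine(i, f, Justification(INFERENCE_RULE, rule, tuple(ants)))


@dataclass(frozen=True)
class ExampleFixture:
    """One worked case study: given premises, the rules it exercises, the
    expected derived function atoms, and the encoded step-by-step proof."""

    example_id: str
    given: tuple[Atom, ...]
    rule_ids_used: tuple[str, ...]
    expected_conclusions: tuple[Atom, ...]
    proof: Proof


def worked_example_fixtures() -> dict[str, ExampleFixture]:
    """The four case-study derivations over placeholder proteins Px, Py.

    Example 1: folding + structure of Px entail its function (conditional
    proof through the folding premise).  Example 2: amino-acid sequences
    of Px and Py entail both functions (sequence-classification premise,
    instantiated in both variable orders).  Example 3: structure of Px
    entails its function via the sequence premises.  Example 4: a
    non-covalent bond between Px and Py plus the function of Px entail
    the function of Py (binding -> interaction -> complex -> function
    transfer).  Antecedent indices follow the corrected reading of the
    printed derivations.
    """
    fd_x, st_x, f_x = _atom("FD", _PX), _atom("ST", _PX), _atom("F", _PX)
    aas_x, aas_y = _atom("AAS", _PX), _atom("AAS", _PY)
    st_y, f_y = _atom("ST", _PY), _atom("F", _PY)
    ncbnd = _atom("NCBND", _PX, _PY)
    ppi, pcf = _atom("PPI", _PX, _PY), _atom("PCF", _PX, _PY)

    ex1 = ExampleFixture(
        "example1",
        given=(fd_x, st_x),
        rule_ids_used=("R1",),
        expected_conclusions=(f_x,),
        proof=Proof(
            (
                _given(1, fd_x),
                _given(2, st_x),
                _inf(3, And(fd_x, st_x), "Conjunction", 1, 2),
                _prem(4, Imp(fd_x, Imp(st_x, f_x)), "R1"),
                _inf(5, f_x, "ConditionalProof", 3, 4),
            )
        ),
    )

    aas_xy = And(aas_x, aas_y)
    ex2 = ExampleFixture(
        "example2",
        given=(aas_x, aas_y),
        rule_ids_used=("R2", "R10"),
        expected_conclusions=(f_x, f_y),
        proof=Proof(
            (
                _given(1, aas_x),
                _given(2, aas_y),
                _inf(3, aas_xy, "Conjunction", 1, 2),
                _prem(4, Imp(aas_x, st_x), "R2"),
                _inf(5, st_x, "ModusPonens", 1, 4),
                _inf(6, And(aas_xy, st_x), "Conjunction", 3, 5),
                _prem(7, Imp(aas_xy, Imp(st_x, f_y)), "R10"),
                _inf(8, f_y, "ConditionalProof", 6, 7),
                _prem(9, Imp(aas_y, st_y), "R2"),
                _inf(10, st_y, "ModusPonens", 2, 9),
                _inf(11, And(aas_xy, st_y), "Conjunction", 3, 10),
                # the swapped-variable instance of R10 (conjunction order as
                # printed; instance matching is commutative in "&")
                _prem(12, Imp(aas_xy, Imp(st_y, f_x)), "R10"),
                _inf(13, f_x, "ConditionalProof", 11, 12),
            )
        ),
    )

    ex3 = ExampleFixture(
        "example3",
        given=(st_x,),
        rule_ids_used=("R13", "R3"),
        expected_conclusions=(f_x,),
        proof=Proof(
            (
                _given(1, st_x),
                _prem(2, Imp(st_x, aas_x), "R13"),
                _inf(3, aas_x, "ModusPonens", 1, 2),
                _prem(4, Imp(aas_x, f_x), "R3"),
                _inf(5, f_x, "ModusPonens", 3, 4),
            )
        ),
    )

    ex4 = ExampleFixture(
        "example4",
        given=(ncbnd, f_x),
        rule_ids_used=("R12", "R6", "R7"),
        expected_conclusions=(f_y,),
        proof=Proof(
            (
                _given(1, ncbnd),
                _given(2, f_x),
                _prem(3, Imp(ncbnd, ppi), "R12"),
                _prem(4, Imp(ppi, pcf), "R6"),
                _inf(5, Imp(ncbnd, pcf), "LawOfSyllogism", 3, 4),
                _inf(6, pcf, "ModusPonens", 1, 5),
                _inf(7, And(pcf, f_x), "Conjunction", 2, 6),
                _prem(8, Imp(pcf, Imp(f_x, f_y)), "R7"),
                _inf(9, f_y, "ConditionalProof", 7, 8),
            )
        ),
    )

    return {fx.example_id: fx for fx in (ex1, ex2, ex3, ex4)}
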