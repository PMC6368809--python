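"""End-to-end annotation pipeline: extraction → grounding → inference →
function transfer.

For an unannotated protein the pipeline (1) extracts explicitly related
terms from its documents, (2) turns predicate-template matches into
ground given premises, (3) grounds the specification-rule base over the
constants those premises mention, (4) forward-chains to derive function
atoms ``F(Px)`` with proofs, and (5) transfers every functional category
annotated to ``Px`` to the query protein as an *implicit* prediction.
Explicitly extracted category terms are emitted as *explicit*
predictions.  Support (the number of independent evidence items) is the
only ranking key; no pseudo-probability is invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .extraction import (
    Document,
    ExtractionError,
    Lexicon,
    ProvenancedAtom,
    ProvenancedCategory,
    RelatedPairIndex,
    extract_given_premises,
)
from .inference import Proof, derive_function_atoms
from .logic import (
    Atom,
    Formula,
    LogicError,
    SpecificationRule,
    formula_constants,
    ground_rules,
    serialize,
)

__all__ = [
    "AnnotationTable",
    "PredictionRecord",
    "PipelineConfig",
    "GivenPremises",
    "mentions_to_given",
    "annotate_protein",
    "write_predictions",
    "read_predictions",
]


# ---------------------------------------------------------------------------
# Known annotations
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """protein id → set of functional-category ids (two-column TSV)."""

    annotations: dict[str, set[str]] = field(default_factory=dict)

    def add(self, protein: str, category: str) -> None:
        self.annotations.setdefault(protein, set()).add(category)

    def categories(self, protein: str) -> set[str]:
        return set(self.annotations.get(protein, set()))

    def __contains__(self, protein: str) -> bool:
        return protein in self.annotations

    @classmethod
    def from_tsv(cls, source: str | Path) -> "AnnotationTable":
        table = cls()
        for lineno, raw in enumerate(
            Path(source).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if lineno == 1 and parts[0] == "protein":
                continue
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ExtractionError(f"annotation line {lineno}: expected 'protein<TAB>category'")
            table.add(parts[0], parts[1])
        return table

    def to_tsv(self, destination: str | Path) -> None:
        rows = ["protein\tcategory"]
        for protein in sorted(self.annotations):
            for category in sorted(self.annotations[protein]):
                rows.append(f"{protein}\t{category}")
        Path(destination).write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionRecord:
    """One predicted (protein, category) pair with its evidence trail."""

    protein: str
    category: str
    evidence: str  # "explicit" | "implicit"
    support: int
    provenance: tuple[str, ...]
    proof: Proof | None = field(default=None, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.evidence not in ("explicit", "implicit"):
            raise LogicError(f"unknown evidence kind {self.evidence!r}")
        if self.support < 1:
            raise LogicError("support must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters with their documented defaults."""

    z_threshold: float = -1.96
    injective_substitution: bool = True
    max_iterations: int = 100
    min_support: int = 1
    seed: int = 17
    inference_enabled: bool = True


# ---------------------------------------------------------------------------
# Given-premise assembly
# ---------------------------------------------------------------------------


@dataclass
class GivenPremises:
    atoms: list[Atom]
    support: dict[Atom, int]
    provenance: dict[Atom, tuple[str, ...]]


def mentions_to_given(
    atoms: Sequence[ProvenancedAtom],
    explicit_categories: Sequence[ProvenancedCategory],
    p_u: str,
) -> tuple[GivenPremises, list[PredictionRecord]]:
    """Deduplicate extracted atoms into a given set (support = number of
    supporting sentences) and turn category extractions into explicit
    prediction records for *p_u*.

    A function term bound to a *named* protein (e.g. ``F(Px)``) stays a
    given atom — it feeds the inference step; a category term related to
    *p_u* itself is a prediction, never a premise.
    """
    support: dict[Atom, int] = {}
    provenance: dict[Atom, tuple[str, ...]] = {}
    order: list[Atom] = []
    for pa in atoms:
        if pa.atom not in support:
            support[pa.atom] = 0
            provenance[pa.atom] = ()
            order.append(pa.atom)
        support[pa.atom] += 1
        provenance[pa.atom] += (f"{pa.doc_id}:s{pa.sentence_index}",)
    given = GivenPremises(atoms=sorted(order, key=serialize), support=support, provenance=provenance)

    by_category: dict[str, list[ProvenancedCategory]] = {}
    for pc in explicit_categories:
        by_category.setdefault(pc.category, []).append(pc)
    records = [
        PredictionRecord(
            protein=p_u,
            category=category,
            evidence="explicit",
            support=len(items),
            provenance=tuple(f"{pc.doc_id}:s{pc.sentence_index}" for pc in items),
        )
        for category, items in sorted(by_category.items())
    ]
    return given, records


# ---------------------------------------------------------------------------
# Annotation pipeline
# ---------------------------------------------------------------------------


def annotate_protein(
    p_u: str,
    query_docs: Iterable[Document],
    lexicon: Lexicon,
    rules: Sequence[SpecificationRule],
    annotations: AnnotationTable,
    index: RelatedPairIndex | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> list[PredictionRecord]:
    """Predict functional categories for *p_u*.

    Explicit records come from category terms extracted as related to
    *p_u*; implicit records come from derived function atoms ``F(Px)``,
    each transferring *all* categories annotated to ``Px`` and citing a
    replayable proof.  Records with support below ``config.min_support``
    are dropped; ordering is deterministic (explicit first, then support
    descending, then category id).
    """
    if not rules:
        raise LogicError("empty specification-rule set")
    docs = list(query_docs)
    categories, atoms = extract_given_premises(
        docs, p_u, lexicon, index=index, z_threshold=config.z_threshold
    )
    given, records = mentions_to_given(atoms, categories, p_u)

    if config.inference_enabled and given.atoms:
        constants = set()
        for a in given.atoms:
            constants.update(formula_constants(a))
        grounded = ground_rules(
            rules, constants, injective=config.injective_substitution
        )
        derived = derive_function_atoms(
            given.atoms, grounded, max_iterations=config.max_iterations
        )
        # aggregate transferred categories across source proteins
        implicit: dict[str, list[tuple[str, Proof]]] = {}
        for f_atom, proof in derived.items():
            source_protein = f_atom.args[0].name
            for category in sorted(annotations.categories(source_protein)):
                implicit.setdefault(category, []).append((source_protein, proof))
        for category, sources in sorted(implicit.items()):
            records.append(
                PredictionRecord(
                    protein=p_u,
                    category=category,
                    evidence="implicit",
                    support=len(sources),
                    provenance=tuple(
                        f"F({src})[proof:{len(proof)} lines]" for src, proof in sources
                    ),
                    proof=sources[0][1],
                )
            )

    records = [r for r in records if r.support >= config.min_support]
    records.sort(key=lambda r: (r.evidence != "explicit", -r.support, r.category))
    return records


# ---------------------------------------------------------------------------
# Prediction TSV round-trip
# ---------------------------------------------------------------------------

_HEADER = "protein\tcategory\tevidence\tsupport\tprovenance"


def write_predictions(records: Iterable[PredictionRecord], destination: str | Path) -> None:
    rows = [_HEADER]
    for r in records:
        rows.append(
            f"{r.protein}\t{r.category}\t{r.evidence}\t{r.support}\t{';'.join(r.provenance)}"
        )
    Path(destination).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_predictions(source: str | Path) -> list[PredictionRecord]:
    records = []
    lines = Path(source).read_text(encoding="utf-8").splitlines()
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip() or (lineno == 1 and raw.startswith("protein\t")):
            continue
        parts = raw.split("\t")
        if len(parts) != 5:
            raise ExtractionError(f"predictions line {lineno}: expected 5 columns")
        try:
            support = int(parts[3])
        except ValueError as exc:
            raise ExtractionError(f"predictions line {lineno}: bad support {parts[3]!r}") from exc
        provenance = tuple(p for p in parts[4].split(";") if p)
        records.append(PredictionRecord(parts[0], parts[1], parts[2], support, provenance))
    return records
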