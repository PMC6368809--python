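"""protofunc: protein function prediction from biomedical text via
predicate-logic forward chaining.

The package couples a dictionary/collocation extraction layer (explicit
term co-occurrence with Z-score validation and sentence-level pronoun /
disconnector rules) with a forward-chaining inference engine over a
protein specification-rule base, deriving implicitly co-occurring
function atoms with replayable natural-deduction proofs.
"""

from importlib import resources

from . import evaluation, extraction, inference, logic, pipeline, synthetic
from .evaluation import (
    EvalCounts,
    EvalSummary,
    FoldAssignment,
    evaluate,
    f_value,
    kfold_split,
    precision,
    recall,
)
from .extraction import (
    CooccurrenceStats,
    Document,
    Lexicon,
    LexiconEntry,
    PairRelatedness,
    RelatedPairIndex,
    SentenceRecord,
    TermMention,
    build_related_pair_index,
    classify_pair,
    compute_zscore,
    extract_given_premises,
    match_terms,
    read_corpus,
    segment_sentences,
    write_corpus,
)
from .inference import (
    DerivationResult,
    Justification,
    Proof,
    ProofLine,
    apply_inference_rule,
    check_proof,
    derive_function_atoms,
    entails_bruteforce,
    forward_chain,
)
from .logic import (
    Atom,
    ConstantSymbol,
    Formula,
    SpecificationRule,
    Substitution,
    Variable,
    apply_substitution,
    ground_rules,
    parse_formula,
    parse_rule_file,
    serialize,
    subformula_closure,
)
from .pipeline import (
    AnnotationTable,
    PipelineConfig,
    PredictionRecord,
    annotate_protein,
    read_predictions,
    write_predictions,
)
from .synthetic import (
    CorpusSpec,
    ExampleFixture,
    GroundTruth,
    PlantedPair,
    generate_corpus,
    worked_example_fixtures,
)

__version__ = "0.1.0"


def load_default_rules() -> list[SpecificationRule]:
    """The bundled 13-premise protein specification-rule base."""
    text = resources.files("protofunc.data").joinpath("protein_rules.plr").read_text("utf-8")
    return parse_rule_file(text)


def default_rules_text() -> str:
    """Raw text of the bundled rule file."""
    return resources.files("protofunc.data").joinpath("protein_rules.plr").read_text("utf-8")
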