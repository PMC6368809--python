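"""Extraction of biological-molecule terms explicitly related to a protein.

Terms are recognised by dictionary (lexicon) lookup in sentences, and a
term is accepted as *semantically related* to a protein mention when

1. a pronoun connector ("that", "who", "which") links the two mentions
   in the sentence and no disconnector ("whereas", "but", "while") lies
   between them,
2. the pair's sentence-level co-occurrence Z-score in the corpus clears
   the configured threshold, and
3. (when a training index is supplied) the same pair was found
   semantically related in the training corpus.

Accepted terms either name a functional category directly (assigned to
the protein as an *explicit* prediction) or instantiate a predicate
template (e.g. "folding" -> FD(·)), producing a ground atom that serves
as a *given premise* for the inference engine.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .logic import (
    LIGAND,
    PROTEIN,
    SIGNATURES,
    Atom,
    ConstantSymbol,
    LogicError,
)

__all__ = [
    "PRONOUN_CONNECTORS",
    "DISCONNECTORS",
    "DEFAULT_ABBREVIATIONS",
    "Document",
    "SentenceRecord",
    "PredicateTemplate",
    "LexiconEntry",
    "Lexicon",
    "TermMention",
    "PairRelatedness",
    "CooccurrenceStats",
    "RelatedPairIndex",
    "ExtractionError",
    "read_corpus",
    "write_corpus",
    "tokenize",
    "segment_sentences",
    "corpus_sentences",
    "match_terms",
    "classify_pair",
    "compute_zscore",
    "term_occurrence_sets",
    "pair_statistics",
    "build_related_pair_index",
    "extract_given_premises",
]

PRONOUN_CONNECTORS = frozenset({"that", "who", "which"})
DISCONNECTORS = frozenset({"whereas", "but", "while"})
DEFAULT_ABBREVIATIONS = frozenset(
    {"e.g.", "i.e.", "cf.", "vs.", "al.", "fig.", "figs.", "dr.", "no.", "ca."}
)


class ExtractionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Corpus I/O — JSON lines, one document per line
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Document:
    doc_id: str
    protein_ids: tuple[str, ...]
    text: str


def read_corpus(source: str | Path | Iterable[str]) -> list[Document]:
    """Read a JSONL corpus: ``{"doc_id":…, "protein_ids":[…], "text":…}``."""
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = source
    docs = []
    for lineno, raw in enumerate(lines, start=1):
        raw = raw.strip()
        if not raw:
            continue
        try:
            obj = json.loads(raw)
            docs.append(
                Document(str(obj["doc_id"]), tuple(obj["protein_ids"]), str(obj["text"]))
            )
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise ExtractionError(f"malformed corpus line {lineno}: {exc}") from exc
    return docs


def write_corpus(docs: Iterable[Document], destination: str | Path) -> None:
    with open(destination, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {"doc_id": d.doc_id, "protein_ids": list(d.protein_ids), "text": d.text}
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sentence segmentation and tokenization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SentenceRecord:
    doc_id: str
    sentence_index: int
    text: str
    tokens: tuple[str, ...]


_WORD_RE = re.compile(r"[A-Za-z0-9_'-]+")


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercased word tokens; punctuation is stripped."""
    return tuple(m.group(0).lower() for m in _WORD_RE.finditer(text))


_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def segment_sentences(
    doc_id: str,
    text: str,
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> list[SentenceRecord]:
    """Deterministic rule-based sentence splitting.

    A run of ``.!?`` followed by whitespace (or end of text) ends a
    sentence unless the preceding word plus the period forms a configured
    abbreviation (``e.g.``, ``i.e.``, …).  Empty input yields no
    sentences; all non-whitespace characters are preserved.
    """
    sentences: list[SentenceRecord] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        prefix = text[start : m.end()]
        tail = prefix.rstrip()
        last_word = tail.rsplit(None, 1)[-1].lower() if tail.split() else ""
        if last_word in abbreviations:
            continue
        chunk = prefix.strip()
        if chunk:
            sentences.append(
                SentenceRecord(doc_id, len(sentences), chunk, tokenize(chunk))
            )
        start = m.end()
    chunk = text[start:].strip()
    if chunk:
        sentences.append(SentenceRecord(doc_id, len(sentences), chunk, tokenize(chunk)))
    return sentences


def corpus_sentences(docs: Iterable[Document]) -> list[SentenceRecord]:
    out: list[SentenceRecord] = []
    for d in docs:
        out.extend(segment_sentences(d.doc_id, d.text))
    return out


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredicateTemplate:
    """A predicate with argument roles, e.g. ``FD(protein)``.

    Matching the template's surface pattern in a sentence produces a
    ground atom once each role slot is bound to a named constant mention.
    """

    predicate: str
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        sig = SIGNATURES.get(self.predicate)
        if sig is None:
            raise LogicError(f"unknown predicate {self.predicate!r}")
        if tuple(self.roles) != sig:
            raise LogicError(
                f"template roles {self.roles} do not match the "
                f"{self.predicate} signature {sig}"
            )


@dataclass(frozen=True)
class LexiconEntry:
    """A dictionary entry: surface phrase patterns plus exactly one payload
    — a predicate template or a functional-category id."""

    entry_id: str
    surface_patterns: tuple[str, ...]
    template: PredicateTemplate | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.surface_patterns:
            raise ExtractionError(f"entry {self.entry_id!r} has no patterns")
        if (self.template is None) == (self.category is None):
            raise ExtractionError(
                f"entry {self.entry_id!r} must carry exactly one payload"
            )


_TEMPLATE_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)\(([^)]*)\)$")


def _parse_template(value: str) -> PredicateTemplate:
    m = _TEMPLATE_RE.match(value.strip())
    if m is None:
        raise ExtractionError(f"malformed template payload {value!r}")
    roles = tuple(r.strip() for r in m.group(2).split(",") if r.strip())
    return PredicateTemplate(m.group(1), roles)


@dataclass
class Lexicon:
    """Term dictionary plus declared protein/ligand constant names.

    Constant sorts are always declared here, never inferred from names.
    """

    entries: list[LexiconEntry] = field(default_factory=list)
    constants: dict[str, ConstantSymbol] = field(default_factory=dict)

    def add_constant(self, name: str, sort: str) -> None:
        self.constants[name.lower()] = ConstantSymbol(name, sort)

    @classmethod
    def from_tsv(cls, source: str | Path) -> "Lexicon":
        """TSV columns: entry_id, pattern (``|``-separated alternatives),
        payload_kind (template|category|protein|ligand), payload_value."""
        lex = cls()
        text = Path(source).read_text(encoding="utf-8")
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "entry_id":
                continue
            if len(parts) < 3:
                raise ExtractionError(f"lexicon line {lineno}: expected >=3 columns")
            entry_id, pattern, kind = parts[0], parts[1], parts[2]
            value = parts[3] if len(parts) > 3 else ""
            patterns = tuple(p.strip() for p in pattern.split("|") if p.strip())
            if kind == "template":
                lex.entries.append(
                    LexiconEntry(entry_id, patterns, template=_parse_template(value))
                )
            elif kind == "category":
                lex.entries.append(LexiconEntry(entry_id, patterns, category=value))
            elif kind in (PROTEIN, LIGAND):
                for p in patterns:
                    lex.constants[p.lower()] = ConstantSymbol(entry_id, kind)
            else:
                raise ExtractionError(f"lexicon line {lineno}: unknown kind {kind!r}")
        return lex

    def to_tsv(self, destination: str | Path) -> None:
        rows = ["entry_id\tpattern\tpayload_kind\tpayload_value"]
        for e in self.entries:
            if e.template is not None:
                kind = "template"
                value = f"{e.template.predicate}({','.join(e.template.roles)})"
            else:
                kind, value = "category", e.category or ""
            rows.append(f"{e.entry_id}\t{'|'.join(e.surface_patterns)}\t{kind}\t{value}")
        for c in sorted(self.constants.values()):
            rows.append(f"{c.name}\t{c.name}\t{c.sort}\t")
        Path(destination).write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Term matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermMention:
    """A lexicon-entry or constant-name occurrence in one sentence.

    ``span`` is a 0-based half-open token range.  For template entries,
    ``bound_args`` holds the constants filled into the role slots (the
    nearest name mentions of the required sort, ties broken leftward).
    """

    entry_id: str
    doc_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    kind: str  # "entry" | "constant"
    constant: ConstantSymbol | None = None
    entry: LexiconEntry | None = field(default=None, compare=False, hash=False)
    bound_args: tuple[ConstantSymbol, ...] | None = field(
        default=None, compare=False, hash=False
    )

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ExtractionError("mention span must be non-empty")


def match_terms(sentence: SentenceRecord, lexicon: Lexicon) -> list[TermMention]:
    """Case-insensitive, longest-match-first, non-overlapping dictionary
    matching over the sentence's tokens, followed by template-argument
    binding to the nearest constant mention of the required sort."""
    tokens = sentence.tokens
    # candidate phrases: (token-tuple, entry | None, constant | None)
    phrases: list[tuple[tuple[str, ...], LexiconEntry | None, ConstantSymbol | None]] = []
    for entry in lexicon.entries:
        for pat in entry.surface_patterns:
            phrases.append((tokenize(pat), entry, None))
    for surface, const in lexicon.constants.items():
        phrases.append((tokenize(surface), None, const))
    # longest first so e.g. "amino acid sequence" beats "sequence"
    phrases.sort(key=lambda p: (-len(p[0]), p[0]))

    taken = [False] * len(tokens)
    raw: list[TermMention] = []
    for phrase, entry, const in phrases:
        L = len(phrase)
        if L == 0:
            continue
        for start in range(0, len(tokens) - L + 1):
            if tuple(tokens[start : start + L]) != phrase:
                continue
            if any(taken[start : start + L]):
                continue
            for i in range(start, start + L):
                taken[i] = True
            raw.append(
                TermMention(
                    entry_id=entry.entry_id if entry else const.name,  # type: ignore[union-attr]
                    doc_id=sentence.doc_id,
                    sentence_index=sentence.sentence_index,
                    start=start,
                    end=start + L,
                    surface=" ".join(phrase),
                    kind="entry" if entry else "constant",
                    constant=const,
                    entry=entry,
                )
            )
    raw.sort(key=lambda m: m.start)

    # bind template role slots to nearest constant mentions
    out: list[TermMention] = []
    const_mentions = [m for m in raw if m.kind == "constant"]
    for m in raw:
        if m.kind == "entry" and m.entry is not None and m.entry.template is not None:
            bound = _bind_roles(m, m.entry.template.roles, const_mentions)
            out.append(
                TermMention(
                    m.entry_id, m.doc_id, m.sentence_index, m.start, m.end,
                    m.surface, m.kind, None, m.entry, bound,
                )
            )
        else:
            out.append(m)
    return out


def _bind_roles(
    mention: TermMention,
    roles: Sequence[str],
    const_mentions: Sequence[TermMention],
) -> tuple[ConstantSymbol, ...] | None:
    """Fill each role slot with the nearest unused constant mention of the
    required sort (token distance; ties broken leftward)."""
    used: set[int] = set()
    bound: list[ConstantSymbol] = []
    for sort in roles:
        best: tuple[int, int, int] | None = None  # (distance, start, idx)
        for i, cm in enumerate(const_mentions):
            if i in used or cm.constant is None or cm.constant.sort != sort:
                continue
            if cm.start < mention.end and cm.end > mention.start:
                continue  # overlapping span cannot fill a slot
            distance = max(cm.start - mention.end, mention.start - cm.end, 0)
            key = (distance, cm.start, i)
            if best is None or key < best:
                best = key
        if best is None:
            return None
        used.add(best[2])
        bound.append(const_mentions[best[2]].constant)  # type: ignore[arg-type]
    return tuple(bound)


# ---------------------------------------------------------------------------
# Linguistic pair classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairRelatedness:
    pair: tuple[str, str]
    label: str  # "related" | "unrelated" | "undetermined"
    connector: str | None = None
    connector_position: int | None = None


def classify_pair(
    sentence: SentenceRecord, mention_a: TermMention, mention_b: TermMention
) -> PairRelatedness:
    """Sentence-level relatedness of two mentions.

    Unrelated if a disconnector ("whereas", "but", "while") lies strictly
    between the spans; else related if a pronoun connector ("that",
    "who", "which") does; else undetermined.  Symmetric in its mentions.
    """
    if mention_a.start > mention_b.start:
        mention_a, mention_b = mention_b, mention_a
    if mention_a.end > mention_b.start:
        raise ExtractionError("mention spans overlap")
    pair = (mention_a.entry_id, mention_b.entry_id)
    between = range(mention_a.end, mention_b.start)
    for i in between:
        if sentence.tokens[i] in DISCONNECTORS:
            return PairRelatedness(pair, "unrelated", sentence.tokens[i], i)
    for i in between:
        if sentence.tokens[i] in PRONOUN_CONNECTORS:
            return PairRelatedness(pair, "related", sentence.tokens[i], i)
    return PairRelatedness(pair, "undetermined")


# ---------------------------------------------------------------------------
# Co-occurrence Z-score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CooccurrenceStats:
    pair: tuple[str, str]
    k: int
    n_a: int
    n_b: int
    N: int
    z: float


def compute_zscore(k: int, n_a: int, n_b: int, N: int) -> float:
    """Collocation Z-score under the independence null.

    With marginal sentence rates ``n_a/N`` and ``n_b/N``, the expected
    number of co-occurrence sentences is ``N*p`` with
    ``p = (n_a/N)(n_b/N)``; the score standardises the observed count
    ``k`` by the binomial null: ``z = (k - N p)/sqrt(N p (1-p))``.
    """
    if N <= 0:
        raise ExtractionError("N must be positive")
    if k > min(n_a, n_b) or n_a > N or n_b > N or min(k, n_a, n_b) < 0:
        raise ExtractionError("inconsistent counts")
    p = (n_a / N) * (n_b / N)
    if p <= 0.0 or p >= 1.0:
        raise ExtractionError("undefined variance: expected rate is 0 or 1")
    return (k - N * p) / math.sqrt(N * p * (1.0 - p))


def term_occurrence_sets(
    sentences: Sequence[SentenceRecord], lexicon: Lexicon
) -> dict[str, set[tuple[str, int]]]:
    """Per term id (lexicon entries and declared constants), the set of
    ``(doc_id, sentence_index)`` keys of the sentences mentioning it."""
    occ: dict[str, set[tuple[str, int]]] = {}
    for s in sentences:
        key = (s.doc_id, s.sentence_index)
        for m in match_terms(s, lexicon):
            occ.setdefault(m.entry_id, set()).add(key)
    return occ


def pair_statistics(
    sentences: Sequence[SentenceRecord], lexicon: Lexicon
) -> dict[tuple[str, str], CooccurrenceStats]:
    """Sentence-level co-occurrence statistics for every unordered id pair
    (lexicon entries and declared constants) observed in the corpus."""
    occ: dict[str, set[tuple[str, int]]] = {}
    pair_sentences: dict[tuple[str, str], set[tuple[str, int]]] = {}
    for s in sentences:
        ids = sorted({m.entry_id for m in match_terms(s, lexicon)})
        key = (s.doc_id, s.sentence_index)
        for i in ids:
            occ.setdefault(i, set()).add(key)
        for a, b in itertools_combinations(ids):
            pair_sentences.setdefault((a, b), set()).add(key)
    N = len(sentences)
    out: dict[tuple[str, str], CooccurrenceStats] = {}
    for (a, b), ks in pair_sentences.items():
        try:
            z = compute_zscore(len(ks), len(occ[a]), len(occ[b]), N)
        except ExtractionError:
            continue
        out[(a, b)] = CooccurrenceStats((a, b), len(ks), len(occ[a]), len(occ[b]), N, z)
    return out


def itertools_combinations(ids: Sequence[str]):
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            yield ids[i], ids[j]


# ---------------------------------------------------------------------------
# Training-corpus validation index
# ---------------------------------------------------------------------------


@dataclass
class RelatedPairIndex:
    """Unordered term pairs accepted as semantically related in the
    training corpus, with the Z-score each was accepted at."""

    pairs: dict[frozenset[str], float] = field(default_factory=dict)
    corpus_id: str = ""
    z_threshold: float = -1.96

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self.pairs

    def to_tsv(self, destination: str | Path) -> None:
        rows = ["id_a\tid_b\tz"]
        for key in sorted(self.pairs, key=sorted):
            a, b = sorted(key)
            rows.append(f"{a}\t{b}\t{self.pairs[key]:.6g}")
        Path(destination).write_text("\n".join(rows) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, source: str | Path, z_threshold: float = -1.96) -> "RelatedPairIndex":
        idx = cls(z_threshold=z_threshold)
        for lineno, raw in enumerate(
            Path(source).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not raw.strip() or (lineno == 1 and raw.startswith("id_a")):
                continue
            parts = raw.split("\t")
            if len(parts) != 3:
                raise ExtractionError(f"index line {lineno}: expected 3 columns")
            idx.pairs[frozenset((parts[0], parts[1]))] = float(parts[2])
        return idx


def build_related_pair_index(
    training_docs: Iterable[Document],
    lexicon: Lexicon,
    z_threshold: float = -1.96,
    corpus_id: str = "",
) -> RelatedPairIndex:
    """Accept a pair iff at least one training sentence links it with a
    pronoun connector (disconnected sentences are discarded as evidence
    but do not veto others) and its corpus-wide Z-score clears the
    threshold."""
    sentences = corpus_sentences(training_docs)
    stats = pair_statistics(sentences, lexicon)
    related_pairs: set[frozenset[str]] = set()
    for s in sentences:
        mentions = match_terms(s, lexicon)
        for i in range(len(mentions)):
            for j in range(i + 1, len(mentions)):
                a, b = mentions[i], mentions[j]
                if a.entry_id == b.entry_id:
                    continue
                lo, hi = (a, b) if a.start <= b.start else (b, a)
                if lo.end > hi.start:
                    continue
                rel = classify_pair(s, lo, hi)
                if rel.label == "related":
                    related_pairs.add(frozenset((a.entry_id, b.entry_id)))
    index = RelatedPairIndex(z_threshold=z_threshold, corpus_id=corpus_id)
    for key in related_pairs:
        a, b = sorted(key)
        st = stats.get((a, b))
        if st is not None and st.z > z_threshold:
            index.pairs[key] = st.z
    return index


# ---------------------------------------------------------------------------
# Given-premise extraction for a query protein
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProvenancedAtom:
    atom: Atom
    doc_id: str
    sentence_index: int
    entry_id: str


@dataclass(frozen=True)
class ProvenancedCategory:
    category: str
    doc_id: str
    sentence_index: int
    entry_id: str


def extract_given_premises(
    query_docs: Iterable[Document],
    p_u: str,
    lexicon: Lexicon,
    index: RelatedPairIndex | None = None,
    z_threshold: float = -1.96,
) -> tuple[list[ProvenancedCategory], list[ProvenancedAtom]]:
    """Extract explicit functional categories and given-premise atoms for
    the unannotated protein *p_u* from its associated documents.

    A lexicon term counts as related to *p_u* when a sentence mentioning
    both links them with the pronoun rule, the pair's query-corpus
    Z-score exceeds *z_threshold*, and (if an index is given) the pair
    was validated on the training corpus.  Category payloads become
    explicit predictions; template payloads become ground atoms over
    their bound constants.  Results are independent of document order.
    """
    docs = list(query_docs)
    if not any(p_u in d.protein_ids for d in docs):
        raise ExtractionError(f"protein {p_u!r} is not associated with the corpus")
    pu_key = p_u.lower()
    if pu_key not in lexicon.constants:
        raise ExtractionError(f"protein {p_u!r} is not declared in the lexicon")
    pu_const_name = lexicon.constants[pu_key].name

    sentences = corpus_sentences(docs)
    stats = pair_statistics(sentences, lexicon)

    def pair_z(entry_id: str) -> float | None:
        key = tuple(sorted((entry_id, pu_const_name)))
        st = stats.get(key)
        return None if st is None else st.z

    categories: list[ProvenancedCategory] = []
    atoms: list[ProvenancedAtom] = []
    for s in sorted(sentences, key=lambda s: (s.doc_id, s.sentence_index)):
        mentions = match_terms(s, lexicon)
        pu_mentions = [
            m for m in mentions if m.kind == "constant" and m.entry_id == pu_const_name
        ]
        if not pu_mentions:
            continue
        for m in mentions:
            if m.kind != "entry" or m.entry is None:
                continue
            related = False
            for pm in pu_mentions:
                lo, hi = (m, pm) if m.start <= pm.start else (pm, m)
                if lo.end > hi.start:
                    continue
                if classify_pair(s, lo, hi).label == "related":
                    related = True
                    break
            if not related:
                continue
            z = pair_z(m.entry_id)
            if z is None or z <= z_threshold:
                continue
            if index is not None and (m.entry_id, pu_const_name) not in index:
                continue
            if m.entry.category is not None:
                categories.append(
                    ProvenancedCategory(m.entry.category, s.doc_id, s.sentence_index, m.entry_id)
                )
            elif m.bound_args is not None:
                atom = Atom(m.entry.template.predicate, m.bound_args)  # type: ignore[union-attr]
                atoms.append(ProvenancedAtom(atom, s.doc_id, s.sentence_index, m.entry_id))
    return categories, atoms
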