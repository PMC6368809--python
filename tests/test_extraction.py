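"""Dictionary matching, linguistic pair rules, Z-score statistics and
the training-corpus validation index."""

import math

import pytest

from protofunc.extraction import (
    Document,
    ExtractionError,
    Lexicon,
    LexiconEntry,
    PredicateTemplate,
    RelatedPairIndex,
    build_related_pair_index,
    classify_pair,
    compute_zscore,
    corpus_sentences,
    extract_given_premises,
    match_terms,
    pair_statistics,
    read_corpus,
    segment_sentences,
    tokenize,
    write_corpus,
)
from protofunc.logic import Atom, ConstantSymbol

from conftest import make_demo_lexicon


# ---------------------------------------------------------------------------
# Segmentation and tokenization
# ---------------------------------------------------------------------------


def test_segment_two_sentences():
    sents = segment_sentences("d1", "A binds B. C folds.")
    assert [s.text for s in sents] == ["A binds B.", "C folds."]
    assert [s.sentence_index for s in sents] == [0, 1]


def test_segment_keeps_abbreviations_together():
    sents = segment_sentences("d1", "Chaperones, e.g. Hsp70, assist folding. They bind.")
    assert len(sents) == 2
    assert "e.g. Hsp70" in sents[0].text


def test_segment_sentence_without_terminal_period():
    sents = segment_sentences("d1", "the protein folds rapidly")
    assert len(sents) == 1 and sents[0].text == "the protein folds rapidly"


def test_segment_empty_text():
    assert segment_sentences("d1", "") == []


def test_segment_preserves_non_whitespace():
    text = "P53 binds MDM2. It regulates apoptosis! Does it fold?"
    sents = segment_sentences("d1", text)
    assert "".join("".join(s.text.split()) for s in sents) == "".join(text.split())


def test_tokenize_lowercases_and_strips_punctuation():
    assert tokenize("P53, which folds.") == ("p53", "which", "folds")


# ---------------------------------------------------------------------------
# Term matching
# ---------------------------------------------------------------------------


def test_match_template_binds_nearest_protein(demo_lexicon):
    (s,) = segment_sentences("d1", "the folding of PA stabilizes the complex")
    mentions = match_terms(s, demo_lexicon)
    fd = next(m for m in mentions if m.entry_id == "fd")
    assert fd.bound_args == (ConstantSymbol("PA", "protein"),)


def test_match_longest_pattern_wins():
    lex = Lexicon()
    lex.entries.append(
        LexiconEntry("aas", ("amino acid sequence",), template=PredicateTemplate("AAS", ("protein",)))
    )
    lex.entries.append(
        LexiconEntry("seq", ("sequence",), category="CAT:1")
    )
    lex.add_constant("PA", "protein")
    (s,) = segment_sentences("d1", "the amino acid sequence of PA")
    ids = [m.entry_id for m in match_terms(s, lex)]
    assert "aas" in ids and "seq" not in ids


def test_match_no_lexicon_phrase(demo_lexicon):
    (s,) = segment_sentences("d1", "nothing relevant happens here")
    assert match_terms(s, demo_lexicon) == []


def test_match_is_case_insensitive(demo_lexicon):
    (s,) = segment_sentences("d1", "the FOLDING of pa was observed")
    ids = {m.entry_id for m in match_terms(s, demo_lexicon)}
    assert {"fd", "PA"} <= ids


def test_match_two_slot_template_binds_two_proteins(demo_lexicon):
    (s,) = segment_sentences("d1", "a non-covalent bond links PA and PB")
    mentions = match_terms(s, demo_lexicon)
    nc = next(m for m in mentions if m.entry_id == "ncbnd")
    assert nc.bound_args is not None
    assert {c.name for c in nc.bound_args} == {"PA", "PB"}


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------


def _mentions(lex, text):
    (s,) = segment_sentences("d1", text)
    return s, match_terms(s, lex)


def test_pronoun_connector_relates(demo_lexicon):
    s, mentions = _mentions(demo_lexicon, "PA , which regulates apoptosis regulation")
    pa = next(m for m in mentions if m.entry_id == "PA")
    cat = next(m for m in mentions if m.entry_id == "cat_apop")
    assert classify_pair(s, pa, cat).label == "related"


def test_disconnector_unrelates(demo_lexicon):
    s, mentions = _mentions(demo_lexicon, "PA was stable whereas folding failed")
    pa = next(m for m in mentions if m.entry_id == "PA")
    fd = next(m for m in mentions if m.entry_id == "fd")
    assert classify_pair(s, pa, fd).label == "unrelated"


def test_disconnector_overrides_pronoun(demo_lexicon):
    s, mentions = _mentions(demo_lexicon, "PA , which was stable whereas folding failed")
    pa = next(m for m in mentions if m.entry_id == "PA")
    fd = next(m for m in mentions if m.entry_id == "fd")
    assert classify_pair(s, pa, fd).label == "unrelated"


def test_no_connector_undetermined(demo_lexicon):
    s, mentions = _mentions(demo_lexicon, "PA and folding were measured")
    pa = next(m for m in mentions if m.entry_id == "PA")
    fd = next(m for m in mentions if m.entry_id == "fd")
    assert classify_pair(s, pa, fd).label == "undetermined"


def test_classify_pair_symmetric(demo_lexicon):
    s, mentions = _mentions(demo_lexicon, "PA , which regulates folding")
    pa = next(m for m in mentions if m.entry_id == "PA")
    fd = next(m for m in mentions if m.entry_id == "fd")
    assert classify_pair(s, pa, fd).label == classify_pair(s, fd, pa).label == "related"


def test_classify_pair_rejects_overlap(demo_lexicon):
    s, mentions = _mentions(demo_lexicon, "the folding of PA")
    fd = next(m for m in mentions if m.entry_id == "fd")
    with pytest.raises(ExtractionError):
        classify_pair(s, fd, fd)


# ---------------------------------------------------------------------------
# Z-score
# ---------------------------------------------------------------------------


def test_zscore_null_expectation_is_zero():
    # k exactly equal to N * (n_a/N)(n_b/N) = 10
    assert compute_zscore(10, 100, 100, 1000) == pytest.approx(0.0)


def test_zscore_strong_association():
    z = compute_zscore(40, 50, 50, 1000)
    assert z == pytest.approx((40 - 2.5) / math.sqrt(2.5 * 0.9975), rel=1e-9)
    assert z == pytest.approx(23.74, abs=0.01)


def test_zscore_rare_pair_slightly_negative():
    assert compute_zscore(0, 1, 1, 1000) == pytest.approx(-0.0316, abs=1e-4)


@pytest.mark.parametrize(
    "args",
    [
        (1, 1, 1, 0),  # N = 0
        (5, 3, 10, 100),  # k > min(n_a, n_b)
        (0, 101, 5, 100),  # n_a > N
        (0, 0, 5, 100),  # p = 0
        (100, 100, 100, 100),  # p = 1
    ],
)
def test_zscore_invalid_inputs(args):
    with pytest.raises(ExtractionError):
        compute_zscore(*args)


# ---------------------------------------------------------------------------
# Training index
# ---------------------------------------------------------------------------


def _docs(texts):
    return [Document(f"d{i}", ("PU",), t) for i, t in enumerate(texts)]


def test_index_contains_planted_related_pair(demo_lexicon):
    docs = _docs(
        ["the folding of PA , which involves PU ."] * 8
        + ["the experiment was repeated ."] * 40
    )
    index = build_related_pair_index(docs, demo_lexicon)
    assert ("fd", "PU") in index
    assert ("PU", "fd") in index  # order-independent


def test_index_excludes_disconnected_pair(demo_lexicon):
    docs = _docs(
        ["the folding was measured whereas PU was measured ."] * 8
        + ["the experiment was repeated ."] * 40
    )
    index = build_related_pair_index(docs, demo_lexicon)
    assert ("fd", "PU") not in index


def test_index_empty_corpus(demo_lexicon):
    assert build_related_pair_index([], demo_lexicon).pairs == {}


def test_index_tsv_roundtrip(tmp_path, demo_lexicon):
    docs = _docs(
        ["the folding of PA , which involves PU ."] * 8
        + ["the experiment was repeated ."] * 40
    )
    index = build_related_pair_index(docs, demo_lexicon)
    path = tmp_path / "index.tsv"
    index.to_tsv(path)
    again = RelatedPairIndex.from_tsv(path)
    assert again.pairs == pytest.approx(index.pairs)


# ---------------------------------------------------------------------------
# Given-premise extraction
# ---------------------------------------------------------------------------


def test_extract_template_atoms(demo_lexicon):
    docs = _docs(
        ["the folding of PA , which involves PU .",
         "the structure of PA , which involves PU ."] * 4
        + ["the experiment was repeated ."] * 30
    )
    categories, atoms = extract_given_premises(docs, "PU", demo_lexicon)
    pa = ConstantSymbol("PA", "protein")
    assert {a.atom for a in atoms} == {Atom("FD", (pa,)), Atom("ST", (pa,))}
    assert categories == []


def test_extract_explicit_category(demo_lexicon):
    docs = _docs(
        ["the apoptosis regulation , which involves PU ."] * 4
        + ["the experiment was repeated ."] * 30
    )
    categories, atoms = extract_given_premises(docs, "PU", demo_lexicon)
    assert {c.category for c in categories} == {"GO:0042981"}
    assert atoms == []


def test_extract_nothing_from_disconnected_corpus(demo_lexicon):
    docs = _docs(
        ["the folding of PA was measured whereas PU was measured ."] * 6
        + ["the experiment was repeated ."] * 30
    )
    categories, atoms = extract_given_premises(docs, "PU", demo_lexicon)
    assert categories == [] and atoms == []


def test_extract_unknown_protein(demo_lexicon):
    docs = _docs(["the folding of PA , which involves PU ."])
    with pytest.raises(ExtractionError):
        extract_given_premises(docs, "PX99", demo_lexicon)


def test_extract_invariant_to_document_order(demo_lexicon):
    texts = (
        ["the folding of PA , which involves PU ."] * 3
        + ["the structure of PB , which involves PU ."] * 3
        + ["the experiment was repeated ."] * 20
    )
    docs = _docs(texts)
    cats1, atoms1 = extract_given_premises(docs, "PU", demo_lexicon)
    cats2, atoms2 = extract_given_premises(list(reversed(docs)), "PU", demo_lexicon)
    assert {a.atom for a in atoms1} == {a.atom for a in atoms2}
    assert sorted(a.doc_id for a in atoms1) == sorted(a.doc_id for a in atoms2)


def test_extracted_atom_constants_mentioned_in_cited_sentence(demo_lexicon):
    docs = _docs(
        ["the folding of PA , which involves PU ."] * 4
        + ["the experiment was repeated ."] * 20
    )
    _, atoms = extract_given_premises(docs, "PU", demo_lexicon)
    by_doc = {d.doc_id: d for d in docs}
    for pa in atoms:
        sent = segment_sentences(pa.doc_id, by_doc[pa.doc_id].text)[pa.sentence_index]
        for const in pa.atom.args:
            assert const.name.lower() in sent.tokens


def test_index_gate_filters_unvalidated_pairs(demo_lexicon):
    docs = _docs(
        ["the folding of PA , which involves PU ."] * 4
        + ["the experiment was repeated ."] * 20
    )
    empty_index = RelatedPairIndex()
    categories, atoms = extract_given_premises(docs, "PU", demo_lexicon, index=empty_index)
    assert categories == [] and atoms == []


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------


def test_corpus_jsonl_roundtrip(tmp_path):
    docs = [Document("d1", ("PU", "PA"), "the folding of PA .")]
    path = tmp_path / "corpus.jsonl"
    write_corpus(docs, path)
    assert read_corpus(path) == docs


def test_corpus_malformed_line_reports_number(tmp_path):
    path = tmp_path / "corpus.jsonl"
    path.write_text('{"doc_id": "d1", "protein_ids": [], "text": "x"}\n{"nope": 1}\n')
    with pytest.raises(ExtractionError, match="line 2"):
        read_corpus(path)
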