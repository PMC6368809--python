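import pytest

import protofunc as pf
from protofunc.extraction import Lexicon, LexiconEntry, PredicateTemplate


@pytest.fixture(scope="session")
def rules():
    return pf.load_default_rules()


@pytest.fixture(scope="session")
def examples():
    return pf.worked_example_fixtures()


def make_demo_lexicon() -> Lexicon:
    """Small lexicon: folding/structure/function templates, one category
    term, and the constants used by the synthetic scenarios."""
    lex = Lexicon()
    lex.entries.append(
        LexiconEntry("fd", ("folding",), template=PredicateTemplate("FD", ("protein",)))
    )
    lex.entries.append(
        LexiconEntry("st", ("structure",), template=PredicateTemplate("ST", ("protein",)))
    )
    lex.entries.append(
        LexiconEntry("fn", ("catalytic function",), template=PredicateTemplate("F", ("protein",)))
    )
    lex.entries.append(
        LexiconEntry(
            "ncbnd",
            ("non-covalent bond",),
            template=PredicateTemplate("NCBND", ("protein", "protein")),
        )
    )
    lex.entries.append(
        LexiconEntry("cat_apop", ("apoptosis regulation",), category="GO:0042981")
    )
    lex.add_constant("PA", "protein")
    lex.add_constant("PB", "protein")
    lex.add_constant("PU", "protein")
    lex.add_constant("ATP", "ligand")
    return lex


@pytest.fixture()
def demo_lexicon():
    return make_demo_lexicon()
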