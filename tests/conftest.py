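import pytest

from biolemma import Lemmatizer, fixtures


@pytest.fixture(scope="session")
def hierarchy():
    return fixtures.default_hierarchy()


@pytest.fixture(scope="session")
def resources():
    return fixtures.default_resources()


@pytest.fixture(scope="session")
def lexicon(resources):
    return resources[1]


@pytest.fixture(scope="session")
def ruleset(resources):
    return resources[2]


@pytest.fixture(scope="session")
def lemmatizer(resources):
    h, lex, rs = resources
    return Lemmatizer(h, lex, rs)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Generated resource files on disk (hierarchy/lexicon/rules)."""
    outdir = tmp_path_factory.mktemp("resources")
    fixtures.build_fixture_hierarchy(outdir)
    fixtures.build_fixture_lexicon(outdir)
    fixtures.build_fixture_rules(outdir)
    return outdir


#: The 9 mis-annotation rows: (token, generated POS, lemmatizer output,
#: corpus gold lemma).  The lemmatizer column is what the fixture
#: resources must reproduce; all rows disagree with the corpus gold.
LLL05_INCONSISTENT_ROWS = [
    ("predominants", "NNS", "predominant", "predominants"),
    ("coding", "NN", "coding", "code"),
    ("Most", "JJS", "many", "most"),
    ("primer", "NN", "primer", "prime"),
    ("directed", "JJ", "directed", "direct"),
    ("might", "MD", "may", "might"),
    ("located", "JJ", "located", "locate"),
    ("least", "JJS", "little", "least"),
    ("more", "RBR", "much", "more"),
]

#: The 13 task-specific-normalization rows: gold lemmas are entity
#: renamings / expansions beyond canonical lemmatization, so the
#: lemmatizer output is the surface form for all of them.
LLL05_TASK_SPECIFIC_ROWS = [
    ("sigmaG", "NN", "sigmaG", "sigG"),
    ("sigmaK", "NN", "sigmaK", "sigK"),
    ("sigmaE", "NN", "sigmaE", "sigE"),
    ("sigmaA", "NN", "sigmaA", "sigA"),
    ("sigmaD", "NN", "sigmaD", "sigD"),
    ("sigmaF", "NN", "sigmaF", "sigF"),
    ("sigmaL", "NN", "sigmaL", "sigL"),
    ("sigmaB", "NN", "sigmaB", "sigB"),
    ("sigmaH", "NN", "sigmaH", "sigH"),
    ("ykvD", "NN", "ykvD", "kinD"),
    ("ykrQ", "NN", "ykrQ", "kinE"),
    ("B.", "NNP", "B.", "Bacillus"),
    ("fulfil", "VB", "fulfil", "fulfill"),
]
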