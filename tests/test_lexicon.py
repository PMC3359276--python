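import random

import pytest

from biolemma import (
    LexiconError,
    PosTag,
    Stage,
    Tagset,
    load_lexicon,
    parse_lexicon,
    save_lexicon,
)
from biolemma.fixtures import lexicon_lines, manifest
from biolemma.normalize import normalize_unicode


def penn(label):
    return PosTag(label, Tagset.PENN)


# -- loading / serialization ----------------------------------------


def test_fixture_lexicon_entry_count_matches_manifest(lexicon):
    assert len(lexicon) == manifest().lexicon_entries


def test_duplicate_lines_collapse(hierarchy):
    line = "spermatogonia\tNNS\tspermatogonium\tPENN\tfixture"
    lex = parse_lexicon([line, line], hierarchy)
    assert len(lex) == 1
    hit = lex.lookup_exact("spermatogonia", penn("NNS"))
    assert hit.stage is Stage.EXACT
    assert hit.lemmas == ("spermatogonium",)


def test_unknown_pos_tag_is_load_error_naming_line(hierarchy):
    with pytest.raises(LexiconError, match="line 2"):
        parse_lexicon(
            ["cell\tNN\tcell\tPENN\tcore", "cell\tXX\tcell\tPENN\tcore"], hierarchy
        )


def test_empty_lemma_field_is_load_error(hierarchy):
    with pytest.raises(LexiconError):
        parse_lexicon(["cell\tNN\t\tPENN\tcore"], hierarchy)


def test_load_save_load_is_identity(tmp_path, hierarchy, lexicon):
    p1 = tmp_path / "lex1.tsv"
    save_lexicon(lexicon, p1)
    lex2 = load_lexicon(p1, hierarchy)
    p2 = tmp_path / "lex2.tsv"
    save_lexicon(lex2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert lex2.entries == lexicon.entries


def test_same_surface_pos_under_different_tagsets_coexist(lexicon):
    # might/MD (Penn) and might/vmd (NUPOS) both present
    assert lexicon.lookup_exact("might", penn("MD")).lemmas == ("may",)
    assert lexicon.lookup_exact("might", PosTag("vmd", Tagset.NUPOS)).lemmas == ("may",)


# -- exact lookup ---------------------------------------------------


def test_exact_hit(lexicon):
    hit = lexicon.lookup_exact("anlagen", penn("NNS"))
    assert hit.stage is Stage.EXACT
    assert hit.candidates == (("anlage", penn("NNS")),)


def test_exact_miss_is_none_not_error(lexicon):
    miss = lexicon.lookup_exact("anlagen", penn("NN"))
    assert miss.stage is Stage.NONE
    assert miss.candidates == ()


def test_exact_via_case_folding(lexicon):
    hit = lexicon.lookup_exact("Most", penn("JJS"))
    assert hit.stage is Stage.EXACT
    assert hit.lemmas == ("many",)


# -- hierarchical lookup --------------------------------------------


@pytest.mark.parametrize(
    "word, pos, lemmas, stage",
    [
        ("anlagen", "NN", ("anlage",), Stage.SIBLING),
        ("spermatogonia", "NN", ("spermatogonium",), Stage.SIBLING),
        ("Laboratories", "NNP", ("Laboratory",), Stage.SIBLING),
        ("Products", "NNP", ("Product",), Stage.SIBLING),
        ("odds", "NNS", ("odds",), Stage.SIBLING),
        ("anlagen", "NNS", ("anlage",), Stage.EXACT),  # exact beats sibling
        ("genera", "NNS", ("genus",), Stage.CROSS_TAGSET),  # NUPOS-only entry
        ("adorning", "VBG", ("adorn",), Stage.CROSS_TAGSET),
    ],
)
def test_hierarchical_stages(lexicon, word, pos, lemmas, stage):
    hit = lexicon.lookup_hierarchical(word, penn(pos))
    assert hit.stage is stage
    assert hit.lemmas == lemmas


def test_cross_tagset_disabled_for_nupos_input_by_default(lexicon):
    # a word present only under Penn tags is not reachable from a
    # NUPOS query unless the symmetric direction is enabled
    miss = lexicon.lookup_hierarchical("appendix", PosTag("vvi", Tagset.NUPOS))
    assert miss.stage is Stage.NONE
    # appendix is a noun; with cross_both a NUPOS noun query reaches it
    hit = lexicon.lookup_hierarchical(
        "appendix", PosTag("n1", Tagset.NUPOS), cross_both=True
    )
    assert hit.stage is Stage.CROSS_TAGSET


def test_exact_nonempty_implies_hierarchical_identical(lexicon):
    for word, pos in [("anlagen", "NNS"), ("coding", "NN"), ("most", "JJS")]:
        exact = lexicon.lookup_exact(word, penn(pos))
        hier = lexicon.lookup_hierarchical(word, penn(pos))
        assert exact.stage is Stage.EXACT
        assert hier.stage is Stage.EXACT
        assert hier.candidates == exact.candidates


# -- any-POS lookup -------------------------------------------------


def test_any_pos_returns_all_senses(lexicon):
    hit = lexicon.lookup_any_pos("axes")
    assert hit.stage is Stage.ANY_POS
    assert set(hit.lemmas) == {"axe", "axis"}


def test_any_pos_single_sense(lexicon):
    hit = lexicon.lookup_any_pos("coding")
    assert ("coding", penn("NN")) in hit.candidates


def test_any_pos_unknown_word(lexicon):
    assert lexicon.lookup_any_pos("qwertyzyx").stage is Stage.NONE


# -- known-forms membership -----------------------------------------


@pytest.mark.parametrize(
    "word, expected",
    [
        ("appendix", True),  # lemma-side membership
        ("appendixis", False),
        ("anlagen", True),  # surface-side membership
        ("", False),
    ],
)
def test_contains_form(lexicon, word, expected):
    assert lexicon.contains_form(word) is expected


# -- brute-force oracle equivalence ---------------------------------


def brute_force_hierarchical(entry_keys, word, pos, hierarchy, lexicon_known):
    """Independent re-derivation of the staged search by scanning every
    lexicon entry, mirroring the verbatim-then-casefolded key policy."""
    key = normalize_unicode(word).normalized
    folded = key.casefold()
    # one full scan of the lexicon per query
    matching = [(k, p, lemma) for k, p, lemma in entry_keys if k.casefold() == folded]

    def probe(tag):
        verbatim = {
            (lemma, p) for k, p, lemma in matching if p == tag and k == key
        }
        if verbatim:
            return verbatim
        return {(lemma, p) for k, p, lemma in matching if p == tag}

    hits = probe(pos)
    if hits:
        return hits, Stage.EXACT
    hits = set()
    for sib in hierarchy.siblings_of(pos):
        hits |= probe(sib)
    if hits:
        return hits, Stage.SIBLING
    if pos.tagset is Tagset.PENN:
        images = sorted(hierarchy.map_tag(pos, Tagset.NUPOS), key=lambda t: t.label)
        for img in images:
            hits |= probe(img)
        if not hits:
            for img in images:
                for sib in hierarchy.siblings_of(img):
                    hits |= probe(sib)
        if hits:
            return hits, Stage.CROSS_TAGSET
    return set(), Stage.NONE


def test_hierarchical_search_matches_brute_force_scan(hierarchy, lexicon):
    entry_keys = [
        (normalize_unicode(e.surface).normalized, e.pos, e.lemma)
        for e in lexicon.entries
    ]
    surfaces = sorted({e.surface for e in lexicon.entries})
    rng = random.Random(20120401)
    words = rng.sample(surfaces, 60) + [
        "anlagen", "spermatogonia", "Laboratories", "genera", "adorning",
        "Most", "odds", "axes", "notaword",
    ]
    probe_tags = [penn(p) for p in hierarchy.penn_to_class] + [
        PosTag(n, Tagset.NUPOS) for n in hierarchy.nupos_to_penn
    ]
    for word in words:
        for pos in probe_tags:
            expected, stage = brute_force_hierarchical(
                entry_keys, word, pos, hierarchy, lexicon.known_forms
            )
            got = lexicon.lookup_hierarchical(word, pos)
            assert got.stage is stage, (word, pos)
            assert set(got.candidates) == expected, (word, pos)


def test_stage_monotonicity_adding_entry_moves_result_earlier(hierarchy, lexicon):
    # (anlagen, NN) resolves at SIBLING; adding an exact NN entry moves
    # it to EXACT, never to a later stage
    base = lexicon.lookup_hierarchical("anlagen", penn("NN"))
    assert base.stage is Stage.SIBLING
    extended = parse_lexicon(
        lexicon_lines() + ["anlagen\tNN\tanlage\tPENN\tfixture"], hierarchy
    )
    assert extended.lookup_hierarchical("anlagen", penn("NN")).stage is Stage.EXACT
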