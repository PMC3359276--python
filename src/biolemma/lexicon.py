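"""Lemmatization lexicon: loading, indexing and POS-relaxed search.

Each entry records an inflected surface form, its POS tag (Penn
Treebank or NUPOS), the lemma, and a provenance label.  Entries with
the same surface and tag label under *different* tagsets coexist.

Search proceeds in strictly ordered stages:

EXACT         the (word, POS) pair as given,
SIBLING       the word under each inflection-family sibling of the POS
              (same tagset) — this is what recovers *anlage* from the
              mis-tagged input (anlagen, NN),
CROSS_TAGSET  the word under the images of the POS in the other
              tagset, then under their siblings (by default only for
              Penn-tagged input, which is what prevailing taggers emit),
ANY_POS       every entry for the word regardless of POS (no-POS mode).

The first non-empty stage wins.  Keys are Unicode-normalized; the
verbatim surface is tried before the case-folded one, so (Most, JJS)
still finds most/JJS→many while case distinctions in the lexicon are
respected.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from .hierarchy import PosHierarchy, PosTag, Tagset, UnknownTagError
from .normalize import normalize_unicode


class Stage(str, Enum):
    EXACT = "EXACT"
    SIBLING = "SIBLING"
    CROSS_TAGSET = "CROSS_TAGSET"
    ANY_POS = "ANY_POS"
    NONE = "NONE"


class LexiconError(ValueError):
    """Malformed lexicon file."""


@dataclass(frozen=True, order=True)
class LexiconEntry:
    surface: str
    pos: PosTag
    lemma: str
    source: str = "fixture"

    def __post_init__(self) -> None:
        if not self.surface or not self.lemma:
            raise ValueError("surface and lemma must be non-empty")


@dataclass(frozen=True)
class LookupResult:
    candidates: tuple[tuple[str, PosTag], ...]
    stage: Stage

    def __bool__(self) -> bool:
        return self.stage is not Stage.NONE

    @property
    def lemmas(self) -> tuple[str, ...]:
        return tuple(lemma for lemma, _ in self.candidates)


_MISS = LookupResult(candidates=(), stage=Stage.NONE)


def _dedup_sorted(pairs: Iterable[tuple[str, PosTag]]) -> tuple[tuple[str, PosTag], ...]:
    return tuple(sorted(set(pairs), key=lambda lp: (lp[0], lp[1].label, lp[1].tagset.value)))


class Lexicon:
    """Indexed multiset of :class:`LexiconEntry`."""

    def __init__(self, entries: Iterable[LexiconEntry], hierarchy: PosHierarchy):
        self.hierarchy = hierarchy
        # de-duplicate on (surface, pos label, tagset, lemma)
        seen: dict[tuple[str, str, Tagset, str], LexiconEntry] = {}
        for e in entries:
            if not hierarchy.has_tag(e.pos):
                raise LexiconError(
                    f"entry {e.surface!r}: POS {e.pos.label!r} not in hierarchy "
                    f"({e.pos.tagset.value})"
                )
            seen.setdefault((e.surface, e.pos.label, e.pos.tagset, e.lemma), e)
        self.entries: tuple[LexiconEntry, ...] = tuple(sorted(seen.values()))
        self._exact: dict[tuple[str, str, Tagset], set[tuple[str, PosTag]]] = {}
        self._folded: dict[tuple[str, str, Tagset], set[tuple[str, PosTag]]] = {}
        self._by_word: dict[str, set[tuple[str, PosTag]]] = {}
        self._by_word_folded: dict[str, set[tuple[str, PosTag]]] = {}
        forms: set[str] = set()
        for e in self.entries:
            key = normalize_unicode(e.surface).normalized
            pair = (e.lemma, e.pos)
            self._exact.setdefault((key, e.pos.label, e.pos.tagset), set()).add(pair)
            self._folded.setdefault((key.casefold(), e.pos.label, e.pos.tagset), set()).add(pair)
            self._by_word.setdefault(key, set()).add(pair)
            self._by_word_folded.setdefault(key.casefold(), set()).add(pair)
            forms.add(key.casefold())
            forms.add(normalize_unicode(e.lemma).normalized.casefold())
        self.known_forms: frozenset[str] = frozenset(forms)

    def __len__(self) -> int:
        return len(self.entries)

    # -- primitive lookups ------------------------------------------

    def _probe(self, word_key: str, pos: PosTag) -> set[tuple[str, PosTag]]:
        hit = self._exact.get((word_key, pos.label, pos.tagset))
        if hit:
            return hit
        return self._folded.get((word_key.casefold(), pos.label, pos.tagset), set())

    def lookup_exact(self, word: str, pos: PosTag) -> LookupResult:
        """Exact (word, POS) match; verbatim surface first, then case-folded."""
        if not self.hierarchy.has_tag(pos):
            raise UnknownTagError(f"unknown tag {pos.label!r} ({pos.tagset.value})")
        key = normalize_unicode(word).normalized
        hit = self._probe(key, pos)
        if hit:
            return LookupResult(candidates=_dedup_sorted(hit), stage=Stage.EXACT)
        return _MISS

    def lookup_hierarchical(self, word: str, pos: PosTag, *, cross_both: bool = False) -> LookupResult:
        """POS-relaxed search: EXACT → SIBLING → CROSS_TAGSET → NONE.

        ``cross_both=True`` enables the NUPOS→Penn direction as well as
        the default Penn→NUPOS direction.
        """
        exact = self.lookup_exact(word, pos)
        if exact:
            return exact
        h = self.hierarchy
        key = normalize_unicode(word).normalized

        sib_hits: set[tuple[str, PosTag]] = set()
        for sib in h.siblings_of(pos):
            sib_hits |= self._probe(key, sib)
        if sib_hits:
            return LookupResult(candidates=_dedup_sorted(sib_hits), stage=Stage.SIBLING)

        if pos.tagset is Tagset.PENN or cross_both:
            other = Tagset.NUPOS if pos.tagset is Tagset.PENN else Tagset.PENN
            images = sorted(h.map_tag(pos, other), key=lambda t: t.label)
            cross_hits: set[tuple[str, PosTag]] = set()
            for img in images:
                cross_hits |= self._probe(key, img)
            if not cross_hits:
                for img in images:
                    for sib in h.siblings_of(img):
                        cross_hits |= self._probe(key, sib)
            if cross_hits:
                return LookupResult(
                    candidates=_dedup_sorted(cross_hits), stage=Stage.CROSS_TAGSET
                )
        return _MISS

    def lookup_any_pos(self, word: str) -> LookupResult:
        """All (lemma, POS) pairs for the word across both tagsets."""
        key = normalize_unicode(word).normalized
        hit = self._by_word.get(key) or self._by_word_folded.get(key.casefold())
        if hit:
            return LookupResult(candidates=_dedup_sorted(hit), stage=Stage.ANY_POS)
        return _MISS

    def contains_form(self, word: str) -> bool:
        """True iff the case-folded word is a known surface or lemma."""
        if not word:
            return False
        return normalize_unicode(word).normalized.casefold() in self.known_forms


def parse_lexicon(lines: Iterable[str], hierarchy: PosHierarchy) -> Lexicon:
    """Parse ``surface<TAB>pos<TAB>lemma<TAB>tagset<TAB>source`` records."""
    entries: list[LexiconEntry] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise LexiconError(f"line {lineno}: expected 5 tab-separated fields")
        surface, pos_label, lemma, tagset, source = fields
        if not surface or not lemma:
            raise LexiconError(f"line {lineno}: empty surface or lemma")
        try:
            ts = Tagset(tagset)
        except ValueError:
            raise LexiconError(f"line {lineno}: unknown tagset {tagset!r}") from None
        pos = PosTag(pos_label, ts)
        if not hierarchy.has_tag(pos):
            raise LexiconError(
                f"line {lineno}: POS tag {pos_label!r} not in the {ts.value} hierarchy"
            )
        entries.append(LexiconEntry(surface, pos, lemma, source))
    return Lexicon(entries, hierarchy)


def load_lexicon(path: str | Path, hierarchy: PosHierarchy) -> Lexicon:
    with open(path, encoding="utf-8") as fh:
        return parse_lexicon(fh, hierarchy)


def save_lexicon(lex: Lexicon, path: str | Path) -> Path:
    """Write sorted, de-duplicated records; load→save→load is identity."""
    path = Path(path)
    lines = sorted(
        f"{e.surface}\t{e.pos.label}\t{e.lemma}\t{e.pos.tagset.value}\t{e.source}"
        for e in lex.entries
    )
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    return path
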