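"""Lemmatization pipeline.

The flow for a (word, POS) input is: Unicode-normalize the lookup key,
search the lexicon hierarchically (exact → sibling POS → cross-tagset),
and only if the lexicon misses fall back to the word class's suffix
detachment rules; inputs whose POS mandates no inflection (punctuation,
symbols, foreign words, singular nouns) bypass the rules and return the
surface form.  Once the lexicon yields a lemma, the rule engine is
never consulted.  Without a POS, the entire lexicon is searched and
lemmas for all possible parts of speech are returned, leaving
disambiguation to the caller.

Every token yields at least one lemma: surface fallback is total.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

from .hierarchy import PosHierarchy, PosTag, Tagset, UnknownTagError
from .lexicon import Lexicon, Stage
from .rules import RuleApplication, RuleSet, apply_rules, bypass_check


class Provenance(str, Enum):
    EXACT = "EXACT"
    SIBLING = "SIBLING"
    CROSS_TAGSET = "CROSS_TAGSET"
    ANY_POS = "ANY_POS"
    RULE = "RULE"
    SURFACE = "SURFACE"


_STAGE_TO_PROVENANCE = {
    Stage.EXACT: Provenance.EXACT,
    Stage.SIBLING: Provenance.SIBLING,
    Stage.CROSS_TAGSET: Provenance.CROSS_TAGSET,
    Stage.ANY_POS: Provenance.ANY_POS,
}

#: General-English abbreviation/symbol expansions inherited from the
#: upstream toolkit.  Off by default: in biomedical text returning the
#: surface form of abbreviations is the more accurate behavior.
ABBREV_EXPANSIONS: dict[str, str] = {
    "&": "and",
    "St.": "saint",
}

_NUMERIC = re.compile(r"[0-9][0-9.,%+–-]*|[0-9.,%+-]*[0-9]")
_COMPOUND_SEP = re.compile(r"([-/])")


@dataclass(frozen=True)
class TokenInput:
    text: str
    pos: str | None = None
    tagset: Tagset = Tagset.PENN

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("token text must be non-empty")


@dataclass(frozen=True)
class LemmaResult:
    input: TokenInput
    lemmas: tuple[tuple[str, PosTag | None], ...]
    provenance: Provenance
    rule_trace: RuleApplication | None = None

    @property
    def lemma(self) -> str:
        """Primary (first) lemma."""
        return self.lemmas[0][0]

    @property
    def lemma_strings(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(l for l, _ in self.lemmas))


@dataclass
class LemmatizerConfig:
    expand_abbrev: bool = False
    split_compounds: bool = True
    cross_tagset_both: bool = False
    enforce_rule_validation: bool = True
    lenient: bool = False


class Lemmatizer:
    """Bundles loaded resources and configuration."""

    def __init__(
        self,
        hierarchy: PosHierarchy,
        lexicon: Lexicon,
        ruleset: RuleSet,
        config: LemmatizerConfig | None = None,
    ):
        self.hierarchy = hierarchy
        self.lexicon = lexicon
        self.ruleset = ruleset
        self.config = config or LemmatizerConfig()

    # -- public API -------------------------------------------------

    def lemmatize(
        self, text: str, pos: str | None = None, tagset: Tagset | str = Tagset.PENN
    ) -> LemmaResult:
        tok = TokenInput(text=text.strip(), pos=pos, tagset=Tagset(tagset))
        return self._lemmatize_token(tok)

    def lemmatize_stream(
        self, tokens: Iterable[TokenInput]
    ) -> Iterator[LemmaResult]:
        """Element-wise, order-preserving lemmatization.  Under the
        lenient config, per-token errors yield a surface-form result
        instead of raising."""
        for tok in tokens:
            try:
                yield self._lemmatize_token(tok)
            except (UnknownTagError, ValueError):
                if not self.config.lenient:
                    raise
                yield LemmaResult(
                    input=tok,
                    lemmas=((tok.text, None),),
                    provenance=Provenance.SURFACE,
                )

    # -- pipeline ---------------------------------------------------

    def _resolve_pos(self, tok: TokenInput) -> PosTag | None:
        if tok.pos is None:
            return None
        return self.hierarchy.tag(tok.pos, tok.tagset)

    def _lemmatize_token(self, tok: TokenInput) -> LemmaResult:
        pos = self._resolve_pos(tok)
        text = tok.text

        if self.config.expand_abbrev and text in ABBREV_EXPANSIONS:
            return LemmaResult(
                input=tok,
                lemmas=((ABBREV_EXPANSIONS[text], pos),),
                provenance=Provenance.EXACT,
            )

        # lexicon first (full token, POS-relaxed when a POS is given)
        if pos is not None:
            hit = self.lexicon.lookup_hierarchical(
                text, pos, cross_both=self.config.cross_tagset_both
            )
        else:
            hit = self.lexicon.lookup_any_pos(text)
        if hit:
            lemmas = self._display_candidates(hit.candidates) if pos is None else hit.candidates
            return LemmaResult(
                input=tok,
                lemmas=tuple(lemmas),
                provenance=_STAGE_TO_PROVENANCE[hit.stage],
            )

        # compound words: split at hyphen/slash, lemmatize each part
        if self.config.split_compounds and self._is_compound(text):
            return self._lemmatize_compound(tok, pos)

        # numbers are their own lemmas
        if _NUMERIC.fullmatch(text):
            return LemmaResult(
                input=tok, lemmas=((text, pos),), provenance=Provenance.SURFACE
            )

        if pos is not None:
            if bypass_check(text, pos, self.hierarchy):
                return LemmaResult(
                    input=tok, lemmas=((text, pos),), provenance=Provenance.SURFACE
                )
            wc = self.hierarchy.word_class_of(pos)
            app = apply_rules(
                text,
                wc,
                self.ruleset,
                self.lexicon,
                enforce_validation=self.config.enforce_rule_validation,
            )
            if app.accepted:
                return LemmaResult(
                    input=tok,
                    lemmas=((app.candidate, pos),),
                    provenance=Provenance.RULE,
                    rule_trace=app,
                )
            return LemmaResult(
                input=tok,
                lemmas=((text, pos),),
                provenance=Provenance.SURFACE,
                rule_trace=app,
            )

        # no-POS miss: try every word class's rule chain, merge accepted
        candidates: list[tuple[str, PosTag]] = []
        trace: RuleApplication | None = None
        for wc in sorted(self.ruleset.by_class):
            app = apply_rules(
                text,
                wc,
                self.ruleset,
                self.lexicon,
                enforce_validation=self.config.enforce_rule_validation,
            )
            if app.accepted:
                candidates.append((app.candidate, PosTag(wc, Tagset.WORD_CLASS)))
                if trace is None:
                    trace = app
        if candidates:
            uniq = tuple(dict.fromkeys(candidates))
            return LemmaResult(
                input=tok, lemmas=uniq, provenance=Provenance.RULE, rule_trace=trace
            )
        return LemmaResult(
            input=tok, lemmas=((text, None),), provenance=Provenance.SURFACE
        )

    # -- compounds --------------------------------------------------

    @staticmethod
    def _is_compound(text: str) -> bool:
        parts = _COMPOUND_SEP.split(text)
        return len(parts) > 1 and all(p for p in parts)

    def _lemmatize_compound(self, tok: TokenInput, pos: PosTag | None) -> LemmaResult:
        """Lemmatize each part with the token's POS context and rejoin
        with the original separators."""
        pieces = _COMPOUND_SEP.split(tok.text)
        out: list[str] = []
        best: Provenance = Provenance.SURFACE
        trace: RuleApplication | None = None
        for i, piece in enumerate(pieces):
            if i % 2 == 1:  # separator
                out.append(piece)
                continue
            sub = TokenInput(text=piece, pos=tok.pos, tagset=tok.tagset)
            res = self._lemmatize_part(sub)
            out.append(res.lemma)
            if res.provenance is Provenance.RULE and trace is None:
                trace = res.rule_trace
            if best is Provenance.SURFACE and res.provenance is not Provenance.SURFACE:
                best = res.provenance
        if trace is not None:
            best = Provenance.RULE
        return LemmaResult(
            input=tok, lemmas=(("".join(out), pos),), provenance=best, rule_trace=trace
        )

    def _lemmatize_part(self, tok: TokenInput) -> LemmaResult:
        saved = self.config.split_compounds
        self.config.split_compounds = False
        try:
            return self._lemmatize_token(tok)
        finally:
            self.config.split_compounds = saved

    # -- no-POS display ---------------------------------------------

    def _display_candidates(
        self, candidates: Sequence[tuple[str, PosTag]]
    ) -> list[tuple[str, PosTag]]:
        """Merge no-POS candidates across tagsets, de-duplicating on
        (lemma, Penn-mapped label) while keeping the raw tag."""
        seen: set[tuple[str, str]] = set()
        out: list[tuple[str, PosTag]] = []
        for lemma, p in candidates:
            if p.tagset is Tagset.NUPOS:
                penns = sorted(t.label for t in self.hierarchy.map_tag(p, Tagset.PENN))
                display = penns[0] if penns else p.label
            else:
                display = p.label
            key = (lemma.casefold(), display)
            if key in seen:
                continue
            seen.add(key)
            out.append((lemma, p))
        return out


def lemmatize(
    tok: TokenInput,
    lexicon: Lexicon,
    ruleset: RuleSet,
    hierarchy: PosHierarchy,
    config: LemmatizerConfig | None = None,
) -> LemmaResult:
    """Functional entry point over a one-shot :class:`Lemmatizer`."""
    return Lemmatizer(hierarchy, lexicon, ruleset, config)._lemmatize_token(tok)
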