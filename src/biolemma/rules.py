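"""Ordered suffix-detachment rules with lexicon validation.

Rules are grouped by major word class and tried in priority order.
Each rule is a literal suffix swap (``suffix → replacement``).  A rule
may carry the lexicon-validation constraint: its candidate lemma must
be a known form (surface or lemma side of the lexicon), otherwise the
candidate is rejected and the next matching rule is attempted — this
is what turns *appendixes* into *appendix* (the validated xes→xis rule
rejects "appendixis") instead of stopping at the first match.  If no
rule accepts, the surface form is the lemma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .hierarchy import (
    BYPASS_CLASSES,
    WORD_CLASSES,
    PosHierarchy,
    PosTag,
    Tagset,
)
from .lexicon import Lexicon


class RuleError(ValueError):
    """Malformed rule file."""


@dataclass(frozen=True, order=True)
class DetachmentRule:
    word_class: str
    suffix: str
    replacement: str
    validate: bool
    priority: int

    def __post_init__(self) -> None:
        if not self.suffix:
            raise ValueError("suffix pattern must be non-empty")
        if self.word_class not in WORD_CLASSES:
            raise ValueError(f"unknown word class {self.word_class!r}")

    def matches(self, word: str) -> bool:
        # proper suffix: never consume the whole word
        return len(word) > len(self.suffix) and word.casefold().endswith(self.suffix)

    def apply(self, word: str) -> str:
        return word[: len(word) - len(self.suffix)] + self.replacement


@dataclass
class RuleSet:
    """Per-word-class ordered rule lists."""

    by_class: dict[str, tuple[DetachmentRule, ...]]

    def __post_init__(self) -> None:
        ordered: dict[str, tuple[DetachmentRule, ...]] = {}
        for wc, rules in self.by_class.items():
            prios = [r.priority for r in rules]
            if len(prios) != len(set(prios)):
                raise RuleError(f"duplicate rule priority in class {wc!r}")
            ordered[wc] = tuple(sorted(rules, key=lambda r: r.priority))
        self.by_class = ordered

    def rules_for(self, word_class: str) -> tuple[DetachmentRule, ...]:
        return self.by_class.get(word_class, ())

    @property
    def counts(self) -> dict[str, tuple[int, int]]:
        """Per-class (total, lexicon-validated) rule counts."""
        return {
            wc: (len(rules), sum(1 for r in rules if r.validate))
            for wc, rules in self.by_class.items()
        }

    def __iter__(self):
        for wc in sorted(self.by_class):
            yield from self.by_class[wc]


@dataclass(frozen=True)
class RuleApplication:
    """Trace of one rule-engine run over a word."""

    input: str
    word_class: str
    matched_rule: DetachmentRule | None
    candidate: str
    accepted: bool
    rejections: tuple[tuple[DetachmentRule, str], ...] = field(default=())


def apply_rules(
    word: str,
    word_class: PosTag | str,
    ruleset: RuleSet,
    lexicon: Lexicon,
    *,
    enforce_validation: bool = True,
) -> RuleApplication:
    """Run the word-class rule chain over *word*.

    Total: if no rule accepts, the surface form is the candidate.
    ``enforce_validation=False`` makes validated rules accept without
    the lexicon check (the pre-fix behavior whose error modes — e.g.
    *immunolabeled* → *immunolabele* under a bare d-strip rule — are
    kept reproducible for regression tests).
    """
    wc = word_class.label if isinstance(word_class, PosTag) else word_class
    if wc not in WORD_CLASSES:
        raise ValueError(f"unknown word class {wc!r}")
    rejections: list[tuple[DetachmentRule, str]] = []
    for rule in ruleset.rules_for(wc):
        if not rule.matches(word):
            continue
        candidate = rule.apply(word)
        if rule.validate and enforce_validation and not lexicon.contains_form(candidate):
            rejections.append((rule, candidate))
            continue
        return RuleApplication(
            input=word,
            word_class=wc,
            matched_rule=rule,
            candidate=candidate,
            accepted=True,
            rejections=tuple(rejections),
        )
    return RuleApplication(
        input=word,
        word_class=wc,
        matched_rule=None,
        candidate=word,
        accepted=False,
        rejections=tuple(rejections),
    )


#: Singular-noun tags: after a lexicon miss these are left untouched
#: (the token is presumed already to be a lemma).
_SINGULAR_NOUN_PENN = frozenset({"NN", "NNP"})


def bypass_check(word: str, pos: PosTag, hierarchy: PosHierarchy) -> bool:
    """True iff the token's POS mandates returning the surface form
    unchanged once lexicon search has failed: punctuation, symbol and
    foreign word classes, and singular-noun tags (NN/NNP or NUPOS tags
    mapping only onto them)."""
    wc = hierarchy.word_class_of(pos).label
    if wc in BYPASS_CLASSES:
        return True
    if wc == "noun":
        if pos.tagset is Tagset.PENN:
            return pos.label in _SINGULAR_NOUN_PENN
        if pos.tagset is Tagset.NUPOS:
            penns = {t.label for t in hierarchy.map_tag(pos, Tagset.PENN)}
            return penns <= _SINGULAR_NOUN_PENN
    return False


def parse_rules(lines: Iterable[str]) -> RuleSet:
    """Parse ``word_class<TAB>suffix<TAB>replacement<TAB>validate<TAB>priority``
    records; empty replacement is encoded as ``-``."""
    by_class: dict[str, list[DetachmentRule]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise RuleError(f"line {lineno}: expected 5 tab-separated fields")
        wc, suffix, replacement, validate, priority = fields
        if wc not in WORD_CLASSES:
            raise RuleError(f"line {lineno}: unknown word class {wc!r}")
        if not suffix:
            raise RuleError(f"line {lineno}: empty suffix pattern")
        if validate not in {"0", "1"}:
            raise RuleError(f"line {lineno}: validate flag must be 0 or 1")
        try:
            prio = int(priority)
        except ValueError:
            raise RuleError(f"line {lineno}: priority must be an integer") from None
        rule = DetachmentRule(
            word_class=wc,
            suffix=suffix,
            replacement="" if replacement == "-" else replacement,
            validate=validate == "1",
            priority=prio,
        )
        if any(r.priority == prio for r in by_class.get(wc, [])):
            raise RuleError(f"line {lineno}: duplicate priority {prio} in class {wc!r}")
        by_class.setdefault(wc, []).append(rule)
    return RuleSet(by_class={wc: tuple(rs) for wc, rs in by_class.items()})


def load_rules(path: str | Path) -> RuleSet:
    with open(path, encoding="utf-8") as fh:
        return parse_rules(fh)


def save_rules(ruleset: RuleSet, path: str | Path) -> Path:
    """Write records in class/priority order; load→save→load is identity."""
    path = Path(path)
    lines = []
    for wc in sorted(ruleset.by_class):
        for r in ruleset.by_class[wc]:
            repl = r.replacement if r.replacement else "-"
            lines.append(f"{wc}\t{r.suffix}\t{repl}\t{int(r.validate)}\t{r.priority}")
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    return path
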