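"""Three-layer part-of-speech hierarchy.

The lemmatizer relates three tagsets: the fine-grained NUPOS tagset
(241 tags in the full inventory), the Penn Treebank tagset (36 primary
tags) and a small set of major word classes that group detachment
rules.  Each NUPOS tag maps to one or more Penn tags (many-to-many
across the layer); each Penn tag maps to exactly one word class.
"Sibling" tags form inflection families (NN/NNS, VBD/VBN, ...) used to
relax lexicon search when the input POS tag is wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator


class Tagset(str, Enum):
    NUPOS = "NUPOS"
    PENN = "PENN"
    WORD_CLASS = "WORD_CLASS"


#: Closed inventory of major word classes; rule files may only
#: reference these.
WORD_CLASSES = frozenset(
    {
        "noun",
        "verb",
        "adjective",
        "adverb",
        "pronoun",
        "preposition",
        "conjunction",
        "determiner",
        "number",
        "punctuation",
        "symbol",
        "foreign",
        "other",
    }
)

#: Word classes whose tokens are never inflected: the surface form is
#: the lemma.
BYPASS_CLASSES = frozenset({"punctuation", "symbol", "foreign"})


class HierarchyError(ValueError):
    """Malformed or inconsistent hierarchy mapping file."""


class UnknownTagError(KeyError):
    """Tag not present in the loaded hierarchy (distinct from an empty
    mapping)."""


@dataclass(frozen=True, order=True)
class PosTag:
    label: str
    tagset: Tagset

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("POS tag label must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.label}[{self.tagset.value}]"


@dataclass
class PosHierarchy:
    """Validated three-layer tag structure with sibling families."""

    nupos_to_penn: dict[str, frozenset[str]]
    penn_to_class: dict[str, str]
    sibling_sets: dict[tuple[Tagset, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.penn_to_nupos: dict[str, frozenset[str]] = {}
        inverse: dict[str, set[str]] = {p: set() for p in self.penn_to_class}
        for n, penns in self.nupos_to_penn.items():
            if not penns:
                raise HierarchyError(f"NUPOS tag {n!r} maps to no Penn tag")
            for p in penns:
                if p not in self.penn_to_class:
                    raise HierarchyError(
                        f"NUPOS tag {n!r} maps to Penn tag {p!r} absent from the P2C layer"
                    )
                inverse[p].add(n)
            classes = {self.penn_to_class[p] for p in penns}
            if len(classes) > 1:
                raise HierarchyError(
                    f"NUPOS tag {n!r} maps to Penn tags with conflicting word "
                    f"classes {sorted(classes)}"
                )
        self.penn_to_nupos = {p: frozenset(s) for p, s in inverse.items()}
        for (tagset, label), sibs in self.sibling_sets.items():
            if label in sibs:
                raise HierarchyError(f"sibling relation is irreflexive: {label}")
            for s in sibs:
                other = self.sibling_sets.get((tagset, s), frozenset())
                if label not in other:
                    raise HierarchyError(f"sibling relation not symmetric: {label}/{s}")

    # -- membership -------------------------------------------------

    def has_tag(self, tag: PosTag) -> bool:
        if tag.tagset is Tagset.NUPOS:
            return tag.label in self.nupos_to_penn
        if tag.tagset is Tagset.PENN:
            return tag.label in self.penn_to_class
        return tag.label in WORD_CLASSES

    def _require(self, tag: PosTag) -> None:
        if not self.has_tag(tag):
            raise UnknownTagError(f"unknown tag {tag.label!r} in tagset {tag.tagset.value}")

    def tag(self, label: str, tagset: Tagset | str) -> PosTag:
        """Build a validated :class:`PosTag` belonging to this hierarchy."""
        t = PosTag(label, Tagset(tagset))
        self._require(t)
        return t

    def resolve(self, label: str) -> PosTag:
        """Resolve a bare label, trying Penn first, then NUPOS."""
        if label in self.penn_to_class:
            return PosTag(label, Tagset.PENN)
        if label in self.nupos_to_penn:
            return PosTag(label, Tagset.NUPOS)
        raise UnknownTagError(f"unknown tag {label!r}")

    # -- queries ----------------------------------------------------

    def map_tag(self, tag: PosTag, target: Tagset | str) -> frozenset[PosTag]:
        """Image of *tag* in *target* tagset.

        NUPOS→WORD_CLASS composes through the Penn layer; mapping a tag
        into its own tagset is the identity.
        """
        target = Tagset(target)
        self._require(tag)
        if tag.tagset is target:
            return frozenset({tag})
        if tag.tagset is Tagset.NUPOS:
            penns = frozenset(PosTag(p, Tagset.PENN) for p in self.nupos_to_penn[tag.label])
            if target is Tagset.PENN:
                return penns
            return frozenset(
                PosTag(self.penn_to_class[p.label], Tagset.WORD_CLASS) for p in penns
            )
        if tag.tagset is Tagset.PENN:
            if target is Tagset.NUPOS:
                return frozenset(
                    PosTag(n, Tagset.NUPOS) for n in self.penn_to_nupos[tag.label]
                )
            return frozenset({PosTag(self.penn_to_class[tag.label], Tagset.WORD_CLASS)})
        # WORD_CLASS source
        penns = frozenset(
            PosTag(p, Tagset.PENN)
            for p, c in self.penn_to_class.items()
            if c == tag.label
        )
        if target is Tagset.PENN:
            return penns
        nupos: set[PosTag] = set()
        for p in penns:
            nupos.update(PosTag(n, Tagset.NUPOS) for n in self.penn_to_nupos[p.label])
        return frozenset(nupos)

    def word_class_of(self, tag: PosTag) -> PosTag:
        """The single major word class of *tag*."""
        self._require(tag)
        if tag.tagset is Tagset.WORD_CLASS:
            return tag
        classes = self.map_tag(tag, Tagset.WORD_CLASS)
        # load-time validation guarantees a single class
        return next(iter(classes))

    def siblings_of(self, tag: PosTag) -> tuple[PosTag, ...]:
        """Inflection-family siblings of *tag*, excluding *tag* itself,
        in deterministic (lexicographic) order."""
        self._require(tag)
        sibs = self.sibling_sets.get((tag.tagset, tag.label), frozenset())
        return tuple(PosTag(s, tag.tagset) for s in sorted(sibs))


def _records(lines: Iterable[str]) -> Iterator[tuple[int, list[str]]]:
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield i, line.split("\t")


def parse_hierarchy(lines: Iterable[str]) -> PosHierarchy:
    """Parse mapping records ``LAYER<TAB>from<TAB>to`` with LAYER in
    {N2P, P2C, SIB}; duplicate records collapse."""
    n2p: dict[str, set[str]] = {}
    p2c: dict[str, str] = {}
    sib_pairs: list[tuple[int, str, str]] = []
    seen_any = False
    for lineno, fields in _records(lines):
        seen_any = True
        if len(fields) != 3 or not all(f.strip() for f in fields):
            raise HierarchyError(f"line {lineno}: expected LAYER<TAB>from<TAB>to")
        layer, src, dst = (f.strip() for f in fields)
        if layer == "N2P":
            n2p.setdefault(src, set()).add(dst)
        elif layer == "P2C":
            if dst not in WORD_CLASSES:
                raise HierarchyError(f"line {lineno}: unknown word class {dst!r}")
            if src in p2c and p2c[src] != dst:
                raise HierarchyError(
                    f"line {lineno}: Penn tag {src!r} assigned two word classes "
                    f"({p2c[src]!r} and {dst!r})"
                )
            p2c[src] = dst
        elif layer == "SIB":
            sib_pairs.append((lineno, src, dst))
        else:
            raise HierarchyError(f"line {lineno}: unknown layer {layer!r}")
    if not seen_any or not p2c:
        raise HierarchyError("empty hierarchy mapping")

    sibling_sets: dict[tuple[Tagset, str], set[str]] = {}
    for lineno, a, b in sib_pairs:
        if a == b:
            raise HierarchyError(f"line {lineno}: tag {a!r} declared its own sibling")
        if a in p2c and b in p2c:
            tagset = Tagset.PENN
            same_class = p2c[a] == p2c[b]
        elif a in n2p and b in n2p:
            tagset = Tagset.NUPOS
            classes_a = {p2c[p] for p in n2p[a] if p in p2c}
            classes_b = {p2c[p] for p in n2p[b] if p in p2c}
            same_class = bool(classes_a) and classes_a == classes_b
        else:
            raise HierarchyError(
                f"line {lineno}: sibling tags {a!r}/{b!r} not both in one tagset"
            )
        if not same_class:
            raise HierarchyError(
                f"line {lineno}: siblings {a!r}/{b!r} differ in word class"
            )
        sibling_sets.setdefault((tagset, a), set()).add(b)
        sibling_sets.setdefault((tagset, b), set()).add(a)

    return PosHierarchy(
        nupos_to_penn={n: frozenset(s) for n, s in n2p.items()},
        penn_to_class=dict(p2c),
        sibling_sets={k: frozenset(v) for k, v in sibling_sets.items()},
    )


def load_hierarchy(mapping_file: str | Path) -> PosHierarchy:
    """Load and validate a hierarchy mapping file (UTF-8 TSV)."""
    with open(mapping_file, encoding="utf-8") as fh:
        return parse_hierarchy(fh)
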