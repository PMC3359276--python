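"""Unicode normalization of lookup keys.

Biomedical text (and the OED in particular) records some terms with
diacritics or ligatures — *tænia*, *zoölogy* — while lexical resources
store the plain-letter form.  Before lexicon lookup, tokens are
normalized by stripping combining diacritical marks (canonical
decomposition, then removal of the Mn category) and expanding a
declared ligature table (æ→ae, œ→oe, ...).  Normalization affects the
lookup key only; the original surface form is preserved in output
records.  Case is preserved.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from pathlib import Path

#: Default ligature expansions.  Mark-stripping runs first, so a
#: decomposed ligature (e.g. ǣ → æ + macron) still ends up expanded.
DEFAULT_LIGATURES: dict[str, str] = {
    "æ": "ae",  # æ
    "Æ": "Ae",  # Æ
    "œ": "oe",  # œ
    "Œ": "Oe",  # Œ
    "ﬀ": "ff",
    "ﬁ": "fi",
    "ﬂ": "fl",
    "ﬃ": "ffi",
    "ﬄ": "ffl",
    "ĳ": "ij",
    "Ĳ": "IJ",
}


@dataclass(frozen=True)
class NormalizationResult:
    original: str
    normalized: str

    @property
    def changed(self) -> bool:
        return self.original != self.normalized


def load_ligature_table(path: str | Path) -> dict[str, str]:
    """Read a ``ligature<TAB>expansion`` TSV overriding the built-in table."""
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: line {lineno}: expected ligature<TAB>expansion")
            table[fields[0]] = fields[1]
    return table


def normalize_unicode(
    text: str, ligatures: dict[str, str] | None = None
) -> NormalizationResult:
    """Strip combining diacritics and expand ligatures.

    Idempotent and total; pure-ASCII input is returned unchanged.
    """
    table = DEFAULT_LIGATURES if ligatures is None else ligatures
    decomposed = unicodedata.normalize("NFD", text)
    stripped = "".join(c for c in decomposed if unicodedata.category(c) != "Mn")
    expanded = "".join(table.get(c, c) for c in stripped)
    return NormalizationResult(original=text, normalized=expanded)
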