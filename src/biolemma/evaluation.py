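"""Scoring, consensus (silver-standard) construction and POS-error QA.

Lemmatization tools differ in output arity: some always emit exactly
one lemma, some emit several for an ambiguous form, and some emit none
for certain inputs.  Scoring therefore uses precision/recall/F rather
than plain accuracy: an input counts as correct when *any* predicted
lemma is in its (variant-expanded) gold set; recall divides correct
inputs by the number of gold inputs, precision by the total number of
emitted lemmas.  For a tool that always emits exactly one lemma the two
coincide.

A "silver standard" is the subset of inputs on which every compared
system produces the identical (case-folded) lemma set; disagreements
are left for manual adjudication.

POS-error QA flags noun tokens whose lemmatizer output is suspicious
given the tag: a token identical to its lemma but tagged plural
(criterion 1), or differing from its lemma but tagged singular
(criterion 2).  Flags are candidates only — nouns like *series* and
*species* have identical singular and plural forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .lemmatizer import Lemmatizer


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class EvalRecord:
    token: str
    pos: str | None
    gold: frozenset[str]
    predicted: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gold:
            raise ValueError(f"record {self.token!r}: gold lemma set must be non-empty")

    @property
    def correct(self) -> bool:
        gold = {g.casefold() for g in self.gold}
        return any(p.casefold() in gold for p in self.predicted)


@dataclass(frozen=True)
class ScoreReport:
    n_gold: int
    n_output: int
    n_correct: int

    @property
    def recall(self) -> float:
        return self.n_correct / self.n_gold if self.n_gold else 0.0

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_output if self.n_output else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def formatted(self) -> str:
        return (
            f"Recall    {_pct(self.n_correct, self.n_gold)}\n"
            f"Precision {_pct(self.n_correct, self.n_output)}\n"
            f"F-score   {self.f_score * 100:.2f}%"
        )


def _pct(num: int, den: int) -> str:
    value = num / den * 100 if den else 0.0
    return f"{value:.2f}% ({num}/{den})"


def score(records: Sequence[EvalRecord]) -> ScoreReport:
    """Score multi-output, possibly-missing-output predictions.

    Empty prediction sets contribute 0 to the output count, so a tool
    that skips inputs is penalized in recall but not precision.
    """
    if not records:
        raise EvaluationError("cannot score an empty record list")
    n_gold = len(records)
    n_output = sum(len(r.predicted) for r in records)
    n_correct = sum(1 for r in records if r.correct)
    return ScoreReport(n_gold=n_gold, n_output=n_output, n_correct=n_correct)


# -- spelling-variant expansion -------------------------------------


def load_variant_map(path: str | Path) -> dict[str, str]:
    """Read a ``form<TAB>variant`` TSV (e.g. British/American pairs)."""
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(fields):
                raise EvaluationError(f"line {lineno}: expected form<TAB>variant")
            table[fields[0]] = fields[1]
    return table


def expand_gold(records: Iterable[EvalRecord], variants: Mapping[str, str]) -> list[EvalRecord]:
    """Augment gold sets with declared spelling variants, both
    directions (a gold *harbour* also accepts *harbor* and vice versa)."""
    both: dict[str, set[str]] = {}
    for a, b in variants.items():
        both.setdefault(a.casefold(), set()).add(b)
        both.setdefault(b.casefold(), set()).add(a)
    out = []
    for r in records:
        gold = set(r.gold)
        for g in r.gold:
            gold |= both.get(g.casefold(), set())
        out.append(EvalRecord(r.token, r.pos, frozenset(gold), r.predicted))
    return out


# -- consensus ------------------------------------------------------


@dataclass(frozen=True)
class ConsensusReport:
    consensus_set: tuple[object, ...]
    disagreement_set: tuple[object, ...]

    @property
    def consensus_rate(self) -> float:
        total = len(self.consensus_set) + len(self.disagreement_set)
        return len(self.consensus_set) / total if total else 0.0


def build_consensus(outputs: Mapping[str, Mapping[object, frozenset[str]]]) -> ConsensusReport:
    """Partition shared inputs into full-agreement and disagreement sets.

    *outputs* maps system name → {input key → predicted lemma set};
    all systems must cover the identical key set.
    """
    if len(outputs) < 2:
        raise EvaluationError("consensus needs at least two systems")
    names = sorted(outputs)
    ref_keys = set(outputs[names[0]])
    for name in names[1:]:
        keys = set(outputs[name])
        if keys != ref_keys:
            missing = sorted(map(str, ref_keys - keys))[:5]
            extra = sorted(map(str, keys - ref_keys))[:5]
            raise EvaluationError(
                f"system {name!r} key set differs from {names[0]!r}: "
                f"missing={missing} extra={extra}"
            )
    consensus, disagreement = [], []
    for key in sorted(ref_keys, key=str):
        folded = {
            frozenset(l.casefold() for l in outputs[name][key]) for name in names
        }
        (consensus if len(folded) == 1 else disagreement).append(key)
    return ConsensusReport(
        consensus_set=tuple(consensus), disagreement_set=tuple(disagreement)
    )


# -- POS-error quality assurance ------------------------------------


@dataclass(frozen=True)
class PosErrorFlag:
    token: str
    pos: str
    lemma: str
    criterion: int  # 1: token==lemma but tagged plural; 2: token!=lemma but tagged singular


_PLURAL = frozenset({"NNS", "NNPS"})
_SINGULAR = frozenset({"NN", "NNP"})


def detect_pos_errors(
    tokens: Iterable[tuple[str, str]], lemmatizer: Lemmatizer
) -> list[PosErrorFlag]:
    """Flag potentially mistagged nouns by comparing each token to its
    lemmatizer output.  Non-noun tags are never flagged."""
    flags: list[PosErrorFlag] = []
    for token, pos in tokens:
        if pos not in _PLURAL | _SINGULAR:
            continue
        result = lemmatizer.lemmatize(token, pos)
        lemma = result.lemma
        identical = lemma.casefold() == token.casefold()
        if identical and pos in _PLURAL:
            flags.append(PosErrorFlag(token, pos, lemma, criterion=1))
        elif not identical and pos in _SINGULAR:
            flags.append(PosErrorFlag(token, pos, lemma, criterion=2))
    return flags


# -- eval-file plumbing ---------------------------------------------


def parse_eval_file(lines: Iterable[str], *, with_pred: bool = True) -> list[EvalRecord]:
    """Parse ``token<TAB>pos<TAB>gold[;gold...][<TAB>pred[;pred...]]``."""
    records = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        expected = 4 if with_pred else 3
        if len(fields) < expected - 1 or len(fields) > expected:
            raise EvaluationError(f"line {lineno}: expected {expected} fields")
        token, pos, gold = fields[0], fields[1], fields[2]
        pred = fields[3] if with_pred and len(fields) == 4 else ""
        records.append(
            EvalRecord(
                token=token,
                pos=pos or None,
                gold=frozenset(g for g in gold.split(";") if g),
                predicted=frozenset(p for p in pred.split(";") if p),
            )
        )
    return records


def load_eval_file(path: str | Path, *, with_pred: bool = True) -> list[EvalRecord]:
    with open(path, encoding="utf-8") as fh:
        return parse_eval_file(fh, with_pred=with_pred)
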