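import random

import pytest

from biolemma import evaluation
from biolemma.evaluation import (
    ConsensusReport,
    EvalRecord,
    EvaluationError,
    PosErrorFlag,
    build_consensus,
    detect_pos_errors,
    expand_gold,
    parse_eval_file,
    score,
)


def rec(token, gold, predicted, pos="NN"):
    return EvalRecord(token, pos, frozenset(gold), frozenset(predicted))


def synthetic_records(n_gold, n_correct, n_output=None):
    """n_gold records, n_correct of them correct; every record starts
    with one prediction and the (n_output - n_gold) surplus emitted
    lemmas are spread round-robin as extra wrong predictions (the shape
    of a tool that returns several lemmas for ambiguous inputs)."""
    if n_output is None:
        n_output = n_gold
    records = []
    for i in range(n_correct):
        records.append(rec(f"t{i}", {f"g{i}"}, {f"g{i}"}))
    for i in range(n_gold - n_correct):
        records.append(rec(f"x{i}", {f"gx{i}"}, {f"wx{i}"}))
    extras = n_output - n_gold
    out = []
    for j, r in enumerate(records):
        k = extras // n_gold + (1 if j < extras % n_gold else 0)
        preds = set(r.predicted) | {f"extra{j}_{m}" for m in range(k)}
        out.append(EvalRecord(r.token, r.pos, r.gold, frozenset(preds)))
    return out


def test_multi_output_tool_scoring():
    """A tool emitting 614 lemmas over 579 inputs with 430 correct:
    R=74.27%, P=70.03%, F=72.09%."""
    records = synthetic_records(n_gold=579, n_correct=430, n_output=614)
    report = score(records)
    assert (report.n_gold, report.n_output, report.n_correct) == (579, 614, 430)
    assert round(report.recall * 100, 2) == 74.27
    assert round(report.precision * 100, 2) == 70.03
    assert round(report.f_score * 100, 2) == 72.09


def test_high_recall_low_precision_tool():
    """482 correct over 579 inputs but 812 emitted lemmas: P=59.36%."""
    records = synthetic_records(n_gold=579, n_correct=482, n_output=812)
    report = score(records)
    assert report.n_output == 812
    assert round(report.precision * 100, 2) == 59.36
    assert round(report.f_score * 100, 2) == 69.30


def test_single_prediction_implies_precision_equals_recall():
    records = synthetic_records(n_gold=50, n_correct=37)
    report = score(records)
    assert report.precision == report.recall


def test_all_correct_single_predictions():
    report = score(synthetic_records(10, 10))
    assert report.precision == report.recall == report.f_score == 1.0


def test_empty_predictions_count_zero_output():
    records = [rec("a", {"a"}, {"a"}), rec("b", {"b"}, set())]
    report = score(records)
    assert report.n_output == 1
    assert report.recall == 0.5
    assert report.precision == 1.0


def test_empty_record_list_is_an_error():
    with pytest.raises(EvaluationError):
        score([])


def test_score_is_permutation_invariant():
    records = synthetic_records(40, 25, 47)
    shuffled = records[:]
    random.Random(3).shuffle(shuffled)
    assert score(records) == score(shuffled)


def test_removing_wrong_prediction_never_lowers_precision():
    records = [rec("a", {"a"}, {"a", "zzz"}), rec("b", {"b"}, {"b"})]
    before = score(records)
    after = score([rec("a", {"a"}, {"a"}), rec("b", {"b"}, {"b"})])
    assert after.precision >= before.precision
    assert after.recall == before.recall


def test_formatted_report_matches_published_layout():
    report = score(synthetic_records(579, 430, 614))
    text = report.formatted()
    assert "74.27% (430/579)" in text
    assert "70.03% (430/614)" in text


def test_variant_expansion_accepts_both_spellings():
    records = [rec("harbours", {"harbour"}, {"harbor"})]
    assert not records[0].correct
    expanded = expand_gold(records, {"harbour": "harbor"})
    assert expanded[0].correct
    # and the reverse direction
    records2 = [rec("harbors", {"harbor"}, {"harbour"})]
    assert expand_gold(records2, {"harbour": "harbor"})[0].correct


# -- consensus ------------------------------------------------------


def _system(keys, lemma_fn):
    return {k: frozenset({lemma_fn(k)}) for k in keys}


def test_consensus_partition_and_rate():
    """Nine systems agreeing on 4559 of 6441 shared keys: 70.78%."""
    keys = [f"k{i}" for i in range(6441)]
    outputs = {}
    for s in range(9):
        out = {}
        for i, k in enumerate(keys):
            if i < 4559 or s == 0:
                out[k] = frozenset({"agree"})
            else:
                out[k] = frozenset({f"sys{s}"})
            # one deviating system is enough for disagreement
        outputs[f"tool{s}"] = out
    report = build_consensus(outputs)
    assert len(report.consensus_set) == 4559
    assert len(report.disagreement_set) == 1882
    assert round(report.consensus_rate * 100, 2) == 70.78


def test_identical_systems_full_consensus():
    keys = ["a", "b", "c"]
    outputs = {"s1": _system(keys, str.upper), "s2": _system(keys, str.upper)}
    report = build_consensus(outputs)
    assert report.consensus_rate == 1.0
    assert report.disagreement_set == ()


def test_single_key_disagreement():
    keys = ["a", "b", "c"]
    s1 = _system(keys, lambda k: k)
    s2 = dict(s1)
    s2["b"] = frozenset({"different"})
    report = build_consensus({"s1": s1, "s2": s2})
    assert report.disagreement_set == ("b",)


def test_consensus_is_case_insensitive():
    outputs = {"s1": {"k": frozenset({"Cell"})}, "s2": {"k": frozenset({"cell"})}}
    assert build_consensus(outputs).consensus_rate == 1.0


def test_duplicate_system_does_not_change_rate():
    keys = [f"k{i}" for i in range(10)]
    s1 = _system(keys, lambda k: k)
    s2 = {k: frozenset({"x" if k == "k3" else k}) for k in keys}
    base = build_consensus({"a": s1, "b": s2})
    dup = build_consensus({"a": s1, "b": s2, "b2": dict(s2)})
    assert base.consensus_rate == dup.consensus_rate


def test_mismatched_key_sets_error_lists_difference():
    outputs = {"s1": {"a": frozenset({"x"})}, "s2": {"b": frozenset({"x"})}}
    with pytest.raises(EvaluationError, match="key set differs"):
        build_consensus(outputs)


def test_fewer_than_two_systems_is_an_error():
    with pytest.raises(EvaluationError):
        build_consensus({"s1": {}})


# -- POS-error QA ---------------------------------------------------


def test_detect_pos_errors_criteria(lemmatizer):
    flags = detect_pos_errors(
        [
            ("retinas", "NN"),   # plural form tagged singular -> criterion 2
            ("retina", "NNS"),   # singular form tagged plural -> criterion 1
            ("species", "NNS"),  # identical sg/pl: flagged though possibly fine
            ("cell", "NN"),      # consistent: not flagged
            ("ran", "VBD"),      # non-noun tags never flagged
        ],
        lemmatizer,
    )
    by_token = {f.token: f for f in flags}
    assert by_token["retinas"].criterion == 2
    assert by_token["retinas"].lemma == "retina"
    assert by_token["retina"].criterion == 1
    assert by_token["species"].criterion == 1
    assert "cell" not in by_token
    assert "ran" not in by_token


def test_eval_file_parsing_multi_lemma_fields():
    records = parse_eval_file(["axes\tNNS\taxe;axis\taxis"], with_pred=True)
    assert records[0].gold == frozenset({"axe", "axis"})
    assert records[0].predicted == frozenset({"axis"})
    assert records[0].correct
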