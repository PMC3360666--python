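"""Confusion counting, Se/Sp/Pr arithmetic, and benchmark-table aggregation."""

import numpy as np
import pytest

from epimapper.candidate_assembly import PredictionSet
from epimapper.evaluation import (
    ConfusionCounts,
    EvaluationError,
    Metrics,
    aggregate,
    confusion,
    load_benchmark,
    metrics,
    write_metrics_table,
)


def _ps(nums):
    return PredictionSet(frozenset(("A", n, "") for n in nums))


UNIVERSE = {("A", n, "") for n in range(1, 51)}


def test_perfect_prediction_counts():
    truth = _ps(range(1, 11))
    c = confusion(truth, truth, UNIVERSE)
    assert (c.tp, c.fp, c.fn, c.tn) == (10, 0, 0, 40)
    m = metrics(c)
    assert (m.se, m.sp, m.pr) == (1.0, 1.0, 1.0)


def test_empty_prediction_has_zero_pe_and_precision():
    c = confusion(_ps([]), _ps(range(1, 11)), UNIVERSE)
    assert c.tp == 0 and c.pe == 0
    assert metrics(c).pr == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_confusion_matches_naive_set_oracle(seed):
    rng = np.random.default_rng(seed)
    pred = set(map(int, rng.choice(50, size=12, replace=False) + 1))
    pos = set(map(int, rng.choice(50, size=9, replace=False) + 1))
    c = confusion(_ps(pred), _ps(pos), UNIVERSE)
    assert c.tp == len(pred & pos)
    assert c.fp == len(pred - pos)
    assert c.fn == len(pos - pred)
    assert c.tn == 50 - len(pred | pos)
    assert c.pe == len(pred)


def test_truth_outside_universe_names_offenders():
    with pytest.raises(EvaluationError, match="A:99"):
        confusion(_ps([1]), _ps([1, 99]), UNIVERSE)


def test_empty_truth_sensitivity_undefined():
    with pytest.raises(EvaluationError):
        metrics(ConfusionCounts(tp=0, fp=3, tn=40, fn=0))


def test_precision_20_of_31():
    m = metrics(ConfusionCounts(tp=20, fp=11, tn=40, fn=1))
    assert round(m.pr, 3) == 0.645


def test_precision_9_of_10():
    m = metrics(ConfusionCounts(tp=9, fp=1, tn=68, fn=12))
    assert m.pr == pytest.approx(0.900)


def test_no_false_positives_means_full_specificity():
    m = metrics(ConfusionCounts(tp=4, fp=0, tn=30, fn=2))
    assert m.sp == 1.0


def test_adding_a_correct_prediction_never_hurts():
    base = ConfusionCounts(tp=5, fp=3, tn=30, fn=4)
    more = ConfusionCounts(tp=6, fp=3, tn=30, fn=3)
    assert metrics(more).se > metrics(base).se
    assert metrics(more).pr > metrics(base).pr
    worse = ConfusionCounts(tp=5, fp=4, tn=29, fn=4)
    assert metrics(worse).sp < metrics(base).sp


def test_aggregate_of_identical_rows_is_that_row():
    row = Metrics(0.5, 0.8, 0.25)
    mean = aggregate([row, row, row])
    assert (mean.se, mean.sp, mean.pr) == (
        pytest.approx(row.se), pytest.approx(row.sp), pytest.approx(row.pr),
    )
    with pytest.raises(EvaluationError):
        aggregate([])


def test_benchmark_row_precision_arithmetic():
    eng = load_benchmark("engines")
    assert len(eng) == 27
    for _, r in eng.iterrows():
        for side in ("mimopro", "pep3d"):
            m = metrics(
                ConfusionCounts(
                    tp=int(r[f"{side}_tp"]),
                    fp=int(r[f"{side}_pe"] - r[f"{side}_tp"]),
                    tn=50,
                    fn=1,
                )
            )
            assert m.pr == pytest.approx(r[f"{side}_pr"], abs=5e-4 + 1e-9)


def test_benchmark_footer_means():
    eng = load_benchmark("engines")
    ens = load_benchmark("ensemble")
    expectations = [
        ("mimopro", eng, (0.460, 0.835, 0.271)),
        ("pep3d", eng, (0.357, 0.847, 0.230)),
        ("inter", ens, (0.286, 0.930, 0.256)),
        ("union", ens, (0.513, 0.745, 0.221)),
    ]
    for side, table, (se, sp, pr) in expectations:
        rows = [
            Metrics(r[f"{side}_se"], r[f"{side}_sp"], r[f"{side}_pr"])
            for _, r in table.iterrows()
        ]
        mean = aggregate(rows).rounded(3)
        assert (mean.se, mean.sp, mean.pr) == (se, sp, pr)


def test_metrics_table_writer_layout(tmp_path):
    path = tmp_path / "table.tsv"
    c = ConfusionCounts(tp=9, fp=1, tn=68, fn=12)
    write_metrics_table([("CASE_X", c, metrics(c))], path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t") == ["case", "TP/PE", "Se", "Sp", "Pr"]
    assert lines[1].split("\t") == ["CASE_X", "9/10", "0.429", "0.986", "0.900"]
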