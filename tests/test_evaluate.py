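"""Confusion-matrix metrics, selection funnel, binary collapse, goodness index."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from racewalk.errors import InputError
from racewalk.evaluate import (
    CHANCE_G,
    aggregate,
    collapse_binary,
    compute_metrics,
    confusion_matrix,
    goodness_from_rates,
    goodness_index,
    selection_funnel,
)
from racewalk.synthdata import CONDITIONS


def counting_oracle(cm):
    """Brute-force per-class one-vs-rest metrics from raw counts."""
    cm = np.asarray(cm, dtype=float)
    k = cm.shape[0]
    total = cm.sum()
    out = {"A": sum(cm[i, i] for i in range(k)) / total, "R": [], "P": [], "F1": []}
    for i in range(k):
        tp = cm[i, i]
        fn = sum(cm[i, j] for j in range(k) if j != i)
        fp = sum(cm[j, i] for j in range(k) if j != i)
        r = tp / (tp + fn) if tp + fn else 0.0
        p = tp / (tp + fp) if tp + fp else 0.0
        out["R"].append(r)
        out["P"].append(p)
        out["F1"].append(2 * r * p / (r + p) if r + p else 0.0)
    return out


def test_confusion_matrix_counts():
    cm = confusion_matrix(["regular", "LC", "KB"], ["regular", "KB", "KB"])
    assert cm[0, 0] == 1 and cm[1, 2] == 1 and cm[2, 2] == 1
    assert cm.sum() == 3
    perfect = confusion_matrix(["regular"] * 4 + ["LC"] * 2, ["regular"] * 4 + ["LC"] * 2)
    assert np.count_nonzero(perfect - np.diag(np.diag(perfect))) == 0
    with pytest.raises(InputError):
        confusion_matrix(["regular"], ["regular", "LC"])


def test_compute_metrics_hand_example():
    cm = np.array([[8, 1, 1], [2, 8, 0], [0, 2, 8]])
    report = compute_metrics(cm)
    assert report.accuracy == pytest.approx(24 / 30)
    assert np.allclose(report.recall, [0.8, 0.8, 0.8])
    assert np.allclose(report.precision, [0.8, 8 / 11, 8 / 9])
    expected_f1 = [
        2 * 0.8 * p / (0.8 + p) for p in (0.8, 8 / 11, 8 / 9)
    ]
    assert np.allclose(report.f1, expected_f1)
    assert report.precision_overall == pytest.approx(np.mean([0.8, 8 / 11, 8 / 9]))


def test_perfect_matrix():
    report = compute_metrics(np.diag([10, 10, 10]))
    assert report.accuracy == 1.0
    assert np.allclose(report.recall, 1.0)
    assert np.allclose(report.precision, 1.0)
    assert np.allclose(report.f1, 1.0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_metrics_match_counting_oracle(seed):
    cm = np.random.default_rng(seed).integers(0, 40, size=(3, 3))
    if cm.sum() == 0 or np.any(cm.sum(axis=1) == 0):
        cm = cm + 1
    report = compute_metrics(cm)
    oracle = counting_oracle(cm)
    assert report.accuracy == pytest.approx(oracle["A"], abs=1e-12)
    assert np.allclose(report.recall, oracle["R"], atol=1e-12)
    assert np.allclose(report.precision, oracle["P"], atol=1e-12)
    assert np.allclose(report.f1, oracle["F1"], atol=1e-12)


def test_balanced_classes_mean_recall_equals_accuracy():
    rng = np.random.default_rng(4)
    for _ in range(20):
        cm = rng.integers(0, 30, size=(3, 3))
        cm = cm + np.diag(60 - cm.sum(axis=1))  # equal row sums
        report = compute_metrics(cm)
        assert np.mean(report.recall) == pytest.approx(report.accuracy, abs=1e-12)


def test_undefined_precision_warns_and_is_zero():
    cm = np.array([[5, 0, 5], [0, 0, 10], [0, 0, 10]])
    with pytest.warns(UserWarning, match="never predicted"):
        report = compute_metrics(cm)
    assert report.precision[1] == 0.0


class _Rec:
    def __init__(self, athlete_id, name, cm):
        self.athlete_id = athlete_id
        self.classifier, self.segment, self.combo = name[:-3], name[-2:], name[-3]
        self.name = name
        self.cm = np.asarray(cm, dtype=float)


def test_aggregate_mean_and_sd():
    cm_a = np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8]])  # accuracy 24/30 = 0.8
    cm_b = np.array([[9, 1, 0], [0, 9, 1], [1, 0, 9]])  # accuracy 27/30 = 0.9
    records = [_Rec("ath00", "SVMqaSH", cm_a), _Rec("ath01", "SVMqaSH", cm_b)]
    table = aggregate(records)
    assert table.loc["SVMqaSH", "A"] == pytest.approx(0.85)
    assert table.loc["SVMqaSH", "A_sd"] == pytest.approx(
        np.std([0.8, 0.9], ddof=1)
    )
    identical = [_Rec("ath00", "DTfaSH", cm_a), _Rec("ath01", "DTfaSH", cm_a)]
    assert aggregate(identical).loc["DTfaSH", "A_sd"] == pytest.approx(0.0)


def test_aggregate_single_athlete_warns():
    with pytest.warns(UserWarning, match="single athlete"):
        table = aggregate([_Rec("ath00", "SVMqaSH", np.diag([5, 5, 5]))])
    assert table.loc["SVMqaSH", "A_sd"] == 0.0


def _funnel_row(name, A, R, P_overall, P):
    return {
        "name": name,
        "classifier": "SVMq",
        "segment": "SH",
        "combo": "a",
        "A": A,
        **{f"R_{c}": r for c, r in zip(CONDITIONS, R)},
        "P_overall": P_overall,
        **{f"P_{c}": p for c, p in zip(CONDITIONS, P)},
    }


def test_selection_funnel_stages_and_nesting():
    table = pd.DataFrame(
        [
            _funnel_row("all_good", 0.9, (0.9, 0.9, 0.9), 0.9, (0.9, 0.9, 0.9)),
            _funnel_row("fail_acc", 0.79, (0.9, 0.9, 0.9), 0.9, (0.9, 0.9, 0.9)),
            _funnel_row("fail_recall", 0.9, (0.9, 0.79, 0.9), 0.9, (0.9, 0.9, 0.9)),
            _funnel_row("fail_p_overall", 0.9, (0.9, 0.9, 0.9), 0.79, (0.9, 0.9, 0.9)),
            _funnel_row("fail_p_class", 0.9, (0.9, 0.9, 0.9), 0.9, (0.79, 0.9, 0.9)),
            # 0.796 rounds to 0.80: passes under two-decimal comparison
            _funnel_row("round_up", 0.796, (0.9, 0.9, 0.9), 0.9, (0.9, 0.9, 0.9)),
        ]
    ).set_index("name")
    out = selection_funnel(table)
    assert out.loc["all_good", "stage_reached"] == "survivor"
    assert out.loc["fail_acc", "stage_reached"] == "rejected@1"
    assert out.loc["fail_recall", "stage_reached"] == "rejected@2"
    assert out.loc["fail_p_overall", "stage_reached"] == "rejected@3"
    assert out.loc["fail_p_class", "stage_reached"] == "rejected@4"
    assert out.loc["round_up", "survivor"]
    # nesting: stage-k survivors are a subset of stage-(k-1) survivors
    reached = out["stage_reached"]
    stages = ["rejected@1", "rejected@2", "rejected@3", "rejected@4", "survivor"]
    past = {s: set(out.index[reached.isin(stages[i + 1 :])]) for i, s in enumerate(stages[:-1])}
    assert past["rejected@4"] <= past["rejected@3"] <= past["rejected@2"] <= past["rejected@1"]


def test_selection_funnel_missing_column():
    table = pd.DataFrame([_funnel_row("x", 0.9, (0.9,) * 3, 0.9, (0.9,) * 3)]).set_index(
        "name"
    )
    with pytest.raises(InputError):
        selection_funnel(table.drop(columns=["P_overall"]))


def test_collapse_binary():
    assert np.array_equal(
        collapse_binary(np.diag([10, 10, 10])), [[10, 0], [0, 20]]
    )
    # LC <-> KB confusions land on the binary diagonal
    cm = np.array([[10, 0, 0], [0, 5, 5], [0, 5, 5]])
    cm2 = collapse_binary(cm)
    assert np.array_equal(cm2, [[10, 0], [0, 20]])
    rng = np.random.default_rng(1)
    for _ in range(20):
        cm = rng.integers(0, 50, size=(3, 3)) + 1
        cm2 = collapse_binary(cm)
        assert cm2.sum() == cm.sum()
        acc3 = np.trace(cm) / cm.sum()
        acc2 = np.trace(cm2) / cm2.sum()
        assert acc2 >= acc3 - 1e-12  # merging cannot create new errors


def test_goodness_index_values_and_categories():
    g, cat = goodness_from_rates(1.0, 1.0)
    assert g == 0.0 and cat == "optimum"
    g, cat = goodness_from_rates(0.5, 0.5)
    assert g == pytest.approx(math.sqrt(0.5))
    assert cat == "random"
    g, cat = goodness_from_rates(0.0, 0.0)
    assert g == pytest.approx(math.sqrt(2))
    assert cat == "bad"
    assert goodness_from_rates(0.9, 0.95)[1] == "optimum"
    assert goodness_from_rates(0.7, 0.8)[1] == "good"


def test_goodness_monotone_decreasing_in_rates():
    rates = np.linspace(0, 1, 21)
    g_tp = [goodness_from_rates(r, 0.6)[0] for r in rates]
    g_tn = [goodness_from_rates(0.6, r)[0] for r in rates]
    assert np.all(np.diff(g_tp) < 0)
    assert np.all(np.diff(g_tn) < 0)
    assert all(0 <= g <= math.sqrt(2) for g in g_tp + g_tn)
    assert CHANCE_G == pytest.approx(math.sqrt(0.5))


def test_goodness_index_from_matrix():
    g, cat = goodness_index([[50, 50], [50, 50]])
    assert g == pytest.approx(math.sqrt(0.5))
    assert cat == "random"
    with pytest.raises(InputError):
        goodness_index([[0, 0], [5, 5]])
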