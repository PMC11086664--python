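"""Kendall tau-b, dichotomization, ROC/AUC with DeLong SE, ratio tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bpequant.evaluation import (
    dichotomize,
    kendall_tau_b,
    ratio_vs_size_table,
    roc_analysis,
)


def tau_b_pair_oracle(x, y):
    """Exhaustive enumeration over all n(n-1)/2 pairs."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    p = q = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                p += 1
            else:
                q += 1
    return (p - q) / np.sqrt((p + q + tx) * (p + q + ty))


def auc_pair_oracle(scores, labels):
    """Exhaustive counting over all positive/negative pairs (ties 0.5)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


# --- Kendall tau-b ---------------------------------------------------------


def test_perfect_concordance_and_discordance():
    r = kendall_tau_b([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])
    assert r.tau_b == pytest.approx(1.0)
    r = kendall_tau_b([1, 2, 3, 4], [0.4, 0.3, 0.2, 0.1])
    assert r.tau_b == pytest.approx(-1.0)


def test_tau_with_ties_matches_pair_oracle():
    ratings = [1, 1, 2, 3]
    scores = [0.2, 0.1, 0.3, 0.25]
    r = kendall_tau_b(ratings, scores)
    assert r.tau_b == pytest.approx(tau_b_pair_oracle(ratings, scores), abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_tau_matches_oracle_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 60))
    ratings = rng.integers(1, 5, n)
    scores = np.round(rng.uniform(0, 1, n), 2)  # rounding induces ties
    if len(set(ratings)) < 2 or len(set(scores)) < 2:
        return
    r = kendall_tau_b(ratings, scores)
    assert r.tau_b == pytest.approx(tau_b_pair_oracle(ratings, scores), abs=1e-10)
    assert -1.0 <= r.tau_b <= 1.0 and 0.0 <= r.p_value <= 1.0


def test_tau_significant_for_strong_trend():
    rng = np.random.default_rng(0)
    ratings = np.repeat([1, 2, 3, 4], 15)
    scores = ratings + rng.normal(0, 0.3, ratings.size)
    r = kendall_tau_b(ratings, scores)
    assert r.p_value < 1e-6
    assert r.z_statistic > 4


def test_tau_undefined_for_constant_input():
    with pytest.raises(ValueError):
        kendall_tau_b([2, 2, 2, 2], [0.1, 0.2, 0.3, 0.4])


def test_tau_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    ratings = rng.integers(1, 5, 40)
    scores = rng.uniform(0, 1, 40)
    r1 = kendall_tau_b(ratings, scores)
    r2 = kendall_tau_b(ratings, np.exp(3 * scores))
    assert r1.tau_b == pytest.approx(r2.tau_b, abs=1e-12)


# --- dichotomization -------------------------------------------------------


def test_low_vs_high_keeps_all():
    labels, keep = dichotomize(["minimal", "mild", "moderate", "marked"], "low_vs_high")
    np.testing.assert_array_equal(labels, [0, 0, 1, 1])
    assert keep.size == 4


def test_minimal_vs_marked_drops_intermediate():
    labels, keep = dichotomize(["minimal", "mild", "moderate", "marked"],
                               "minimal_vs_marked")
    np.testing.assert_array_equal(labels, [0, 1])
    assert keep.size == 2


def test_clinical_composition_split():
    """A 99/159/78/14 minimal/mild/moderate/marked cohort dichotomizes to
    258 low and 92 high exams."""
    ratings = (["minimal"] * 99 + ["mild"] * 159 + ["moderate"] * 78 + ["marked"] * 14)
    labels, keep = dichotomize(ratings, "low_vs_high")
    assert keep.size == 350
    assert (labels == 0).sum() == 258
    assert (labels == 1).sum() == 92
    labels_mm, keep_mm = dichotomize(ratings, "minimal_vs_marked")
    assert (labels_mm == 0).sum() == 99
    assert (labels_mm == 1).sum() == 14


def test_empty_class_rejected():
    with pytest.raises(ValueError, match="positive"):
        dichotomize(["minimal", "mild"], "minimal_vs_marked")


# --- ROC analysis ----------------------------------------------------------


def test_perfect_separation():
    r = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1])
    assert r.auc == 1.0
    assert r.curve_points[0].tolist() == [0.0, 0.0]
    assert r.curve_points[-1].tolist() == [1.0, 1.0]


def test_tie_convention_gives_half():
    r = roc_analysis([1.0, 1.0, 1.0, 2.0, 1.0, 2.0], [0, 0, 1, 1, 1, 0])
    assert r.auc == pytest.approx(auc_pair_oracle([1, 1, 1, 2, 1, 2], [0, 0, 1, 1, 1, 0]))


def test_four_point_example():
    r = roc_analysis([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert r.auc == pytest.approx(0.75)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_matches_pair_oracle_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 80))
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        return
    scores = np.round(rng.uniform(0, 1, n), 2)
    r = roc_analysis(scores, labels)
    assert r.auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)


def test_trapezoid_curve_area_equals_mann_whitney():
    rng = np.random.default_rng(4)
    scores = np.round(rng.uniform(0, 1, 120), 2)
    labels = rng.integers(0, 2, 120)
    r = roc_analysis(scores, labels)
    area = np.trapezoid(r.curve_points[:, 1], r.curve_points[:, 0])
    assert area == pytest.approx(r.auc, abs=1e-12)


def test_flipping_labels_mirrors_auc():
    rng = np.random.default_rng(5)
    scores = rng.uniform(0, 1, 60)
    labels = rng.integers(0, 2, 60)
    a = roc_analysis(scores, labels).auc
    b = roc_analysis(scores, 1 - labels).auc
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(6)
    scores = rng.uniform(0, 1, 50)
    labels = rng.integers(0, 2, 50)
    assert roc_analysis(scores, labels).auc == pytest.approx(
        roc_analysis(np.log(scores + 1), labels).auc, abs=1e-12)


def test_degenerate_scores_give_chance_auc():
    with pytest.warns(UserWarning):
        r = roc_analysis(np.ones(10), [0] * 5 + [1] * 5)
    assert r.auc == 0.5
    assert np.isinf(r.se)
    assert r.p_vs_chance == 1.0


def test_bonferroni_correction_caps_at_one():
    rng = np.random.default_rng(7)
    scores = rng.uniform(0, 1, 40)
    labels = rng.integers(0, 2, 40)
    r = roc_analysis(scores, labels, n_comparisons=13)
    assert r.p_corrected == pytest.approx(min(1.0, r.p_vs_chance * 13))
    assert r.p_corrected <= 1.0


def test_strong_separation_is_significant():
    rng = np.random.default_rng(8)
    neg = rng.normal(0, 1, 60)
    pos = rng.normal(2.5, 1, 60)
    r = roc_analysis(np.concatenate([neg, pos]), [0] * 60 + [1] * 60,
                     n_comparisons=13)
    assert r.p_corrected < 0.001


def test_binormal_fit_close_to_empirical_on_gaussian_data():
    rng = np.random.default_rng(9)
    scores = np.concatenate([rng.normal(0, 1, 150), rng.normal(1.4, 1, 150)])
    labels = np.array([0] * 150 + [1] * 150)
    emp = roc_analysis(scores, labels, method="empirical")
    bn = roc_analysis(scores, labels, method="binormal")
    assert bn.method == "binormal"
    assert bn.auc == pytest.approx(emp.auc, abs=0.05)
    assert bn.binormal_params is not None


# --- ratio vs size ---------------------------------------------------------


def make_records(rows):
    return pd.DataFrame(rows)


def test_identical_scores_give_unit_ratios():
    rows = []
    for i, level in enumerate(["minimal", "marked"]):
        for removed in (False, True):
            rows.append(dict(exam_id=f"e{i}", region="affected",
                             projection_type="MIP", time_point=2,
                             rescale_mode="rescaled", lesion_removed=removed,
                             score=0.3, rating=level))
    per_exam, agg = ratio_vs_size_table(make_records(rows), {"e0": 8.0, "e1": 22.0})
    assert (per_exam.ratio == 1.0).all()
    assert len(per_exam) == 2


def test_missing_pair_skipped_with_warning():
    rows = [dict(exam_id="e0", region="affected", projection_type="MIP",
                 time_point=2, rescale_mode="rescaled", lesion_removed=False,
                 score=0.3, rating="mild")]
    with pytest.warns(UserWarning, match="missing"):
        per_exam, _ = ratio_vs_size_table(make_records(rows), {"e0": 10.0})
    assert per_exam.empty
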