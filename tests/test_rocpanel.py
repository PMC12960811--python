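"""ROC/AUC machinery, Youden cutoffs and combinatorial panels vs oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swabmark.rocpanel import (auc, combo_score, evaluate_combos,
                               marker_roc_table, roc_curve, stratified_eval,
                               youden_cutoff)


def auc_pair_counting(scores, labels):
    """Exhaustive pair-counting oracle with ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_brute_force(scores, labels):
    """Scan every candidate threshold for max J (smallest cutoff on ties)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best = (-np.inf, np.inf)
    for t in np.concatenate([[-np.inf], np.unique(scores), [np.inf]]):
        called = scores >= t
        se = (called & labels).sum() / labels.sum()
        sp = (~called & ~labels).sum() / (~labels).sum()
        j = se + sp - 1
        if j > best[0] or (j == best[0] and t < best[1]):
            best = (j, t)
    return best


instances = st.integers(min_value=0, max_value=2 ** 31 - 1).map(
    lambda seed: _random_instance(seed))


def _random_instance(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 50)
    labels = np.zeros(n, bool)
    labels[: rng.integers(1, n)] = True
    rng.shuffle(labels)
    # coarse grid forces ties
    scores = rng.choice(np.linspace(0, 1, 7), size=n)
    return scores, labels


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_perfect_separation_auc_one():
    assert auc([1, 2, 3, 10, 11, 12],
               [0, 0, 0, 1, 1, 1]) == pytest.approx(1.0)


def test_all_tied_scores_auc_half():
    assert auc([5.0] * 6, [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)


def test_169_pair_fixture():
    scores = np.array([0.6] * 12 + [0.3] + [0.2] * 12 + [0.7])
    labels = np.array([1] * 13 + [0] * 13, bool)
    expected = (144 + 12) / 169  # exhaustive pair counting
    assert auc(scores, labels) == pytest.approx(expected)
    assert auc_pair_counting(scores, labels) == pytest.approx(expected)


def test_one_class_absent_is_error():
    with pytest.raises(ValueError):
        auc([1.0, 2.0], [1, 1])


@settings(max_examples=300, deadline=None, derandomize=True)
@given(instances)
def test_auc_equals_pair_counting_oracle(instance):
    scores, labels = instance
    assert auc(scores, labels) == pytest.approx(
        auc_pair_counting(scores, labels), abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(instances)
def test_sign_reversal_maps_auc_to_complement(instance):
    scores, labels = instance
    assert auc(-scores, labels) == pytest.approx(1.0 - auc(scores, labels))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(instances)
def test_auc_invariant_under_monotone_transform(instance):
    scores, labels = instance
    assert auc(np.exp(3 * scores) + 1, labels) == pytest.approx(
        auc(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# ROC curve + Youden
# ---------------------------------------------------------------------------

def test_two_sample_curve_hits_perfect_corner():
    r = roc_curve([1.0, 0.0], [1, 0])
    corner = (r.sensitivity == 1.0) & (r.specificity == 1.0)
    assert corner.any()
    assert r.auc == 1.0 and r.youden_j == 1.0


@settings(max_examples=300, deadline=None, derandomize=True)
@given(instances)
def test_trapezoid_area_equals_pair_counting(instance):
    scores, labels = instance
    r = roc_curve(scores, labels)
    # integrate SE over (1 - SP); thresholds descending traces the curve
    order = np.argsort(-r.thresholds)
    x = 1 - r.specificity[order]
    y = r.sensitivity[order]
    area = float(np.trapezoid(y, x))
    assert area == pytest.approx(r.auc, abs=1e-12)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(instances)
def test_youden_equals_brute_force_scan(instance):
    scores, labels = instance
    cutoff, j, se, sp, confusion = youden_cutoff(scores, labels)
    j0, t0 = youden_brute_force(scores, labels)
    assert j == pytest.approx(j0, abs=1e-12)
    assert cutoff == t0
    assert j == pytest.approx(se + sp - 1, abs=1e-12)
    assert confusion["tp"] + confusion["fn"] == labels.sum()
    assert confusion["tn"] + confusion["fp"] == (~labels).sum()


def test_perfectly_separated_groups_zero_false_calls():
    r = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert r.youden_j == 1.0
    assert r.fp == 0 and r.fn == 0
    assert r.pct_false_pos == 0.0 and r.pct_false_neg == 0.0


def test_cutoff_shift_equivariance():
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.9])
    labels = np.array([0, 0, 0, 1, 1, 1])
    r0 = roc_curve(scores, labels)
    r1 = roc_curve(scores + 2.5, labels)
    assert r1.youden_cutoff == pytest.approx(r0.youden_cutoff + 2.5)
    assert r1.youden_j == pytest.approx(r0.youden_j)


# ---------------------------------------------------------------------------
# panel combination
# ---------------------------------------------------------------------------

def _two_marker_cohort(seed=0, n=30, shift=3.0):
    rng = np.random.default_rng(seed)
    labels = np.repeat([False, True], n // 2)
    a = rng.normal(0, 1, n) + shift * labels
    b = rng.normal(0, 1, n)  # pure noise
    return pd.DataFrame({"A": a, "B": b}), labels


def test_mean_z_single_marker_is_standardisation():
    expr, labels = _two_marker_cohort()
    s = combo_score(expr, labels, ["A"], method="mean_z")
    z = (expr["A"] - expr["A"].mean()) / expr["A"].std(ddof=0)
    np.testing.assert_allclose(s, z, atol=1e-12)


def test_separable_panel_scores_order_classes():
    expr, labels = _two_marker_cohort(shift=10.0)
    s = combo_score(expr, labels, ["A", "B"], method="logistic")
    assert auc(s, labels) == pytest.approx(1.0)
    assert np.all((s >= 0) & (s <= 1))


def test_noise_marker_does_not_dominate_strong_marker():
    deltas = []
    for seed in range(10):
        expr, labels = _two_marker_cohort(seed=seed, n=40, shift=2.0)
        single = auc(expr["A"], labels)
        combo = auc(combo_score(expr, labels, ["A", "B"]), labels)
        deltas.append(combo - single)
    assert np.mean(np.abs(deltas)) < 0.05


def test_constant_marker_dropped_with_warning(caplog):
    expr, labels = _two_marker_cohort()
    expr["C"] = 1.0
    s = combo_score(expr, labels, ["A", "C"], method="mean_z")
    z = (expr["A"] - expr["A"].mean()) / expr["A"].std(ddof=0)
    np.testing.assert_allclose(s, z, atol=1e-12)
    expr["A"] = 2.0
    with pytest.raises(ValueError, match="constant"):
        combo_score(expr, labels, ["A", "C"])


def test_four_markers_sizes_2_to_4_give_eleven_combos():
    rng = np.random.default_rng(1)
    labels = np.repeat([False, True], 13)
    expr = pd.DataFrame(rng.normal(size=(26, 4)),
                        columns=["c-JUN", "SFN", "HSP90AB1", "STARD7"])
    panel = evaluate_combos(expr, labels, list(expr.columns),
                            min_size=2, max_size=4)
    assert len(panel.table) == 11  # C(4,2) + C(4,3) + C(4,4)
    assert panel.table["rank"].tolist() == list(range(1, 12))


def test_duplicated_marker_not_double_counted():
    expr, labels = _two_marker_cohort()
    panel = evaluate_combos(expr, labels, ["A", "B", "A"],
                            min_size=2, max_size=2)
    assert len(panel.table) == 1


def test_min_size_below_two_rejected():
    expr, labels = _two_marker_cohort()
    with pytest.raises(ValueError, match="min_size"):
        evaluate_combos(expr, labels, ["A", "B"], min_size=1)


def test_all_noise_panel_auc_near_half():
    rng = np.random.default_rng(3)
    aucs = []
    for _ in range(20):
        labels = np.repeat([False, True], 40)
        expr = pd.DataFrame(rng.normal(size=(80, 3)),
                            columns=["a", "b", "c"])
        s = combo_score(expr, labels, ["a", "b", "c"], method="mean_z")
        aucs.append(auc(s, labels))
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


def test_panel_ranking_orders_by_auc_then_j():
    expr, labels = _two_marker_cohort(shift=2.0)
    panel = evaluate_combos(expr, labels, ["A", "B"], min_size=2, max_size=2)
    t = panel.table
    key = list(zip(-t["auc"], -t["youden_j"], t["size"]))
    assert key == sorted(key)


# ---------------------------------------------------------------------------
# stratified evaluation
# ---------------------------------------------------------------------------

def test_identical_strata_have_zero_auc_difference():
    expr, labels = _two_marker_cohort(n=40)
    strata = np.tile(["m", "f"], 20)
    # make strata truly identical by construction
    expr2 = pd.concat([expr, expr], ignore_index=True)
    labels2 = np.concatenate([labels, labels])
    strata2 = np.array(["m"] * len(labels) + ["f"] * len(labels))
    out = stratified_eval(expr2, labels2, strata2, ["A", "B"])
    diffs = out[out["stratum"].str.startswith("diff:")]
    np.testing.assert_allclose(diffs["auc"], 0.0, atol=1e-12)


def test_single_class_stratum_skipped(caplog):
    expr, labels = _two_marker_cohort(n=20)
    strata = np.where(labels, "all_pos", "mixed")
    strata[:3] = "mixed"
    out = stratified_eval(expr, labels, strata, ["A"])
    assert "all_pos" not in set(out["stratum"])


def test_attenuated_stratum_has_lower_auc_over_seeds():
    gaps = []
    for seed in range(15):
        rng = np.random.default_rng(seed)
        labels = np.repeat([False, True], 30)
        strata = np.tile(["male", "female"], 30)
        effect = np.where(strata == "male", 2.5, 0.75)
        x = rng.normal(0, 1, 60) + effect * labels
        expr = pd.DataFrame({"A": x, "B": rng.normal(0, 1, 60)})
        out = stratified_eval(expr, labels, strata, ["A"])
        male = out[(out["stratum"] == "male") & (out["marker"] == "A")]
        female = out[(out["stratum"] == "female") & (out["marker"] == "A")]
        gaps.append(float(male["auc"].iloc[0] - female["auc"].iloc[0]))
    assert np.mean(gaps) > 0.1


def test_marker_roc_table_shape():
    expr, labels = _two_marker_cohort()
    tab = marker_roc_table(expr, labels, ["A", "B"])
    assert list(tab["marker"]) == ["A", "B"]
    assert ((tab["auc"] >= 0) & (tab["auc"] <= 1)).all()
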