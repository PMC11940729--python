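"""Evaluation protocol: AUC oracle, hit-rate identities, screens."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oculocog.dataset import FEATURE_NAMES
from oculocog.evaluation import (SplitScheme, ablation_suite,
                                 feature_behavior_correlations,
                                 group_difference_screen, model_comparison,
                                 repeated_holdout, results_table, roc_auc)

FAST_CNN = {"epochs": 25}


def _separable_table(n_per_group=15, seed=0, groups=("control", "mci"),
                     sep=8.0):
    """A canonical-format table with an easily separable group signal."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(groups):
        for k in range(n_per_group):
            vals = rng.normal(0, 1, len(FEATURE_NAMES))
            vals[:5] += sep * gi
            rows.append({"participant_id": f"{g[0]}{k}", "group": g,
                         **dict(zip(FEATURE_NAMES, vals))})
    return pd.DataFrame(rows, columns=["participant_id", "group"]
                        + FEATURE_NAMES)


def brute_force_auc(pos_scores, neg_scores):
    wins = sum(0.5 if p == n else (p > n)
               for p, n in itertools.product(pos_scores, neg_scores))
    return wins / (len(pos_scores) * len(neg_scores))


def test_auc_toy_scores_match_pair_counting():
    # negatives 0.1, 0.4; positives 0.35, 0.8: the positive wins 3 of the
    # 4 positive-negative pairs (0.35 < 0.4 loses one), no ties -> 0.75
    scores = np.array([0.1, 0.4, 0.35, 0.8])
    labels = np.array([False, False, True, True])
    assert brute_force_auc([0.35, 0.8], [0.1, 0.4]) == 0.75
    assert roc_auc(scores, labels) == pytest.approx(0.75)


def test_auc_ties_and_perfect_ranking():
    labels = np.array([True, False, True, False])
    assert roc_auc(np.full(4, 0.5), labels) == pytest.approx(0.5)
    assert roc_auc(np.array([0.9, 0.1, 0.8, 0.2]), labels) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="one class absent"):
        roc_auc(np.array([0.1, 0.2]), np.array([True, True]))


def test_auc_equals_pair_counting_on_random_scores(rng):
    pos = rng.normal(1, 1, 13)
    neg = rng.normal(0, 1, 9)
    scores = np.concatenate([pos, neg])
    labels = np.array([True] * 13 + [False] * 9)
    assert roc_auc(scores, labels) == pytest.approx(
        brute_force_auc(pos, neg))


def test_separable_groups_classified_perfectly():
    table = _separable_table()
    res = repeated_holdout(table, "binary", "combined", "svm",
                           SplitScheme(n_repeats=4, base_seed=1))
    assert res.mean_accuracy == 1.0
    assert res.sd_accuracy == 0.0
    assert res.auc == 1.0


def test_accuracy_equals_weighted_hit_rates_each_fold():
    table = _separable_table(sep=1.0, n_per_group=20)
    res = repeated_holdout(table, "binary", "combined", "rf",
                           SplitScheme(n_repeats=5, base_seed=3))
    for rep, cm in enumerate(res.confusions):
        acc = np.trace(cm) / cm.sum()
        assert acc == pytest.approx(res.accuracies[rep])
        weighted = sum(res.hit_rates[c][rep] * cm[i].sum()
                       for i, c in enumerate(res.classes)) / cm.sum()
        assert weighted == pytest.approx(acc)


def test_repeated_holdout_deterministic_and_disjoint():
    table = _separable_table(sep=2.0)
    scheme = SplitScheme(n_repeats=3, base_seed=9)
    a = repeated_holdout(table, "binary", "combined", "rf", scheme)
    b = repeated_holdout(table, "binary", "combined", "rf", scheme)
    assert a.accuracies == b.accuracies
    assert a.misclassified == b.misclassified


def test_misclassified_ids_are_real_participants():
    table = _separable_table(sep=0.3)
    res = repeated_holdout(table, "binary", "combined", "rf",
                           SplitScheme(n_repeats=2, base_seed=0))
    ids = set(table.participant_id)
    for fold in res.misclassified:
        for pid, true, pred in fold:
            assert pid in ids and true != pred


def test_permuted_labels_give_chance_accuracy():
    rng = np.random.default_rng(4)
    table = _separable_table(sep=6.0, n_per_group=20)
    table["group"] = rng.permutation(table["group"].to_numpy())
    res = repeated_holdout(table, "binary", "combined", "cnn",
                           SplitScheme(n_repeats=3, base_seed=2), FAST_CNN)
    # 95% binomial band around the majority rate over 3 x 8 test rows
    p0 = 0.5
    half_width = 1.96 * np.sqrt(p0 * (1 - p0) / 24)
    assert abs(res.mean_accuracy - p0) <= half_width + 1e-9


def test_ablation_suite_has_seven_feature_sets():
    table = _separable_table(sep=5.0, n_per_group=12)
    results = ablation_suite(table, "binary", "svm",
                             SplitScheme(n_repeats=2, base_seed=0))
    assert len(results) == 7
    tab = results_table(results)
    assert set(tab.feature_set) == {"combined", "eye_only", "behavior_only",
                                    "no_proanti", "no_pursuit", "no_memory",
                                    "no_predictive"}
    assert {"hit_rate_control", "hit_rate_mci"} <= set(tab.columns)


def test_triple_task_reports_three_hit_rates():
    table = _separable_table(groups=("control", "mci", "young"),
                             n_per_group=10, sep=5.0)
    res = repeated_holdout(table, "triple", "combined", "rf",
                           SplitScheme(n_repeats=2, base_seed=1))
    assert res.classes == ("control", "mci", "young")


def test_model_comparison_runs_all_four_kinds():
    table = _separable_table(sep=6.0, n_per_group=10)
    out = model_comparison(table, "binary", SplitScheme(n_repeats=1,
                                                        base_seed=0),
                           FAST_CNN)
    assert sorted(out) == ["cnn", "fcnn", "rf", "svm"]
    # trivially separable contrast: every model is essentially perfect
    assert all(r.mean_accuracy >= 0.99 for r in out.values())


def test_welch_screen_type_one_error_calibrated():
    """Under the null, ~5% of t-tests reject at alpha = 0.05."""
    rng = np.random.default_rng(11)
    rejections, total = 0, 0
    for _ in range(400):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        from scipy import stats
        _, p = stats.ttest_ind(a, b, equal_var=False)
        rejections += p < 0.05
        total += 1
    assert 0.02 <= rejections / total <= 0.08


def test_welch_screen_detects_large_shift_and_covers_all_features():
    table = _separable_table(sep=2.0, n_per_group=30,
                             groups=("young", "control"))
    screen = group_difference_screen(table)
    assert len(screen) == 39
    assert (screen.kind == "eye").sum() == 31
    shifted = screen[screen.feature == FEATURE_NAMES[0]]
    assert bool(shifted.pass_young_elderly.iloc[0])
    with pytest.raises(ValueError, match="young"):
        group_difference_screen(_separable_table(groups=("control", "mci")))


def test_correlation_matrix_shape_and_null_behaviour(rng):
    n = 100
    data = {"participant_id": [str(i) for i in range(n)],
            "group": ["control"] * n}
    for name in FEATURE_NAMES:
        data[name] = rng.normal(0, 1, n)
    table = pd.DataFrame(data)
    corr = feature_behavior_correlations(table)
    assert len(corr) == 31 * 8
    # independent columns: 95% of |r| below ~0.3 at n = 100
    assert (corr.r.abs() < 0.3).mean() >= 0.95

    # exact anticorrelation is recovered
    table[FEATURE_NAMES[31]] = -table[FEATURE_NAMES[0]]
    corr2 = feature_behavior_correlations(table)
    row = corr2[(corr2.eye_feature == FEATURE_NAMES[0])
                & (corr2.behavior_feature == FEATURE_NAMES[31])]
    assert row.r.iloc[0] == pytest.approx(-1.0)

    # constant columns are reported as missing, not crashes
    table[FEATURE_NAMES[1]] = 3.14
    corr3 = feature_behavior_correlations(table)
    assert corr3[corr3.eye_feature == FEATURE_NAMES[1]].r.isna().all()
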