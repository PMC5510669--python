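import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwtriage import (
    ClassifierConfig,
    SyntheticConfig,
    auc,
    cohort_features,
    decision_value,
    default_exclusion_mask,
    enumerate_intervals,
    fit,
    generate_cohort,
    loo_cross_validate,
    roc_curve,
    specificity_at_full_sensitivity,
    sweep_model_selection,
)


def labels_for(n_pos, n_neg):
    return np.array(["cSDH"] * n_pos + ["HC"] * n_neg)


def mann_whitney_auc(scores, labels):
    """Independent oracle: brute-force pair counting with half-credit ties."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == "cSDH"]
    neg = scores[np.asarray(labels) == "HC"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROCCurve:
    def test_enumerated_threshold_points(self):
        curve = roc_curve([2, 3, 0, 1], labels_for(2, 2))
        assert curve.points == [(0, 0), (0, 0.5), (0, 1), (0.5, 1), (1, 1)]

    def test_all_scores_equal_is_chance(self):
        curve = roc_curve([1.5] * 6, labels_for(3, 3))
        assert curve.points == [(0, 0), (1, 1)]
        assert auc([1.5] * 6, labels_for(3, 3)) == pytest.approx(0.5)

    def test_negating_scores_mirrors_auc(self, rng):
        scores = rng.standard_normal(12)
        labels = labels_for(5, 7)
        assert auc(-scores, labels) == pytest.approx(1 - auc(scores, labels))

    def test_monotone_from_origin_to_corner(self, rng):
        curve = roc_curve(rng.standard_normal(20), labels_for(10, 10))
        assert (curve.fpr[0], curve.tpr[0]) == (0, 0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1, 1)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], np.array(["HC", "HC"]))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([2, 3, 0, 1], labels_for(2, 2)) == 1.0

    def test_three_of_four_pairs_ordered(self):
        assert auc([1, 3, 2, 0], labels_for(2, 2)) == 0.75

    def test_single_tied_pair(self):
        assert auc([1.0, 1.0], labels_for(1, 1)) == 0.5

    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=30),
        st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equals_mann_whitney_with_ties(self, raw, data):
        n = len(raw)
        n_pos = data.draw(st.integers(1, n - 1))
        labels = labels_for(n_pos, n - n_pos)
        scores = np.asarray(raw, float)
        assert auc(scores, labels) == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12
        )

    def test_matches_scipy_and_sklearn_oracles(self, rng):
        # independent routes: rank-sum statistic and sklearn's ROC area
        from scipy.stats import mannwhitneyu
        from sklearn.metrics import roc_auc_score

        scores = rng.integers(-3, 4, size=30).astype(float)  # ties guaranteed
        labels = labels_for(13, 17)
        ours = auc(scores, labels)
        assert ours == pytest.approx(
            roc_auc_score((labels == "cSDH").astype(int), scores), abs=1e-12
        )
        u = mannwhitneyu(scores[:13], scores[13:]).statistic
        assert ours == pytest.approx(u / (13 * 17), abs=1e-12)

    def test_shift_invariance(self, rng):
        scores = rng.standard_normal(16)
        labels = labels_for(8, 8)
        assert auc(scores + 5.7, labels) == pytest.approx(auc(scores, labels))
        assert specificity_at_full_sensitivity(
            scores + 5.7, labels
        ) == pytest.approx(specificity_at_full_sensitivity(scores, labels))


class TestSpecificityAtFullSensitivity:
    def test_counting(self):
        scores = np.concatenate([[1.0] * 5, np.linspace(0, 2, 20)])
        labels = labels_for(5, 20)
        expected = np.sum(np.linspace(0, 2, 20) < 1.0) / 20
        assert specificity_at_full_sensitivity(scores, labels) == pytest.approx(expected)

    def test_perfect_separation(self):
        assert specificity_at_full_sensitivity([2, 3, 0, 1], labels_for(2, 2)) == 1.0

    def test_tied_negative_counts_as_false_positive(self):
        # min patient score 1.0; one control tied at 1.0 is a false positive
        assert specificity_at_full_sensitivity(
            [1.0, 2.0, 1.0, 0.0], labels_for(2, 2)
        ) == pytest.approx(0.5)

    def test_matches_roc_curve_full_sensitivity_point(self, rng):
        scores = rng.standard_normal(24)
        labels = labels_for(12, 12)
        curve = roc_curve(scores, labels)
        best_spec = 1 - min(f for f, t in zip(curve.fpr, curve.tpr) if t == 1.0)
        assert specificity_at_full_sensitivity(scores, labels) == pytest.approx(best_spec)


class TestLOOCrossValidation:
    def test_matches_hand_rolled_loop(self, tiny_cohort):
        cfg = ClassifierConfig(rank=1, f_lo=0.4, f_hi=1.9)
        result = loo_cross_validate(tiny_cohort, cfg)
        X, labels, ids = cohort_features(tiny_cohort, cfg.mask, 0.4, 1.9)
        for i in range(len(labels)):
            keep = [j for j in range(len(labels)) if j != i]
            Xp = X[[j for j in keep if labels[j] == "cSDH"]]
            Xc = X[[j for j in keep if labels[j] == "HC"]]
            model = fit(Xp, Xc, cfg)
            assert result.scores[i] == pytest.approx(decision_value(model, X[i]), abs=1e-12)
        assert result.auc == pytest.approx(auc(result.scores, labels))

    def test_subject_order_invariance(self, tiny_cohort):
        cfg = ClassifierConfig(rank=1, f_lo=0.4, f_hi=1.9)
        res1 = loo_cross_validate(tiny_cohort, cfg)
        perm = [7, 2, 9, 0, 4, 11, 1, 3, 10, 6, 5, 8]
        res2 = loo_cross_validate(tiny_cohort.subset(perm), cfg)
        by_id = dict(zip(res2.subject_ids, res2.scores))
        for sid, score in zip(res1.subject_ids, res1.scores):
            assert by_id[sid] == pytest.approx(score, abs=1e-12)

    def test_perfectly_separated_scores_give_auc_one(self):
        scores = np.array([1.0, 2, 3, -1, -2, -3])
        labels = labels_for(3, 3)
        assert auc(scores, labels) == 1.0
        assert specificity_at_full_sensitivity(scores, labels) == 1.0

    def test_class_too_small_names_class(self, tiny_cohort):
        cfg = ClassifierConfig(rank=6, f_lo=0.4, f_hi=1.9)
        with pytest.raises(ValueError, match="cSDH|HC"):
            loo_cross_validate(tiny_cohort, cfg)


class TestSweep:
    def test_default_grid_has_465_candidate_intervals(self):
        assert len(enumerate_intervals(0.10, 1.95, 0.05, 0.40)) == 465

    def test_min_width_equal_to_span_gives_single_interval(self):
        assert enumerate_intervals(0.1, 0.5, 0.1, 0.4) == [(0.1, 0.5)]

    def test_min_width_below_step_rejected(self):
        with pytest.raises(ValueError):
            enumerate_intervals(0.1, 1.0, 0.1, 0.05)

    def test_planted_band_recovered(self):
        # lesion confined to >= 1.0 GHz at a weak gain, so including the dead
        # low band dilutes the signal; the selected interval should start
        # within two grid steps of the live band.  Without planted structure
        # the wider-interval tie-break would drag the start down to 0.1 GHz.
        hits = 0
        n_rep = 10
        for seed in range(1, n_rep + 1):
            cfg = SyntheticConfig(
                n_patients=14,
                n_controls=14,
                freq_start=0.10,
                freq_stop=1.90,
                freq_step=0.15,
                lesion_band=(1.0, 1.9),
                hematoma_gain=0.06,
                seed=seed,
            )
            cohort = generate_cohort(cfg)
            sweep = sweep_model_selection(
                cohort, f_start=0.10, f_stop=1.90, step=0.15, min_width=0.45, ranks=[1]
            )
            if sweep.selected_interval[0] >= 1.0 - 2 * 0.15 - 1e-9:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_sweep_table_covers_all_interval_rank_pairs(self, tiny_cohort):
        sweep = sweep_model_selection(
            tiny_cohort, f_start=0.1, f_stop=1.9, step=0.3, min_width=0.9, ranks=[1, 2]
        )
        n_intervals = len(enumerate_intervals(0.1, 1.9, 0.3, 0.9))
        assert len(sweep.table) == 2 * n_intervals
        assert set(sweep.table["rank"]) == {1, 2}
        assert sweep.selected_rank in (1, 2)
        f_lo, f_hi = sweep.selected_interval
        assert f_hi - f_lo >= 0.9 - 1e-9
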