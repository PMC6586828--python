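"""ROC curves, operating points, predictive values, and repeat-split evaluation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import exclusig as ex
from exclusig.evaluate import confusion_at, ols_refit_scores, stratified_half_split
from tests.conftest import two_group_cohort

CASES4 = np.array([0.9, 0.35, 0.4, 0.3])
LABELS4 = np.array([1, 1, 0, 0])


def _pair_count_auc(scores, labels):
    """O(n^2) oracle: concordant pairs, ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def _enumerate_points(scores, labels):
    """Exhaustive threshold enumeration oracle for operating points."""
    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    pts = []
    for t in thresholds:
        tp, fp, tn, fn = confusion_at(scores, labels, t)
        pts.append((t, tp / (tp + fn), tn / (tn + fp)))
    return pts


class TestRocCurve:
    def test_four_sample_hand_table(self):
        roc = ex.roc_curve(CASES4, LABELS4)
        expected = pd.DataFrame(
            {
                "threshold": [np.inf, 0.9, 0.4, 0.35, 0.3],
                "sens": [0.0, 0.5, 0.5, 1.0, 1.0],
                "spec": [1.0, 1.0, 0.5, 0.5, 0.0],
            }
        )
        pd.testing.assert_frame_equal(roc, expected)

    def test_perfect_separation_reaches_corner(self):
        roc = ex.roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert ((roc["sens"] == 1.0) & (roc["spec"] == 1.0)).any()

    def test_constant_scores_only_corners(self):
        roc = ex.roc_curve([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert len(roc) == 2
        assert roc["sens"].tolist() == [0.0, 1.0]
        assert roc["spec"].tolist() == [1.0, 0.0]

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ex.roc_curve([1.0, 2.0], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    def test_points_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        roc = ex.roc_curve(scores, labels)
        got = set(zip(roc["threshold"], roc["sens"], roc["spec"]))
        assert got == set(_enumerate_points(scores, labels))


class TestAuc:
    def test_four_sample_value(self):
        assert ex.auc(CASES4, LABELS4) == pytest.approx(0.75)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        assert ex.auc(s, y) == pytest.approx(1 - ex.auc(s, 1 - y))

    def test_all_ties_give_half(self):
        assert ex.auc([1.0] * 10, [0, 1] * 5) == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_pair_counting_and_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got = ex.auc(scores, labels)
        assert got == pytest.approx(_pair_count_auc(scores, labels), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestOperatingPoints:
    def test_best_point_perfect_classifier(self):
        roc = ex.roc_curve([1, 2, 10, 11], [0, 0, 1, 1])
        bp = ex.best_point(roc)
        assert (bp.sens, bp.spec) == (1.0, 1.0)

    def test_best_point_four_sample_vs_distance_oracle(self):
        roc = ex.roc_curve(CASES4, LABELS4)
        pts = _enumerate_points(CASES4, LABELS4)
        d = [math.hypot(1 - s, 1 - p) for _, s, p in pts]
        best = min(d)
        oracle = max(
            (pt for pt, dd in zip(pts, d) if dd == best),
            key=lambda pt: (pt[1], pt[0]),
        )
        bp = ex.best_point(roc)
        assert (bp.threshold, bp.sens, bp.spec) == oracle

    def test_best_point_tie_breaks_toward_sensitivity(self):
        roc = pd.DataFrame(
            {"threshold": [2.0, 1.0], "sens": [0.6, 0.8], "spec": [0.8, 0.6]}
        )
        bp = ex.best_point(roc)
        assert bp.sens == 0.8

    def test_point_at_min_perfect(self):
        roc = ex.roc_curve([1, 2, 10, 11], [0, 0, 1, 1])
        pt = ex.point_at_min(roc, "sensitivity", 0.98)
        assert (pt.sens, pt.spec, pt.attained) == (1.0, 1.0, True)

    def test_point_at_min_matches_enumeration(self):
        roc = ex.roc_curve(CASES4, LABELS4)
        pt = ex.point_at_min(roc, "sensitivity", 0.93)
        feasible = [p for p in _enumerate_points(CASES4, LABELS4) if p[1] >= 0.93]
        oracle = max(feasible, key=lambda p: p[2])
        assert (pt.sens, pt.spec) == (oracle[1], oracle[2])
        assert pt.attained

    def test_unattainable_level_flagged(self):
        # a truncated curve with no point at sens >= 0.93
        roc = pd.DataFrame(
            {"threshold": [np.inf, 1.0], "sens": [0.0, 0.6], "spec": [1.0, 0.9]}
        )
        pt = ex.point_at_min(roc, "sensitivity", 0.93)
        assert not pt.attained
        assert pt.sens == 0.6  # maximal constrained metric reported


class TestPpvNpv:
    def test_arithmetic(self):
        assert ex.ppv_npv(9, 3, 8, 2) == pytest.approx((0.75, 0.8))

    def test_no_false_positives(self):
        ppv, _ = ex.ppv_npv(5, 0, 3, 1)
        assert ppv == 1.0

    def test_degenerate_denominator_flagged(self):
        ppv, npv = ex.ppv_npv(0, 0, 3, 1)
        assert math.isnan(ppv) and npv == 0.75


class TestEvaluateModelReplication:
    def test_perfectly_separable(self, separable_cohort):
        coding = ex.code_outcome(separable_cohort, "benign_vs_III_IV")
        summary = ex.evaluate_model_replication(
            ["SEP"], separable_cohort, coding, n_repeats=10, seed=0
        )
        assert summary.means["AUC"] == 1.0
        assert summary.sds["AUC"] == 0.0
        assert summary.means["BPse"] == 1.0 and summary.means["BPsp"] == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        cohort = two_group_cohort(
            rng.standard_normal((80, 3)), rng.standard_normal((80, 3))
        )
        coding = ex.code_outcome(cohort, "benign_vs_III_IV")
        summary = ex.evaluate_model_replication(
            cohort.proteins, cohort, coding, n_repeats=50, seed=2
        )
        assert summary.means["AUC"] == pytest.approx(0.5, abs=0.08)

    def test_seed_determinism(self, separable_cohort):
        coding = ex.code_outcome(separable_cohort, "benign_vs_III_IV")
        a = ex.evaluate_model_replication(
            ["SEP", "N1"], separable_cohort, coding, n_repeats=5, seed=7
        )
        b = ex.evaluate_model_replication(
            ["SEP", "N1"], separable_cohort, coding, n_repeats=5, seed=7
        )
        assert a.means == b.means and a.sds == b.sds

    def test_single_repeat_equals_hand_driven_split(self):
        rng = np.random.default_rng(3)
        cohort = two_group_cohort(
            rng.standard_normal((40, 2)), rng.standard_normal((40, 2)) + 1.2
        )
        coding = ex.code_outcome(cohort, "benign_vs_III_IV")
        summary = ex.evaluate_model_replication(
            cohort.proteins, cohort, coding, n_repeats=1, seed=11
        )
        # oracle: walk the same rng through the same steps
        from exclusig.data import design_matrix

        X, y, _ = design_matrix(cohort, coding, cohort.proteins)
        rng2 = np.random.default_rng(11)
        tr, te = stratified_half_split(y, rng2)
        s = ols_refit_scores(X[tr], y[tr], X[te])
        assert summary.means["AUC"] == pytest.approx(ex.auc(s, y[te]))
        bp = ex.best_point(ex.roc_curve(s, y[te]))
        assert summary.means["BPse"] == pytest.approx(bp.sens)
        assert summary.means["BPsp"] == pytest.approx(bp.spec)

    def test_missing_protein_raises(self, separable_cohort):
        coding = ex.code_outcome(separable_cohort, "benign_vs_III_IV")
        with pytest.raises(KeyError):
            ex.evaluate_model_replication(
                ["ABSENT"], separable_cohort, coding, n_repeats=2, seed=0
            )


class TestRankModels:
    def _summary(self, bpse, bpsp, auc_, size, mid):
        means = {m: 0.5 for m in ("PPV", "NPV", "FSEse", "FSEsp", "FSPse", "FSPsp")}
        means |= {"BPse": bpse, "BPsp": bpsp, "AUC": auc_}
        return ex.EvaluationSummary(
            comparison="benign_vs_III_IV", n_repeats=10, min_level=0.93,
            means=means, sds={m: 0.0 for m in means}, model_size=size, model_id=mid,
        )

    def test_ordering_and_tie_breaks(self):
        perfect = self._summary(1.0, 1.0, 1.0, 10, "perfect")
        good = self._summary(0.9, 0.9, 0.97, 12, "good")
        good_small = self._summary(0.9, 0.9, 0.97, 8, "good_small")
        good_lowauc = self._summary(0.9, 0.9, 0.90, 8, "good_lowauc")
        ranked = ex.rank_models([good_lowauc, good, perfect, good_small])
        assert [s.model_id for s in ranked] == [
            "perfect", "good_small", "good", "good_lowauc"
        ]

    def test_input_order_invariance(self):
        models = [self._summary(0.8 + 0.01 * i, 0.8, 0.9, 10, f"m{i}") for i in range(5)]
        a = [s.model_id for s in ex.rank_models(models)]
        b = [s.model_id for s in ex.rank_models(models[::-1])]
        assert a == b

    def test_mixed_comparisons_rejected(self):
        a = self._summary(0.9, 0.9, 0.9, 5, "a")
        b = self._summary(0.9, 0.9, 0.9, 5, "b")
        b.comparison = "benign_vs_I_II"
        with pytest.raises(ValueError):
            ex.rank_models([a, b])


class TestCompareScoreGroups:
    def test_bonferroni_threshold_six_comparisons(self):
        rng = np.random.default_rng(4)
        groups = {g: rng.normal(size=12) for g in ["a", "b", "c", "d"]}
        out = ex.compare_score_groups(groups)  # 4 choose 2 = 6 pairs
        assert len(out) == 6
        assert out.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 6)

    def test_identical_groups_not_significant(self):
        x = np.arange(10.0)
        out = ex.compare_score_groups({"a": x, "b": x.copy()})
        assert out["p"].iloc[0] > 0.9
        assert not out["significant"].iloc[0]

    def test_fully_separated_groups_match_exact_tail(self):
        out = ex.compare_score_groups(
            {"lo": np.arange(10.0), "hi": np.arange(100.0, 110.0)}
        )
        # two-sided exact rank-sum p for complete separation: 2 / C(20, 10)
        assert out["p"].iloc[0] == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)
        assert out["significant"].iloc[0]

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            ex.compare_score_groups({"a": [1.0], "b": [1.0, 2.0]})
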