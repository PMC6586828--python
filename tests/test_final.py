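"""Stratified splitting, one-SE ridge, DeLong comparison, cut-offs, prediction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import exclusig as ex
from exclusig.final import RidgeFitResult, _ridge_path, delong_auc_variance
from tests.conftest import two_group_cohort


class TestStratifiedSplit:
    def test_equal_halves_per_stratum(self):
        labels = pd.Series(
            ["benign"] * 100 + ["malign"] * 90,
            index=[f"S{i}" for i in range(190)],
        )
        train, val = ex.stratified_split(labels, seed=0)
        tr = labels.loc[train].value_counts()
        va = labels.loc[val].value_counts()
        assert tr["benign"] == va["benign"] == 50
        assert tr["malign"] == va["malign"] == 45

    def test_disjoint_and_covering(self):
        labels = pd.Series([0, 0, 0, 1, 1, 1, 1], index=list("abcdefg"))
        train, val = ex.stratified_split(labels, seed=1)
        assert set(train) | set(val) == set(labels.index)
        assert not set(train) & set(val)

    def test_seed_determinism(self):
        labels = pd.Series([0] * 10 + [1] * 10)
        assert ex.stratified_split(labels, seed=3) == ex.stratified_split(labels, seed=3)
        assert ex.stratified_split(labels, seed=3) != ex.stratified_split(labels, seed=4)

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError):
            ex.stratified_split(pd.Series([0, 1, 1]), seed=0)


class TestOneSePenalty:
    def test_flat_curve_picks_largest_penalty(self):
        alphas = np.logspace(-3, 3, 20)
        assert ex.one_se_penalty(alphas, np.ones(20), np.full(20, 0.1)) == alphas.max()

    def test_constructed_curve(self):
        alphas = np.array([0.1, 1.0, 10.0, 100.0])
        errors = np.array([0.30, 0.20, 0.24, 0.50])
        ses = np.array([0.02, 0.05, 0.04, 0.02])
        # bound = 0.20 + 0.05: alphas 1.0 and 10.0 qualify, largest wins
        assert ex.one_se_penalty(alphas, errors, ses) == 10.0


class TestRidgeFit:
    def test_ridge_path_matches_closed_form(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        alphas = np.array([0.01, 1.0, 50.0])
        B = _ridge_path(Z, y, alphas)
        Zc = Z - Z.mean(0)
        yc = y - y.mean()
        for a, b in zip(alphas, B):
            expected = np.linalg.solve(Zc.T @ Zc + a * np.eye(4), Zc.T @ yc)
            np.testing.assert_allclose(b, expected, atol=1e-8)

    def test_tiny_penalty_close_to_ols(self):
        rng = np.random.default_rng(1)
        n = 200
        X = rng.standard_normal((n, 3))
        beta_true = np.array([1.0, -2.0, 0.5])
        y = X @ beta_true + rng.normal(0, 0.05, n)
        y_bin = (y > np.median(y)).astype(float)
        fit = ex.fit_final_model(X, y_bin, folds=5, seed=2, alphas=np.array([1e-8]))
        A = np.column_stack([np.ones(n), X])
        ols = np.linalg.lstsq(A, y_bin, rcond=None)[0]
        got = np.array([fit.coefficients[f"x{i}"] for i in range(3)])
        np.testing.assert_allclose(got, ols[1:], rtol=0.05)

    def test_separating_predictor_gives_perfect_validation_auc(self):
        rng = np.random.default_rng(3)
        n = 120
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = np.column_stack([y * 4 + rng.normal(0, 0.1, n), rng.standard_normal(n)])
        val = np.arange(n) % 3 == 0  # both classes in each block
        fit = ex.fit_final_model(X[~val], y[~val], folds=5, seed=4)
        beta = np.array([fit.coefficients[f"x{i}"] for i in range(2)])
        val_scores = fit.intercept + X[val] @ beta
        assert ex.auc(val_scores, y[val]) == 1.0

    def test_constant_outcome_rejected(self):
        X = np.random.default_rng(0).standard_normal((40, 2))
        with pytest.raises(ValueError):
            ex.fit_final_model(X, np.ones(40))


class TestDelong:
    def test_equal_scores_no_difference(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        auc_a, auc_b, p = ex.delong_test(s, y, s.copy())
        assert auc_a == auc_b
        assert p == 1.0

    def test_two_by_two_variance_hand_enumeration(self):
        # cases {3, 1}, controls {2, 0}: placements V10 = (1, 1/2),
        # V01 = (1/2, 1); var = 0.125/2 + 0.125/2 = 0.125
        auc_, var = delong_auc_variance([3.0, 1.0, 2.0, 0.0], [1, 1, 0, 0])
        assert auc_ == pytest.approx(0.75)
        assert var == pytest.approx(0.125)

    def test_paired_p_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(6)
        n = 20
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        sa = y + rng.normal(0, 1.0, n)
        sb = y + rng.normal(0, 2.0, n)
        _, _, p = ex.delong_test(sa, y, sb)
        # bootstrap distribution of the AUC difference
        boots = []
        for _ in range(20000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            boots.append(ex.auc(sa[idx], y[idx]) - ex.auc(sb[idx], y[idx]))
        boots = np.array(boots)
        p_boot = 2 * min((boots <= 0).mean(), (boots >= 0).mean())
        assert p == pytest.approx(min(p_boot, 1.0), abs=0.05)

    def test_unpaired_null_behaviour(self):
        rng = np.random.default_rng(7)
        ya = np.r_[np.zeros(40), np.ones(40)].astype(int)
        sa = ya + rng.normal(0, 1, 80)
        yb = np.r_[np.zeros(40), np.ones(40)].astype(int)
        sb = yb + rng.normal(0, 1, 80)
        auc_a, auc_b, p = ex.delong_test(sa, ya, sb, yb)
        assert 0 < p <= 1
        assert auc_a == pytest.approx(ex.auc(sa, ya))
        assert auc_b == pytest.approx(ex.auc(sb, yb))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ex.delong_test([1.0, 2.0], [1, 1], [1.0, 2.0])


class TestCutoffs:
    def test_perfect_classifier_all_cutoffs_perfect(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        cs = ex.determine_cutoffs(scores, labels)
        for pre in ("bp", "fse", "fsp"):
            assert getattr(cs, f"{pre}_sens") == 1.0
            assert getattr(cs, f"{pre}_spec") == 1.0

    def test_cutoffs_reproduce_recorded_sens_spec_exactly(self):
        rng = np.random.default_rng(8)
        labels = np.r_[np.zeros(50), np.ones(50)].astype(int)
        scores = ex.link(labels * 1.2 + rng.normal(0, 1, 100))
        cs = ex.determine_cutoffs(scores, labels)
        from exclusig.evaluate import confusion_at

        for cut, se, sp in [
            (cs.bp_cut, cs.bp_sens, cs.bp_spec),
            (cs.fse_cut, cs.fse_sens, cs.fse_spec),
            (cs.fsp_cut, cs.fsp_sens, cs.fsp_spec),
        ]:
            tp, fp, tn, fn = confusion_at(scores, labels, cut)
            assert tp / (tp + fn) == se
            assert tn / (tn + fp) == sp

    def test_cutoff_ordering_when_attained(self):
        rng = np.random.default_rng(9)
        labels = np.r_[np.zeros(200), np.ones(200)].astype(int)
        scores = ex.link(labels * 2.0 + rng.normal(0, 1, 400))
        cs = ex.determine_cutoffs(scores, labels)
        assert cs.fse_cut <= cs.bp_cut <= cs.fsp_cut


class TestFinalModelPredict:
    def _model(self, cutoffs=None):
        return ex.FinalModel(
            proteins=("A", "B"),
            includes_age=False,
            coefficients={"A": 1.0, "B": -1.0},
            intercept=0.0,
            cutoffs=cutoffs
            or ex.CutoffSet(0.5, 1, 1, 0.3, 1, 1, True, 0.7, 1, 1, True),
        )

    def test_zero_linear_predictor_scores_half(self):
        m = self._model()
        out = m.predict(pd.DataFrame({"A": [2.0], "B": [2.0]}, index=["s"]))
        assert out.at["s", "score"] == pytest.approx(0.5)
        assert out.at["s", "class_at_bp"] == 1  # boundary is positive

    def test_log_three_gives_three_quarters(self):
        m = self._model()
        out = m.predict(pd.DataFrame({"A": [math.log(3)], "B": [0.0]}, index=["s"]))
        assert out.at["s", "score"] == pytest.approx(0.75)

    @given(st.floats(-30, 30))
    def test_link_symmetry(self, x):
        assert ex.link(x) + ex.link(-x) == pytest.approx(1.0, abs=1e-12)

    def test_score_monotone_in_positive_coefficient(self):
        m = self._model()
        vals = pd.DataFrame({"A": [0.0, 1.0, 2.0], "B": [1.0, 1.0, 1.0]})
        s = m.score(vals)
        assert s.is_monotonic_increasing

    def test_missing_protein_refused(self):
        m = self._model()
        with pytest.raises(KeyError):
            m.predict(pd.DataFrame({"A": [1.0]}))
        with pytest.raises(ValueError):
            m.predict(pd.DataFrame({"A": [1.0], "B": [np.nan]}))

    def test_model_card_round_trip(self, tmp_path):
        m = self._model()
        m.save(tmp_path / "model.json")
        back = ex.FinalModel.load(tmp_path / "model.json")
        assert back.to_dict() == m.to_dict()


class TestFixModelWorkflow:
    def test_end_to_end_on_separable_cohort(self):
        rng = np.random.default_rng(10)
        n = 60
        X0 = rng.standard_normal((n, 3))
        X1 = rng.standard_normal((n, 3)) + np.array([2.5, 2.0, 0.0])
        cohort = two_group_cohort(X0, X1, case_group="stageIII_IV")
        coding = ex.code_outcome(cohort, "benign_vs_III_IV")
        report = ex.fix_model(
            cohort, coding, cohort.proteins[:2], include_age=False, seed=0
        )
        assert report.validation_auc > 0.95
        assert report.delong_p > 0.01
        scores = report.model.score(cohort.matrix)
        assert ((scores > 0) & (scores < 1)).all()
        # recorded BP sens/spec reproduce exactly on the defining data
        from exclusig.evaluate import confusion_at

        tp, fp, tn, fn = confusion_at(
            scores.loc[coding.sample_ids], coding.y, report.model.cutoffs.bp_cut
        )
        assert tp / (tp + fn) == report.model.cutoffs.bp_sens
        assert tn / (tn + fp) == report.model.cutoffs.bp_spec
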