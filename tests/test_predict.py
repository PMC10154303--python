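"""Early-response prediction: eligibility, CV mechanics, evaluation metrics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tmsdecay import (
    PHQ9,
    ClassificationMetrics,
    CohortConfig,
    CVScheme,
    RatingSeries,
    ScaleSpec,
    crossval_predict,
    eligible_subjects,
    evaluate_categorical,
    evaluate_continuous,
    generate_cohort,
)
from tmsdecay.predict import PredictionResult

WIDE = ScaleSpec("WIDE", -100.0, 200.0, remission_cutoff=5)


def _mock_result(d0, c_pred, observed, scale=PHQ9):
    table = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(len(d0))],
            "d0": d0,
            "early_score": d0,
            "c_pred_unclamped": c_pred,
            "c_pred": c_pred,
            "observed_final": observed,
            "final_time": 6.0,
            "fold": 0,
            "fold_b": 1.2,
        }
    )
    return PredictionResult(
        table=table,
        fold_b=np.array([1.2]),
        t_early=1.0,
        scheme=CVScheme.kfold(5),
        scale=scale,
        n_eligible=len(d0),
    )


class TestEligibility:
    def test_complete_cohort_fully_eligible(self):
        cohort = generate_cohort(CohortConfig(seed=0, retention=1.0))
        assert len(eligible_subjects(cohort, 1.0)) == len(cohort)

    def test_subject_missing_early_visit_excluded(self):
        s_ok = RatingSeries("ok", [0, 1, 6], [20, 15, 9], PHQ9)
        s_gap = RatingSeries("gap", [0, 2, 6], [20, 15, 9], PHQ9)
        assert eligible_subjects([s_ok, s_gap], 1.0) == [s_ok]

    def test_subject_without_later_visit_excluded(self):
        s = RatingSeries("pair", [0, 1], [20, 15], PHQ9)
        assert eligible_subjects([s], 1.0) == []

    def test_eligible_counts_decrease_with_later_early_timepoint(self):
        counts_1, counts_2 = [], []
        for seed in range(20):
            cohort = generate_cohort(CohortConfig(seed=seed))
            counts_1.append(len(eligible_subjects(cohort, 1.0)))
            counts_2.append(len(eligible_subjects(cohort, 2.0)))
        assert np.mean(counts_2) < np.mean(counts_1)


class TestCrossval:
    def test_zero_noise_pipeline_recovers_each_subject(
        self, heterogeneous_noiseless_cohort
    ):
        """Noise-free limit: fold Bs equal the truth, predictions hit C."""
        res = crossval_predict(heterogeneous_noiseless_cohort, "kfold5", t_early=1.0)
        np.testing.assert_allclose(res.fold_b, 1.2, atol=1e-3)
        # predicted C equals each subject's latent floor (= final minus the
        # residual exp(-t_last/B) amplitude remnant, which is tiny)
        err = res.table["c_pred"] - res.table["observed_final"]
        assert np.max(np.abs(err)) < 0.2
        assert res.adjusted_r2() > 0.999
        assert res.classification_metrics().accuracy == 1.0

    def test_partition_every_eligible_subject_predicted_once(self, default_cohort):
        res = crossval_predict(default_cohort, "kfold5", t_early=1.0)
        ids = sorted(res.table["subject_id"])
        expected = sorted(s.subject_id for s in eligible_subjects(default_cohort, 1.0))
        assert ids == expected

    def test_schemes_agree_through_fold_time_constants(self, default_cohort):
        """Predictions differ across schemes only via fold-level B estimates."""
        res5 = crossval_predict(default_cohort, "kfold5", t_early=1.0)
        res10 = crossval_predict(default_cohort, "kfold10", t_early=1.0)
        loo = crossval_predict(default_cohort, "loo", t_early=1.0)
        merged = res5.table.merge(res10.table, on="subject_id").merge(
            loo.table, on="subject_id"
        )
        for a, b in (("c_pred_x", "c_pred_y"), ("c_pred_x", "c_pred")):
            r = np.corrcoef(merged[a], merged[b])[0, 1]
            assert r > 0.99
        # recompute one subject's prediction from its stored fold B
        from tmsdecay import predict_final

        row = res5.table.iloc[0]
        again = predict_final(row.d0, row.early_score, 1.0, row.fold_b, PHQ9)
        assert again.clamped == row.c_pred

    def test_loo_fold_b_less_variable_than_kfold(self):
        sds_k, sds_loo = [], []
        for seed in range(3):
            cohort = generate_cohort(CohortConfig(seed=seed))
            sds_k.append(crossval_predict(cohort, "kfold5", t_early=1.0).b_sd)
            sds_loo.append(crossval_predict(cohort, "loo", t_early=1.0).b_sd)
        assert np.mean(sds_loo) < np.mean(sds_k)

    def test_folds_partition_indices(self):
        for scheme in (CVScheme.kfold(5, seed=3), CVScheme.kfold(10, seed=1), CVScheme.loo()):
            folds = scheme.folds(23)
            flat = np.sort(np.concatenate(folds))
            np.testing.assert_array_equal(flat, np.arange(23))


class TestContinuousEvaluation:
    def test_perfect_predictions_give_r2_one(self):
        res = _mock_result([20, 22, 24], [2.0, 10.0, 18.0], [2.0, 10.0, 18.0])
        assert evaluate_continuous(res) == pytest.approx(1.0)

    def test_against_closed_form_ols_oracle(self):
        x = np.array([4.0, 10.0, 15.0, 7.0, 12.0])
        y = np.array([2.0, 10.0, 18.0, 9.0, 11.0])
        res = _mock_result([20] * 5, x, y)
        # independent oracle: textbook OLS R^2 and the n=2-regressor adjustment
        r = np.corrcoef(x, y)[0, 1]
        expected = 1 - (1 - r**2) * (len(x) - 1) / (len(x) - 2)
        assert evaluate_continuous(res) == pytest.approx(expected, abs=1e-12)

    def test_equal_signal_and_noise_variance_gives_half(self):
        """E[R^2] ~ 0.5 when predictions carry as much noise as signal."""
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(500):
            c = rng.normal(10, 3, size=60)
            obs = c + rng.normal(0, 3, size=60)
            vals.append(evaluate_continuous(_mock_result([20] * 60, c, obs, WIDE)))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_zero_variance_predictions_rejected(self):
        res = _mock_result([20, 20, 20], [5.0, 5.0, 5.0], [2.0, 10.0, 18.0])
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_continuous(res)


class TestCategoricalEvaluation:
    def test_perfect_predictions(self):
        d0 = [20.0, 20.0, 20.0, 20.0]
        finals = [5.0, 18.0, 9.0, 16.0]
        res = _mock_result(d0, finals, finals)
        m = evaluate_categorical(res)
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_constructed_confusion_table_arithmetic(self):
        m = ClassificationMetrics(tp=15, fn=7, fp=7, tn=32)
        assert m.accuracy == pytest.approx(47 / 61)
        assert m.ppv == pytest.approx(15 / 22)
        assert m.npv == pytest.approx(32 / 39)
        assert m.sensitivity == pytest.approx(15 / 22)
        assert m.specificity == pytest.approx(32 / 39)
        for v in (m.accuracy, m.sensitivity, m.specificity, m.npv, m.ppv):
            assert 0.0 <= v <= 1.0

    def test_empty_margin_reported_as_nan_not_zero(self):
        # no predicted responders: PPV undefined
        res = _mock_result([20.0, 20.0], [15.0, 18.0], [5.0, 18.0])
        m = evaluate_categorical(res)
        assert np.isnan(m.ppv)
        assert not np.isnan(m.npv)

    def test_baseline_at_scale_floor_excluded(self):
        res = _mock_result([0.0, 20.0], [0.0, 5.0], [0.0, 5.0])
        m = evaluate_categorical(res)
        assert m.n_excluded == 1
        assert m.n == 1

    def test_week_two_predictions_more_accurate_than_week_one(self):
        """Later early-response information should not hurt accuracy."""
        wins = ties = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cohort = generate_cohort(CohortConfig(seed=seed))
            acc1 = evaluate_categorical(
                crossval_predict(cohort, "kfold5", t_early=1.0)
            ).accuracy
            acc2 = evaluate_categorical(
                crossval_predict(cohort, "kfold5", t_early=2.0)
            ).accuracy
            wins += acc2 > acc1
            ties += acc2 == acc1
        assert wins + ties >= 0.6 * n_seeds
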