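"""LASSO clock training, zero-imputation prediction, and evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import regclock as rc
from regclock.errors import ValidationError
from regclock.quantitation import RegionMatrix


def _matrix(values: np.ndarray, ages, region_ids=None, sample_ids=None):
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    region_ids = region_ids or [f"1:{j * 100 + 1}:{j * 100 + 50}"
                                for j in range(p)]
    return RegionMatrix(
        pd.DataFrame(values, index=sample_ids, columns=region_ids),
        pd.Series(ages, index=sample_ids),
    )


class TestSplit:
    def test_holdout_is_floor_of_fraction(self, region_matrix):
        cfg = rc.TrainConfig(seed=0)
        train, holdout = rc.split_train_cv(region_matrix, cfg)
        n = region_matrix.n_samples
        assert holdout.n_samples == int(np.floor(0.1 * n))
        assert train.n_samples + holdout.n_samples == n
        assert not set(train.sample_ids) & set(holdout.sample_ids)

    def test_even_split(self):
        m = _matrix(np.full((10, 2), 0.5), np.arange(10, dtype=float))
        cfg = rc.TrainConfig(train_fraction=0.5, seed=0)
        train, holdout = rc.split_train_cv(m, cfg)
        assert train.n_samples == holdout.n_samples == 5

    def test_same_seed_same_partition(self, region_matrix):
        cfg = rc.TrainConfig(seed=42)
        t1, h1 = rc.split_train_cv(region_matrix, cfg)
        t2, h2 = rc.split_train_cv(region_matrix, cfg)
        assert t1.sample_ids == t2.sample_ids
        assert h1.sample_ids == h2.sample_ids

    def test_too_few_samples_rejected(self):
        m = _matrix(np.full((5, 2), 0.5), np.arange(5, dtype=float))
        with pytest.raises(ValidationError):
            rc.split_train_cv(m, rc.TrainConfig())


class TestTraining:
    def test_recovers_informative_regions(self, trained_clock, region_matrix,
                                          filtered_cohort):
        _, truth = filtered_cohort
        model, holdout = trained_clock
        informative = set(truth.clock_regions.ids)
        assert len(informative & set(model.terms)) >= 4
        pred = rc.predict_age(model, holdout)
        ev = rc.evaluate_predictions(pred.e_age, holdout.ages.to_numpy())
        assert ev.adj_r2 >= 0.9

    def test_huge_penalty_gives_intercept_only_mean_model(self, region_matrix):
        model = rc.train_lasso_clock(region_matrix, rc.TrainConfig(seed=0),
                                     alpha=1e6)
        assert model.terms == {}
        assert model.intercept == pytest.approx(
            region_matrix.ages.mean(), rel=1e-6)

    def test_zero_penalty_matches_ols(self, rng):
        n, p = 40, 4
        X = rng.uniform(0.1, 0.9, (n, p))
        beta = np.array([10.0, -5.0, 3.0, 0.5])
        y = 2.0 + X @ beta
        m = _matrix(X, y)
        model = rc.train_lasso_clock(m, rc.TrainConfig(seed=0), alpha=0.0)
        # closed-form least squares oracle
        A = np.column_stack([np.ones(n), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert model.intercept == pytest.approx(coef[0], abs=1e-6)
        got = np.array([model.terms.get(rid, 0.0) for rid in m.region_ids])
        assert got == pytest.approx(coef[1:], abs=1e-6)

    def test_nan_regions_dropped_before_fit(self, rng):
        X = rng.uniform(0.2, 0.8, (30, 3))
        ages = np.linspace(3, 30, 30)
        X[:, 0] = 0.2 + 0.02 * ages  # informative
        X[4, 2] = np.nan
        m = _matrix(X, ages)
        model = rc.train_lasso_clock(m, rc.TrainConfig(seed=0, cv_folds=10))
        assert m.region_ids[2] not in model.terms

    def test_constant_age_rejected(self):
        m = _matrix(np.random.default_rng(0).uniform(0, 1, (12, 3)),
                    np.full(12, 5.0))
        with pytest.raises(ValidationError):
            rc.train_lasso_clock(m, rc.TrainConfig())

    def test_all_missing_features_rejected(self):
        m = _matrix(np.full((12, 2), np.nan), np.arange(12, dtype=float))
        with pytest.raises(ValidationError):
            rc.train_lasso_clock(m, rc.TrainConfig())

    def test_training_reproducible_under_seed(self, region_matrix):
        cfg = rc.TrainConfig(seed=7)
        m1 = rc.train_lasso_clock(region_matrix, cfg)
        m2 = rc.train_lasso_clock(region_matrix, cfg)
        assert m1.intercept == m2.intercept
        assert m1.terms == m2.terms


class TestPrediction:
    def test_direct_formula(self):
        model = rc.ClockModel(intercept=5.0, terms={"1:1:10": 10.0})
        m = _matrix(np.array([[0.4]]), [7.0], region_ids=["1:1:10"])
        assert rc.predict_age(model, m).e_age[0] == pytest.approx(9.0)

    def test_signed_sum(self):
        model = rc.ClockModel(intercept=10.0,
                              terms={"1:1:10": 12.0, "1:20:30": -6.0})
        m = _matrix(np.array([[0.5, 0.5]]), [7.0],
                    region_ids=["1:1:10", "1:20:30"])
        assert rc.predict_age(model, m).e_age[0] == pytest.approx(13.0)

    def test_fully_missing_sample_predicts_intercept(self):
        model = rc.ClockModel(intercept=34.16,
                              terms={"1:1:10": 2.0, "2:5:9": -1.0})
        m = _matrix(np.array([[np.nan, np.nan]]), [7.0],
                    region_ids=["1:1:10", "2:5:9"])
        pred = rc.predict_age(model, m)
        assert pred.e_age[0] == pytest.approx(34.16)
        assert pred.n_imputed[0] == 2

    def test_absent_model_region_imputes_zero(self):
        model = rc.ClockModel(intercept=1.0,
                              terms={"1:1:10": 5.0, "9:1:10": 100.0})
        m = _matrix(np.array([[0.2]]), [7.0], region_ids=["1:1:10"])
        pred = rc.predict_age(model, m)
        assert pred.e_age[0] == pytest.approx(2.0)
        assert pred.n_imputed[0] == 1

    @given(st.integers(0, 2**31 - 1))
    def test_zero_imputation_equals_zero_substitution(self, seed):
        r = np.random.default_rng(seed)
        X = r.uniform(0, 1, (8, 4))
        X[r.random((8, 4)) < 0.3] = np.nan
        ids = [f"1:{j * 10 + 1}:{j * 10 + 5}" for j in range(4)]
        model = rc.ClockModel(intercept=3.0,
                              terms=dict(zip(ids, r.normal(size=4))))
        m_nan = _matrix(X, np.arange(8, dtype=float), region_ids=ids)
        m_zero = _matrix(np.nan_to_num(X), np.arange(8, dtype=float),
                         region_ids=ids)
        np.testing.assert_allclose(rc.predict_age(model, m_nan).e_age,
                                   rc.predict_age(model, m_zero).e_age)


class TestEvaluation:
    def test_adjusted_r2_formula(self):
        # residuals orthogonal to span{1, chron} scaled so the pred~chron
        # fit has R^2 exactly 0.9; with N=12, k=1 the adjustment gives 0.89
        rng = np.random.default_rng(3)
        chron = np.linspace(1, 30, 12)
        v = rng.normal(size=12)
        A = np.column_stack([np.ones(12), chron])
        e = v - A @ np.linalg.lstsq(A, v, rcond=None)[0]
        ss_chron = np.sum((chron - chron.mean()) ** 2)
        e *= np.sqrt(ss_chron / 9) / np.linalg.norm(e)  # SS_res = SS_tot/10
        ev = rc.evaluate_predictions(chron + e, chron)
        assert ev.adj_r2 == pytest.approx(0.89, abs=1e-9)

    def test_perfect_prediction(self):
        x = np.array([1.0, 5.0, 9.0, 20.0])
        ev = rc.evaluate_predictions(x, x)
        assert ev.adj_r2 == pytest.approx(1.0)
        assert ev.mae_months == 0.0

    def test_mae_is_median(self):
        ev = rc.evaluate_predictions(np.array([10.0, 12.0, 20.0]),
                                     np.array([11.0, 12.0, 15.0]), k=1)
        assert ev.mae_months == pytest.approx(1.0)

    def test_adj_r2_never_exceeds_r2(self, rng):
        chron = rng.uniform(3, 30, 25)
        pred = chron + rng.normal(0, 4, 25)
        from scipy.stats import linregress
        r2 = linregress(chron, pred).rvalue ** 2
        ev = rc.evaluate_predictions(pred, chron)
        assert ev.adj_r2 <= r2 < 1

    @pytest.mark.parametrize("pred,chron", [
        ([1, 2], [1, 2, 3]),          # length mismatch
        ([1, 2, 3], [1, 2, 3]),       # n == k+2 ok; see below
    ])
    def test_length_mismatch_rejected(self, pred, chron):
        if len(pred) != len(chron):
            with pytest.raises(ValidationError):
                rc.evaluate_predictions(np.array(pred, dtype=float),
                                        np.array(chron, dtype=float))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            rc.evaluate_predictions(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestGroupComparison:
    def test_identical_groups_null(self):
        vals = np.array([-1.0, 0.0, 1.0, 2.0, -2.0])
        res = rc.compare_groups(vals, vals)
        assert res.median_error == 0.0
        assert res.p_value > 0.9

    def test_shift_detected(self, rng):
        control = rng.normal(0, 1, 20)
        treated = rng.normal(-3, 1, 20)
        res = rc.compare_groups(treated, control)
        assert res.p_value < 0.05
        assert res.median_error < -2

    def test_median_error_reported(self):
        res = rc.compare_groups(np.array([-2.0, -1.0, -3.0]),
                                np.array([0.0, 1.0, -1.0]))
        assert res.median_error == pytest.approx(-2.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rc.compare_groups(np.array([]), np.array([1.0]))
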