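"""PLS/LOOCV statistics: q2, PRESS, component selection, contributions."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from comsia.pls import (
    CvCurve,
    QsarModel,
    evaluate_test,
    field_contributions,
    fit_final,
    loocv,
    predict,
    select_components,
)
from comsia.preprocess import ColumnMeta, FeatureMatrix


def make_fm(X, y, roles=None, activities=None, field_names=None):
    """FeatureMatrix around a preprocessed (centered) design matrix."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    roles = roles or ["train"] * X.shape[0]
    n_train = sum(r == "train" for r in roles)
    y_mean = float(y[:n_train].mean())
    Xc = X - X[:n_train].mean(axis=0)
    fields = field_names or ["S"] * X.shape[1]
    cols = [
        ColumnMeta(f, j, True, 0.0, float(X[:, j].std()))
        for j, f in enumerate(fields)
    ]
    acts = activities if activities is not None else list(y) + [None] * (X.shape[0] - len(y))
    return FeatureMatrix(
        X=Xc,
        y=y[:n_train] - y_mean,
        y_mean=y_mean,
        columns=cols,
        row_names=[f"m{i}" for i in range(X.shape[0])],
        roles=roles,
        activities=acts,
    )


def rank_one_problem(n=12, p=6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    t = rng.normal(size=n)
    loadings = rng.normal(size=p)
    X = np.outer(t, loadings)
    y = 2.0 * t + 5.0 + noise * rng.normal(size=n)
    return X, y


class TestLoocv:
    def test_noiseless_one_latent_variable_gives_q2_of_one(self):
        X, y = rank_one_problem()
        curve = loocv(make_fm(X, y), max_components=1)
        assert curve.q2[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_per_fold_refit_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(8, 10))
        y = rng.normal(size=8)
        fm = make_fm(X, y)
        curve = loocv(fm, max_components=3)
        n = 8
        ssy = float(np.sum(fm.y ** 2))
        for ki, k in enumerate((1, 2, 3)):
            press = 0.0
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                est = PLSRegression(n_components=k, scale=False)
                est.fit(fm.X[mask], fm.y[mask].reshape(-1, 1))
                press += (fm.y[i] - float(est.predict(fm.X[i:i + 1])[0, 0])) ** 2
            assert curve.press[ki] == pytest.approx(press, abs=1e-10)
            assert curve.q2[ki] == pytest.approx(1 - press / ssy, abs=1e-10)
            assert curve.s_press[ki] == pytest.approx(
                np.sqrt(press / (n - k - 1)), abs=1e-10
            )

    def test_excessive_components_truncated_with_warning(self):
        X, y = rank_one_problem(n=6)
        with pytest.warns(UserWarning, match="truncat"):
            curve = loocv(make_fm(X, y), max_components=10)
        assert curve.components[-1] == 4  # n - 2

    def test_constant_activity_rejected(self):
        X, _ = rank_one_problem(n=6)
        with pytest.raises(ValueError, match="constant"):
            loocv(make_fm(X, np.full(6, 3.0)), max_components=2)


class TestSelectComponents:
    @pytest.mark.parametrize(
        "q2s, expect",
        [([0.3, 0.6, 0.55], 2), ([0.5, 0.5], 1), ([0.4], 1)],
    )
    def test_argmax_with_parsimony_ties(self, q2s, expect):
        curve = CvCurve(list(range(1, len(q2s) + 1)), [0.0] * len(q2s), q2s, [0.0] * len(q2s))
        assert select_components(curve) == expect

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            select_components(CvCurve([], [], [], []))


class TestFitFinal:
    def test_training_residual_mean_is_zero(self):
        X, y = rank_one_problem(n=10, noise=0.3)
        fm = make_fm(X, y)
        model = fit_final(fm, 1)
        residuals = fm.raw_activities("train") - predict(model, fm.X_train)
        assert residuals.mean() == pytest.approx(0.0, abs=1e-10)

    def test_full_rank_noiseless_system_fits_exactly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 5))
        beta = rng.normal(size=5)
        y = X @ beta + 3.0
        model = fit_final(make_fm(X, y), 5)
        assert model.metrics["r2_train"] == pytest.approx(1.0, abs=1e-8)

    def test_q2_not_above_r2_train(self, small_feature_matrix):
        fm, _ = small_feature_matrix
        curve = loocv(fm, max_components=4)
        for k in curve.components:
            model = fit_final(fm, k)
            assert curve.q2[k - 1] <= model.metrics["r2_train"] + 1e-10

    def test_coefficients_permute_with_columns(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        perm = np.array([3, 1, 4, 0, 2])
        m1 = fit_final(make_fm(X, y), 2)
        m2 = fit_final(make_fm(X[:, perm], y), 2)
        assert np.allclose(m2.coefficients, m1.coefficients[perm], atol=1e-10)


class TestPredictAndEvaluate:
    def test_mean_feature_row_predicts_training_mean(self):
        X, y = rank_one_problem(n=10, noise=0.2)
        fm = make_fm(X, y)
        model = fit_final(fm, 1)
        assert predict(model, np.zeros((1, X.shape[1])))[0] == pytest.approx(fm.y_mean)

    def test_duplicate_training_row_gets_fitted_value(self):
        X, y = rank_one_problem(n=10, noise=0.2)
        fm = make_fm(X, y)
        model = fit_final(fm, 1)
        fitted = predict(model, fm.X_train)
        assert predict(model, fm.X_train[4:5])[0] == pytest.approx(fitted[4])

    def test_column_count_mismatch_rejected(self):
        X, y = rank_one_problem()
        model = fit_final(make_fm(X, y), 1)
        with pytest.raises(ValueError, match="mismatch"):
            predict(model, np.zeros((1, 3)))

    def test_r2_pred_limits(self):
        X, y = rank_one_problem(n=16, noise=0.0)
        roles = ["train"] * 10 + ["test"] * 6
        fm = make_fm(X, y[:10], roles=roles, activities=list(y))
        model = fit_final(fm, 1)
        # noiseless rank-one system extrapolates exactly: r2_pred -> 1
        metrics = evaluate_test(model, fm)
        assert metrics["r2_pred"] == pytest.approx(1.0, abs=1e-6)
        # predicting the training mean for every test row gives r2_pred = 0
        yhat_mean = np.full(6, fm.y_mean)
        y_test = fm.raw_activities("test")
        sse = np.sum((y_test - yhat_mean) ** 2)
        ss0 = np.sum((y_test - fm.y_mean) ** 2)
        assert 1 - sse / ss0 == pytest.approx(0.0, abs=1e-12)

    def test_empty_test_set_yields_no_metrics(self):
        X, y = rank_one_problem()
        fm = make_fm(X, y)
        model = fit_final(fm, 1)
        assert evaluate_test(model, fm) == {}


class TestFieldContributions:
    def _model(self, coefs, fields, stds):
        cols = [ColumnMeta(f, j, True, 0.0, s) for j, (f, s) in enumerate(zip(fields, stds))]
        return QsarModel(
            n_components=1, coefficients=np.array(coefs), y_mean=0.0, columns=cols
        )

    def test_single_field_gets_everything(self):
        m = self._model([1.0, -2.0], ["S", "S"], [1.0, 1.0])
        assert field_contributions(m) == {"S": 1.0}

    def test_symmetric_fields_split_evenly(self):
        m = self._model([1.0, -1.0], ["S", "E"], [0.7, 0.7])
        contrib = field_contributions(m)
        assert contrib["S"] == pytest.approx(0.5)
        assert contrib["E"] == pytest.approx(0.5)

    def test_zero_coefficient_field_contributes_nothing(self):
        m = self._model([0.0, 2.0], ["S", "E"], [1.0, 1.0])
        contrib = field_contributions(m)
        assert contrib["S"] == 0.0 and contrib["E"] == 1.0

    def test_fractions_sum_to_one(self, small_feature_matrix):
        fm, _ = small_feature_matrix
        model = fit_final(fm, 2)
        assert sum(model.field_contributions.values()) == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_consistent_block_rescaling(self):
        # doubling a field's column stds while halving its coefficients
        # leaves every contribution unchanged
        m1 = self._model([1.0, 0.5, -2.0], ["S", "S", "E"], [1.0, 2.0, 0.5])
        m2 = self._model([0.5, 0.25, -2.0], ["S", "S", "E"], [2.0, 4.0, 0.5])
        c1, c2 = field_contributions(m1), field_contributions(m2)
        for f in c1:
            assert c1[f] == pytest.approx(c2[f], abs=1e-12)
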