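"""PLS regression, LOOCV component selection, and all reported statistics.

The latent-variable fit itself is scikit-learn's PLSRegression (NIPALS); this
module owns the cross-validation protocol and every metric convention:

  PRESS(k)   = sum_i (y_i - yhat_{-i})^2 over leave-one-out folds
  q^2(k)     = 1 - PRESS(k) / sum_i (y_i - ybar)^2
  S_PRESS(k) = sqrt(PRESS(k) / (n - k - 1))
  r^2_train  = 1 - SSE/SSY,   S = sqrt(SSE / (n - k - 1))
  r^2_pred   = 1 - sum(y_test - yhat)^2 / sum(y_test - ybar_train)^2

The feature-matrix preprocessing statistics (block scaling, column centering)
are computed once and reused across LOOCV folds; a strict mode that recenters
the fold's design matrix is available for comparison.  The optimal component
count maximizes q^2, ties broken toward fewer components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .preprocess import ColumnMeta, FeatureMatrix

__all__ = [
    "CvCurve",
    "QsarModel",
    "loocv",
    "select_components",
    "fit_final",
    "evaluate_test",
    "field_contributions",
    "predict",
]


@dataclass
class CvCurve:
    components: list[int]
    press: list[float]
    q2: list[float]
    s_press: list[float]

    def as_rows(self) -> list[tuple[int, float, float, float]]:
        return list(zip(self.components, self.press, self.q2, self.s_press))


@dataclass
class QsarModel:
    n_components: int
    coefficients: np.ndarray           # per kept column, centered/scaled space
    y_mean: float
    columns: list[ColumnMeta]
    metrics: dict = dc_field(default_factory=dict)
    field_contributions: dict = dc_field(default_factory=dict)
    _estimator: PLSRegression | None = None


def _fit_pls(X: np.ndarray, y: np.ndarray, k: int) -> PLSRegression:
    est = PLSRegression(n_components=k, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on low-rank deflation
        est.fit(X, y.reshape(-1, 1))
    return est


def max_usable_components(n_train: int, n_features: int, cap: int = 10) -> int:
    return max(1, min(cap, n_train - 2, n_features))


def loocv(
    fm: FeatureMatrix,
    max_components: int | None = None,
    strict_refit: bool = False,
) -> CvCurve:
    """Leave-one-out cross-validation curve over component counts 1..max.

    With ``strict_refit`` the fold's design matrix is re-centered on the n-1
    retained rows before fitting; by default the preprocessing statistics of
    the full training matrix are reused, and only the PLS fit is repeated.
    """
    X, y = fm.X_train, fm.y
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 training molecules")
    kmax = max_usable_components(n, X.shape[1]) if max_components is None else max_components
    hard_cap = min(n - 2, X.shape[1])
    if kmax > hard_cap:
        warnings.warn(
            f"max_components {kmax} exceeds usable rank; truncating to {hard_cap}"
        )
        kmax = hard_cap
    ssy = float(np.sum(y ** 2))  # y is training-mean centered
    if ssy == 0:
        raise ValueError("training activities are constant; q^2 undefined")
    components, press_list, q2_list, s_press_list = [], [], [], []
    for k in range(1, kmax + 1):
        press = 0.0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            X_fit, y_fit = X[mask], y[mask]
            X_out = X[i:i + 1]
            if strict_refit:
                mu = X_fit.mean(axis=0)
                ybar = y_fit.mean()
                est = _fit_pls(X_fit - mu, y_fit - ybar, k)
                pred = float(est.predict(X_out - mu)[0, 0]) + ybar
            else:
                est = _fit_pls(X_fit, y_fit, k)
                pred = float(est.predict(X_out)[0, 0])
            press += (float(y[i]) - pred) ** 2
        components.append(k)
        press_list.append(press)
        q2_list.append(1.0 - press / ssy)
        denom = n - k - 1
        s_press_list.append(float(np.sqrt(press / denom)) if denom > 0 else float("nan"))
    return CvCurve(components, press_list, q2_list, s_press_list)


def select_components(curve: CvCurve) -> int:
    """Component count maximizing q^2; ties go to the smaller count."""
    if not curve.components:
        raise ValueError("empty cross-validation curve")
    best = curve.components[0]
    best_q2 = curve.q2[0]
    for k, q2 in zip(curve.components, curve.q2):
        if q2 > best_q2 + 1e-12:
            best, best_q2 = k, q2
    return best


def fit_final(fm: FeatureMatrix, k: int) -> QsarModel:
    """Fit the final model with k latent variables on the training rows."""
    X, y = fm.X_train, fm.y
    n = X.shape[0]
    if k < 1:
        raise ValueError("n_components must be >= 1")
    usable = min(n - 1, X.shape[1])
    if k > usable:
        warnings.warn(f"rank-deficient system; fitting {usable} components instead of {k}")
        k = usable
    est = _fit_pls(X, y, k)
    coef = np.asarray(est.coef_).reshape(-1)
    fitted = est.predict(X).ravel() + fm.y_mean
    y_raw = y + fm.y_mean
    sse = float(np.sum((y_raw - fitted) ** 2))
    ssy = float(np.sum(y ** 2))
    r2_train = 1.0 - sse / ssy
    denom = n - k - 1
    s_train = float(np.sqrt(sse / denom)) if denom > 0 else float(np.sqrt(sse / n))
    model = QsarModel(
        n_components=k,
        coefficients=coef,
        y_mean=fm.y_mean,
        columns=fm.kept_columns,
        metrics={"r2_train": r2_train, "s_train": s_train},
        _estimator=est,
    )
    model.field_contributions = field_contributions(model)
    return model


def predict(model: QsarModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted activities, original units, for preprocessed feature rows."""
    X_new = np.atleast_2d(X_new)
    if X_new.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"feature count mismatch: model has {model.coefficients.shape[0]} "
            f"columns, input has {X_new.shape[1]}"
        )
    return model._estimator.predict(X_new).ravel() + model.y_mean


def evaluate_test(model: QsarModel, fm: FeatureMatrix, role: str = "test") -> dict:
    """Predictive statistics on held-out rows transformed with training stats.

    r^2_pred benchmarks predictions against the training-mean predictor;
    s_test uses the (n_test - k - 1) denominator when positive, else RMSE.
    """
    X_test = fm.rows(role)
    if X_test.shape[0] == 0:
        return {}
    y_test = fm.raw_activities(role)
    yhat = predict(model, X_test)
    sse = float(np.sum((y_test - yhat) ** 2))
    ss_about_train_mean = float(np.sum((y_test - fm.y_mean) ** 2))
    r2_pred = 1.0 - sse / ss_about_train_mean
    denom = len(y_test) - model.n_components - 1
    s_test = float(np.sqrt(sse / denom)) if denom > 0 else float(np.sqrt(sse / len(y_test)))
    return {"r2_pred": r2_pred, "s_test": s_test}


def field_contributions(model: QsarModel) -> dict[str, float]:
    """Fraction of |coefficient x scaled-column std| mass per field; sums to 1."""
    mass: dict[str, float] = {}
    for b, col in zip(model.coefficients, model.columns):
        mass[col.field_name] = mass.get(col.field_name, 0.0) + abs(b * col.scale_std)
    total = sum(mass.values())
    if total == 0:
        return {f: 0.0 for f in mass}
    return {f: v / total for f, v in mass.items()}
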