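"""PLS calibration and the Rc/SEC/Rp/SEP workflow.

:class:`PLS1Regression` is a NIPALS PLS1 written from first principles
(scores t = X w from the dominant covariance direction, rank-one
deflation of X, regression coefficients recovered through
W (P' W)^-1 q).  Calibration quality is summarised the chemometric way:
Rc/Rp are the Pearson correlations between observed and fitted
concentrations on the calibration and prediction sets, SEC/SEP the
corresponding root mean squared residuals (population form, divisor n).

Two study workflows sit on top: ranking the eight preprocessing
schemes on a shared calibration/prediction split, and comparing a
full-spectrum model against one restricted to the characteristic
bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted, validate_data

from .preprocess import PreprocessMethod, SGFilterSpec, make_transformer
from .spectra import SpectraMatrix

__all__ = [
    "PLS1Regression",
    "CalibMetrics",
    "pls_fit",
    "pls_predict",
    "calib_metrics",
    "compare_preprocessing",
    "compare_bands",
]


class PLS1Regression(RegressorMixin, BaseEstimator):
    """NIPALS partial least squares with a single response.

    Predictors are centred (and optionally unit-scaled) with training
    statistics.  For PLS1 each NIPALS iteration is closed-form: the
    weight vector is the normalised covariance X'y, so the algorithm is
    deterministic given input order.

    Attributes
    ----------
    coef_ : (p,) regression coefficients on the original predictor scale
    intercept_ : float
    x_weights_, x_loadings_ : (p, k) per-component weight/loading vectors
    x_scores_ : (n, k) training scores
    y_loadings_ : (k,)
    """

    def __init__(self, n_components: int = 5, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True, ensure_min_samples=2)
        y = y.astype(float)
        if np.ptp(y) == 0:
            raise ValueError("y is constant; PLS undefined")
        n, p = X.shape
        k = self.n_components
        if k < 1 or k > min(n - 1, p):
            raise ValueError(
                f"n_components={k} outside [1, {min(n - 1, p)}] for {n}x{p} data")

        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        self.x_std_ = np.where(self.x_std_ == 0, 1.0, self.x_std_)
        self.y_mean_ = y.mean()

        E = (X - self.x_mean_) / self.x_std_
        f = y - self.y_mean_

        W = np.zeros((p, k))
        P = np.zeros((p, k))
        T = np.zeros((n, k))
        q = np.zeros(k)
        for a in range(k):
            w = E.T @ f
            nw = np.linalg.norm(w)
            if nw == 0:
                # residual X orthogonal to y: truncate
                k = a
                W, P, T, q = W[:, :k], P[:, :k], T[:, :k], q[:k]
                warnings.warn(f"PLS truncated to {k} components (no covariance left)")
                break
            w /= nw
            t = E @ w
            tt = t @ t
            if tt == 0:
                k = a
                W, P, T, q = W[:, :k], P[:, :k], T[:, :k], q[:k]
                warnings.warn(f"PLS truncated to {k} components (zero score)")
                break
            pvec = E.T @ t / tt
            qa = f @ t / tt
            E = E - np.outer(t, pvec)
            f = f - qa * t
            W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa

        self.n_components_ = k
        self.x_weights_, self.x_loadings_, self.x_scores_ = W, P, T
        self.y_loadings_ = q
        beta = W @ np.linalg.solve(P.T @ W, q) if k else np.zeros(p)
        self.coef_ = beta / self.x_std_
        self.intercept_ = float(self.y_mean_ - self.x_mean_ @ self.coef_)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X @ self.coef_ + self.intercept_


def pls_fit(X, y, n_components: int = 5) -> PLS1Regression:
    """Functional wrapper: fitted :class:`PLS1Regression`."""
    X = X.values if isinstance(X, SpectraMatrix) else X
    return PLS1Regression(n_components=n_components).fit(X, y)


def pls_predict(model: PLS1Regression, X) -> np.ndarray:
    X = X.values if isinstance(X, SpectraMatrix) else X
    return model.predict(X)


@dataclass
class CalibMetrics:
    """Calibration (Rc, SEC) and prediction (Rp, SEP) quality."""

    Rc: float
    SEC: float
    Rp: float
    SEP: float

    def as_dict(self) -> dict:
        return {"Rc": self.Rc, "SEC": self.SEC, "Rp": self.Rp, "SEP": self.SEP}


def _pearson(y, yhat) -> float:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        warnings.warn("degenerate (constant) vector; correlation reported as 0")
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1])


def _se(y, yhat) -> float:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def calib_metrics(y_cal, yhat_cal, y_pred, yhat_pred) -> CalibMetrics:
    """Rc/SEC on the calibration pair, Rp/SEP on the prediction pair.

    Standard errors use the population divisor n (switch to a
    dof-corrected form by post-scaling if needed).
    """
    for a, b in ((y_cal, yhat_cal), (y_pred, yhat_pred)):
        a, b = np.asarray(a), np.asarray(b)
        if a.shape != b.shape:
            raise ValueError("paired vectors must have equal length")
        if a.size < 2:
            raise ValueError("need >= 2 points per set")
    return CalibMetrics(Rc=_pearson(y_cal, yhat_cal), SEC=_se(y_cal, yhat_cal),
                        Rp=_pearson(y_pred, yhat_pred), SEP=_se(y_pred, yhat_pred))


def _split(n: int, test_fraction: float, seed: int):
    idx = np.arange(n)
    cal, pred = train_test_split(idx, test_size=test_fraction, random_state=seed)
    return np.sort(cal), np.sort(pred)


def _fit_eval(Xc, yc, Xp, yp, n_components: int) -> CalibMetrics:
    k = min(n_components, Xc.shape[0] - 1, Xc.shape[1])
    model = PLS1Regression(n_components=k).fit(Xc, yc)
    return calib_metrics(yc, model.predict(Xc), yp, model.predict(Xp))


def compare_preprocessing(M_raw: SpectraMatrix, y,
                          methods=tuple(PreprocessMethod),
                          test_fraction: float = 0.2, seed: int = 0,
                          sg: SGFilterSpec = SGFilterSpec(),
                          n_components: int = 5) -> pd.DataFrame:
    """PLS metrics per preprocessing scheme on one shared 8:2 split.

    Each transformer is fitted on the calibration rows only and applied
    to both sets, so data-dependent schemes (MSC, mean centering) see
    no prediction-set information.  Rows are sorted by Rp, best first.
    """
    methods = [PreprocessMethod(m) for m in methods]
    if len(methods) < 1:
        raise ValueError("need at least one method")
    y = np.asarray(y, float)
    cal, pred = _split(M_raw.n_samples, test_fraction, seed)
    rows = []
    for m in methods:
        tr = make_transformer(m, sg)
        Xc = tr.fit_transform(M_raw.values[cal])
        Xp = tr.transform(M_raw.values[pred])
        met = _fit_eval(Xc, y[cal], Xp, y[pred], n_components)
        rows.append({"method": m.value, **met.as_dict()})
    return (pd.DataFrame(rows)
            .sort_values("Rp", ascending=False)
            .reset_index(drop=True))


def compare_bands(M: SpectraMatrix, y, bands,
                  test_fraction: float = 0.2, seed: int = 0,
                  n_components: int = 5) -> pd.DataFrame:
    """Full-spectrum vs characteristic-band PLS on one shared split."""
    bands = list(bands)
    if not bands:
        raise ValueError("bands must be non-empty")
    cols = np.array([M.band_index(b) for b in bands])
    y = np.asarray(y, float)
    cal, pred = _split(M.n_samples, test_fraction, seed)
    full = _fit_eval(M.values[cal], y[cal], M.values[pred], y[pred], n_components)
    sub = _fit_eval(M.values[np.ix_(cal, cols)], y[cal],
                    M.values[np.ix_(pred, cols)], y[pred], n_components)
    return pd.DataFrame([
        {"model": "full_band", "n_wavelengths": M.n_wavelengths, **full.as_dict()},
        {"model": "characteristic_band", "n_wavelengths": len(cols), **sub.as_dict()},
    ])
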