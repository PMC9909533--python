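"""The eight spectral preprocessing schemes used to condition reflectance
data before calibration: raw pass-through, per-spectrum min-max
normalization, multiplicative scatter correction (MSC), plain first
derivative, Savitzky-Golay (SG) convolution smoothing, SG first and
second convolution derivatives, and column mean-centering.

The SG filter is built from first principles: a window of half-width m
holds 2m+1 points fitted by a degree-`poly_order` polynomial in the
offsets x = (-m..m); the least-squares fit is the orthogonal projection
B = X (X'X)^-1 X' onto the polynomial span, and the smoothed value at
the window centre is the centre row of B dotted with the window.
Derivative filters evaluate the fitted polynomial's derivative at the
centre instead.

Each scheme is exposed both as a scikit-learn transformer (for use in
pipelines and model selection) and as a function on
:class:`~leafspec.spectra.SpectraMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from math import factorial

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .spectra import Spectrum, SpectraMatrix

__all__ = [
    "SGFilterSpec",
    "PreprocessMethod",
    "minmax_normalize",
    "sg_filter_matrix",
    "sg_center_coefficients",
    "sg_smooth",
    "derivative",
    "msc_correct",
    "mean_center",
    "apply_method",
    "RowMinMaxScaler",
    "SavitzkyGolaySmoother",
    "FiniteDifferenceDerivative",
    "MultiplicativeScatterCorrection",
    "MeanCenterer",
]


@dataclass(frozen=True)
class SGFilterSpec:
    """SG window: n = 2*half_width + 1 points, polynomial degree poly_order.

    The window must overdetermine the fit: n >= poly_order + 2, i.e. the
    point count strictly exceeds the number of polynomial coefficients.
    """

    half_width: int = 5
    poly_order: int = 3

    @property
    def window(self) -> int:
        return 2 * self.half_width + 1

    def validate(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if self.window <= self.poly_order + 1:
            raise ValueError(
                f"window {self.window} must exceed the {self.poly_order + 1} "
                "polynomial coefficients")


class PreprocessMethod(str, Enum):
    """The eight preprocessing schemes compared by the calibration study."""

    raw = "raw"
    standard_normalization = "standard_normalization"
    msc = "msc"
    first_derivative = "first_derivative"
    sg_first_derivative = "sg_first_derivative"
    sg_second_derivative = "sg_second_derivative"
    sg_smoothing = "sg_smoothing"
    mean_center = "mean_center"


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map a vector to [0, 1]: y_i = (x_i - min) / (max - min).

    Raises on constant input, where the mapping is undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant vector: min-max normalization undefined")
    return (x - lo) / (hi - lo)


def _sg_design(spec: SGFilterSpec) -> np.ndarray:
    m = spec.half_width
    x = np.arange(-m, m + 1, dtype=float)
    return np.vander(x, spec.poly_order + 1, increasing=True)


def sg_filter_matrix(spec: SGFilterSpec) -> np.ndarray:
    """The (2m+1)x(2m+1) projection B = X (X'X)^-1 X' onto the window's
    polynomial span; symmetric, idempotent, and exact on polynomials up
    to `poly_order`."""
    spec.validate()
    X = _sg_design(spec)
    return X @ np.linalg.solve(X.T @ X, X.T)


def sg_center_coefficients(spec: SGFilterSpec, deriv: int = 0,
                           step: float = 1.0) -> np.ndarray:
    """Convolution weights giving the fitted value (deriv=0) or the
    d-th derivative of the fitted polynomial, evaluated at the window
    centre, per unit `step` of the abscissa."""
    spec.validate()
    if deriv > spec.poly_order:
        raise ValueError("derivative order exceeds polynomial order")
    X = _sg_design(spec)
    # rows of (X'X)^-1 X' are the polynomial-coefficient extractors;
    # d-th derivative at x=0 is d! * a_d
    coef_rows = np.linalg.solve(X.T @ X, X.T)
    return coef_rows[deriv] * factorial(deriv) / step ** deriv


def _sliding_apply(values: np.ndarray, weights: np.ndarray,
                   edge: str = "copy") -> np.ndarray:
    """Apply centre-row weights over sliding windows of each row.

    edge='copy' leaves the first/last m points untouched (used for
    smoothing); edge='nearest' repeats the nearest interior result
    (used for derivatives, whose units differ from the signal's).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m = (weights.size - 1) // 2
    if values.shape[1] < weights.size:
        raise ValueError(
            f"signal of length {values.shape[1]} shorter than window {weights.size}")
    windows = np.lib.stride_tricks.sliding_window_view(values, weights.size, axis=1)
    interior = windows @ weights
    out = np.empty_like(values)
    out[:, m:values.shape[1] - m] = interior
    if edge == "copy":
        out[:, :m] = values[:, :m]
        out[:, values.shape[1] - m:] = values[:, values.shape[1] - m:]
    else:
        out[:, :m] = interior[:, :1]
        out[:, values.shape[1] - m:] = interior[:, -1:]
    return out


def sg_smooth(s: Spectrum, spec: SGFilterSpec = SGFilterSpec()) -> Spectrum:
    """SG-smooth one spectrum; the first/last m points are copied through."""
    w = sg_center_coefficients(spec, deriv=0)
    return Spectrum(s.wavelengths, _sliding_apply(s.reflectance, w)[0])


def derivative(s: Spectrum, order: int,
               spec: SGFilterSpec | None = SGFilterSpec()) -> Spectrum:
    """Spectral derivative per nm.

    With an :class:`SGFilterSpec`, the derivative of the window
    polynomial at the centre (edges repeat the nearest interior value);
    with ``spec=None``, the plain adjacent finite difference, the first
    point repeating the first difference.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    y = np.asarray(s.reflectance, dtype=float)
    if spec is None:
        if y.size < 3:
            raise ValueError("need at least 3 points for finite differences")
        step = np.diff(s.wavelengths)
        d = np.diff(y) / step
        for _ in range(order - 1):
            d = np.diff(d) / step[: d.size - 1]
        out = np.concatenate([np.repeat(d[0], y.size - d.size), d])
        return Spectrum(s.wavelengths, out)
    step = float(np.diff(s.wavelengths).mean())
    w = sg_center_coefficients(spec, deriv=order, step=step)
    return Spectrum(s.wavelengths, _sliding_apply(y, w, edge="nearest")[0])


def msc_correct(M: SpectraMatrix,
                reference: np.ndarray | None = None) -> SpectraMatrix:
    """Multiplicative scatter correction against the mean spectrum.

    Each row i is regressed on the reference (OLS intercept a_i and
    slope b_i); the corrected row is (row - a_i) / b_i, undoing
    per-sample multiplicative and additive scatter.
    """
    if M.n_samples < 2 and reference is None:
        raise ValueError("need >= 2 samples to form a reference")
    ref = M.values.mean(axis=0) if reference is None else np.asarray(reference, float)
    if np.ptp(ref) == 0:
        raise ValueError("zero-variance reference spectrum")
    rc = ref - ref.mean()
    rows = M.values
    b = (rows - rows.mean(axis=1, keepdims=True)) @ rc / (rc @ rc)
    a = rows.mean(axis=1) - b * ref.mean()
    return M.with_values((rows - a[:, None]) / b[:, None])


def mean_center(M: SpectraMatrix) -> SpectraMatrix:
    """Subtract each wavelength's mean across samples."""
    if M.n_samples < 2:
        raise ValueError("need >= 2 samples")
    return M.with_values(M.values - M.values.mean(axis=0))


def apply_method(M: SpectraMatrix, method: PreprocessMethod | str,
                 sg: SGFilterSpec = SGFilterSpec()) -> SpectraMatrix:
    """Dispatch one of the eight preprocessing schemes on a matrix."""
    method = PreprocessMethod(method)
    if method is PreprocessMethod.raw:
        return M.with_values(M.values.copy())
    if method is PreprocessMethod.standard_normalization:
        return M.with_values(np.vstack([minmax_normalize(r) for r in M.values]))
    if method is PreprocessMethod.msc:
        return msc_correct(M)
    if method is PreprocessMethod.first_derivative:
        vals = np.vstack([derivative(M.row(i), 1, spec=None).reflectance
                          for i in range(M.n_samples)])
        return M.with_values(vals)
    if method is PreprocessMethod.sg_first_derivative:
        w = sg_center_coefficients(sg, 1, step=float(np.diff(M.wavelengths).mean()))
        return M.with_values(_sliding_apply(M.values, w, edge="nearest"))
    if method is PreprocessMethod.sg_second_derivative:
        w = sg_center_coefficients(sg, 2, step=float(np.diff(M.wavelengths).mean()))
        return M.with_values(_sliding_apply(M.values, w, edge="nearest"))
    if method is PreprocessMethod.sg_smoothing:
        w = sg_center_coefficients(sg, 0)
        return M.with_values(_sliding_apply(M.values, w, edge="copy"))
    if method is PreprocessMethod.mean_center:
        return mean_center(M)
    raise ValueError(f"unknown method {method!r}")  # pragma: no cover


# --------------------------------------------------------------------------
# scikit-learn transformers
# --------------------------------------------------------------------------

class RowMinMaxScaler(TransformerMixin, BaseEstimator):
    """Per-spectrum min-max normalization to [0, 1] (stateless)."""

    def fit(self, X, y=None):
        validate_data(self, X, ensure_min_features=2)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return np.vstack([minmax_normalize(r) for r in X])


class SavitzkyGolaySmoother(TransformerMixin, BaseEstimator):
    """SG convolution smoothing/derivative as a stateless transformer.

    Parameters mirror :class:`SGFilterSpec`: ``window`` = 2m+1 points,
    ``poly_order`` the fitted degree, ``deriv`` in {0, 1, 2}.
    """

    def __init__(self, window: int = 11, poly_order: int = 3, deriv: int = 0,
                 step: float = 1.0):
        self.window = window
        self.poly_order = poly_order
        self.deriv = deriv
        self.step = step

    def _spec(self) -> SGFilterSpec:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        return SGFilterSpec((self.window - 1) // 2, self.poly_order)

    def fit(self, X, y=None):
        validate_data(self, X, ensure_min_features=self.window)
        self._spec().validate()
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        w = sg_center_coefficients(self._spec(), self.deriv, step=self.step)
        return _sliding_apply(X, w, edge="copy" if self.deriv == 0 else "nearest")


class FiniteDifferenceDerivative(TransformerMixin, BaseEstimator):
    """Plain adjacent finite difference per `step` (first value repeated)."""

    def __init__(self, step: float = 1.0):
        self.step = step

    def fit(self, X, y=None):
        validate_data(self, X, ensure_min_features=3)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        d = np.diff(X, axis=1) / self.step
        return np.hstack([d[:, :1], d])


class MultiplicativeScatterCorrection(TransformerMixin, BaseEstimator):
    """MSC against the training-set mean spectrum.

    ``fit`` stores the reference; ``transform`` de-scatters any matrix
    on the same wavelength grid against it, so calibration and
    prediction sets are corrected consistently.
    """

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=2)
        self.reference_ = X.mean(axis=0)
        if np.ptp(self.reference_) == 0:
            raise ValueError("zero-variance reference spectrum")
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        M = SpectraMatrix(np.arange(X.shape[1], dtype=float) + 1.0, X)
        return msc_correct(M, reference=self.reference_).values


class MeanCenterer(TransformerMixin, BaseEstimator):
    """Column centering with training-set means."""

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=2)
        self.mean_ = X.mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X - self.mean_


#: transformer factory per scheme, fitted on calibration data only
def make_transformer(method: PreprocessMethod | str,
                     sg: SGFilterSpec = SGFilterSpec()):
    """Scheme -> fresh sklearn transformer (identity for `raw`)."""
    from sklearn.preprocessing import FunctionTransformer

    method = PreprocessMethod(method)
    window = sg.window
    if method is PreprocessMethod.raw:
        return FunctionTransformer(validate=True)
    if method is PreprocessMethod.standard_normalization:
        return RowMinMaxScaler()
    if method is PreprocessMethod.msc:
        return MultiplicativeScatterCorrection()
    if method is PreprocessMethod.first_derivative:
        return FiniteDifferenceDerivative()
    if method is PreprocessMethod.sg_first_derivative:
        return SavitzkyGolaySmoother(window, sg.poly_order, deriv=1)
    if method is PreprocessMethod.sg_second_derivative:
        return SavitzkyGolaySmoother(window, sg.poly_order, deriv=2)
    if method is PreprocessMethod.sg_smoothing:
        return SavitzkyGolaySmoother(window, sg.poly_order, deriv=0)
    if method is PreprocessMethod.mean_center:
        return MeanCenterer()
    raise ValueError(f"unknown method {method!r}")  # pragma: no cover
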