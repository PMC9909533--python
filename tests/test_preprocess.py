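"""Spectral preprocessing: SG projection filter, normalization, MSC,
derivatives, mean centering, and the eight-scheme dispatcher."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from leafspec.preprocess import (FiniteDifferenceDerivative, MeanCenterer,
                                 MultiplicativeScatterCorrection,
                                 PreprocessMethod, RowMinMaxScaler,
                                 SavitzkyGolaySmoother, SGFilterSpec,
                                 apply_method, derivative, mean_center,
                                 minmax_normalize, msc_correct,
                                 sg_center_coefficients, sg_filter_matrix,
                                 sg_smooth)
from leafspec.spectra import Spectrum, SpectraMatrix


def _matrix(rng, n=10, p=50):
    return SpectraMatrix(np.arange(p, dtype=float) + 400.0,
                         rng.uniform(0.05, 0.9, size=(n, p)))


class TestMinMax:
    @pytest.mark.parametrize("x, expected", [
        ([1, 2, 3], [0, 0.5, 1]),
        ([0, 10], [0, 1]),
        ([5, -5], [1, 0]),
    ])
    def test_examples(self, x, expected):
        np.testing.assert_allclose(minmax_normalize(x), expected)

    def test_matches_direct_formula_and_preserves_order(self, rng):
        x = rng.normal(size=50)
        y = minmax_normalize(x)
        np.testing.assert_allclose(y, (x - x.min()) / (x.max() - x.min()))
        assert y.min() == 0 and y.max() == 1
        assert np.array_equal(np.argsort(y), np.argsort(x))

    def test_idempotent_on_normalized(self, rng):
        y = minmax_normalize(rng.normal(size=20))
        np.testing.assert_allclose(minmax_normalize(y), y, atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize([3.0, 3.0, 3.0])


class TestSGFilterMatrix:
    def test_quadratic_window5_center_row(self):
        B = sg_filter_matrix(SGFilterSpec(half_width=2, poly_order=2))
        np.testing.assert_allclose(B[2], np.array([-3, 12, 17, 12, -3]) / 35,
                                   atol=1e-12)

    @pytest.mark.parametrize("m, k", [(2, 2), (5, 3), (12, 4), (7, 0)])
    def test_projection_identities(self, m, k):
        spec = SGFilterSpec(m, k)
        B = sg_filter_matrix(spec)
        assert B.shape == (2 * m + 1, 2 * m + 1)
        np.testing.assert_allclose(B, B.T, atol=1e-9)
        np.testing.assert_allclose(B @ B, B, atol=1e-9)
        # reproduces monomials up to the polynomial order
        x = np.arange(-m, m + 1, dtype=float)
        for d in range(k + 1):
            np.testing.assert_allclose(B @ x ** d, x ** d, atol=1e-8)

    def test_matches_scipy_coefficients(self):
        for m, k, d in [(5, 3, 0), (5, 3, 1), (5, 3, 2), (3, 2, 1)]:
            ours = sg_center_coefficients(SGFilterSpec(m, k), deriv=d)
            ref = savgol_coeffs(2 * m + 1, k, deriv=d)[::-1]
            np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_underdetermined_window_rejected(self):
        with pytest.raises(ValueError):
            SGFilterSpec(half_width=1, poly_order=2).validate()


class TestSGSmooth:
    def test_reproduces_quadratic_interior(self):
        w = np.arange(400.0, 460.0)
        y = 2.0 + 0.3 * w + 0.01 * w ** 2
        out = sg_smooth(Spectrum(w, y), SGFilterSpec(5, 3))
        np.testing.assert_allclose(out.reflectance[5:-5], y[5:-5], rtol=1e-9)

    def test_constant_unchanged(self):
        w = np.arange(400.0, 430.0)
        out = sg_smooth(Spectrum(w, np.full_like(w, 0.4)))
        np.testing.assert_allclose(out.reflectance, 0.4)

    def test_matches_per_window_polyfit_oracle(self, rng):
        w = np.arange(500.0, 600.0)
        y = np.sin(w / 7.0) + rng.normal(0, 0.1, w.size)
        m, k = 5, 3
        out = sg_smooth(Spectrum(w, y), SGFilterSpec(m, k)).reflectance
        x = np.arange(-m, m + 1, dtype=float)
        for i in range(m, w.size - m):
            coeffs = np.polynomial.polynomial.polyfit(x, y[i - m:i + m + 1], k)
            assert out[i] == pytest.approx(coeffs[0], abs=1e-9)

    def test_edges_copied_through(self, rng):
        w = np.arange(400.0, 450.0)
        y = rng.normal(size=w.size)
        out = sg_smooth(Spectrum(w, y), SGFilterSpec(5, 3)).reflectance
        np.testing.assert_array_equal(out[:5], y[:5])
        np.testing.assert_array_equal(out[-5:], y[-5:])

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sg_smooth(Spectrum(np.arange(5.0), np.ones(5)), SGFilterSpec(5, 3))


class TestDerivative:
    def test_linear_slope_recovered(self):
        w = np.arange(400.0, 450.0)
        s = Spectrum(w, 0.002 * w + 1.0)
        np.testing.assert_allclose(derivative(s, 1, SGFilterSpec(5, 3)).reflectance,
                                   0.002, atol=1e-10)
        np.testing.assert_allclose(derivative(s, 1, spec=None).reflectance,
                                   0.002, atol=1e-10)

    def test_quadratic_second_derivative(self):
        w = np.arange(-20.0, 21.0)
        s = Spectrum(w, 3.0 * w ** 2)
        out = derivative(s, 2, SGFilterSpec(5, 3)).reflectance
        np.testing.assert_allclose(out, 6.0, atol=1e-8)

    def test_matches_polyfit_derivative_oracle(self, rng):
        w = np.arange(0.0, 60.0)
        y = rng.normal(size=w.size)
        m, k = 4, 3
        for order in (1, 2):
            out = derivative(Spectrum(w, y), order, SGFilterSpec(m, k)).reflectance
            x = np.arange(-m, m + 1, dtype=float)
            for i in range(m, w.size - m, 7):
                c = np.polynomial.polynomial.polyfit(x, y[i - m:i + m + 1], k)
                expected = c[1] if order == 1 else 2 * c[2]
                assert out[i] == pytest.approx(expected, abs=1e-9)

    def test_invalid_order(self):
        s = Spectrum(np.arange(30.0), np.ones(30))
        with pytest.raises(ValueError, match="order"):
            derivative(s, 3)


class TestMSC:
    def test_exact_descatter(self, rng):
        ref = rng.uniform(0.1, 0.9, size=40)
        a = rng.normal(0, 0.2, size=6)
        b = rng.uniform(0.5, 2.0, size=6)
        M = SpectraMatrix(np.arange(40.0), a[:, None] + b[:, None] * ref)
        out = msc_correct(M)
        # all rows collapse onto the (affinely adjusted) common shape
        assert np.allclose(out.values - out.values[0], 0, atol=1e-8)

    def test_fixed_point_regression(self, rng):
        M = _matrix(rng, 8, 30)
        out = msc_correct(M)
        ref = M.values.mean(axis=0)  # the correction's own reference
        for row in out.values:
            b, a = np.polyfit(ref, row, 1)
            assert b == pytest.approx(1.0, abs=1e-8)
            assert a == pytest.approx(0.0, abs=1e-8)

    def test_matches_rowwise_lstsq_oracle(self, rng):
        M = _matrix(rng, 5, 20)
        out = msc_correct(M)
        ref = M.values.mean(axis=0)
        A = np.c_[np.ones_like(ref), ref]
        for i in range(5):
            (a, b), *_ = np.linalg.lstsq(A, M.values[i], rcond=None)
            np.testing.assert_allclose(out.values[i], (M.values[i] - a) / b,
                                       rtol=1e-10)

    def test_scatter_free_matrix_unchanged(self):
        row = np.linspace(0.2, 0.8, 25)
        M = SpectraMatrix(np.arange(25.0), np.tile(row, (4, 1)))
        np.testing.assert_allclose(msc_correct(M).values, M.values, atol=1e-10)


class TestMeanCenter:
    def test_toy(self):
        M = SpectraMatrix([1.0, 2.0], [[1, 2], [3, 4]])
        np.testing.assert_allclose(mean_center(M).values, [[-1, -1], [1, 1]])

    def test_idempotent_zero_columns(self, rng):
        M = _matrix(rng)
        once = mean_center(M)
        np.testing.assert_allclose(once.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(mean_center(once).values, once.values,
                                   atol=1e-12)


class TestApplyMethod:
    def test_raw_identity(self, rng):
        M = _matrix(rng)
        np.testing.assert_array_equal(apply_method(M, "raw").values, M.values)

    @pytest.mark.parametrize("method", list(PreprocessMethod))
    def test_all_methods_run_and_preserve_shape(self, method, rng):
        M = _matrix(rng, 10, 50)
        out = apply_method(M, method, SGFilterSpec(5, 3))
        assert out.values.shape == M.values.shape
        assert np.all(np.isfinite(out.values))
        # determinism
        again = apply_method(M, method, SGFilterSpec(5, 3))
        np.testing.assert_array_equal(out.values, again.values)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_method(_matrix(rng), "bogus")


class TestTransformers:
    """The sklearn faces mirror the functional operations."""

    def test_msc_transformer_consistent_reference(self, rng):
        M = _matrix(rng, 12, 30)
        tr = MultiplicativeScatterCorrection().fit(M.values[:8])
        out = tr.transform(M.values[:8])
        oracle = msc_correct(SpectraMatrix(M.wavelengths[:30], M.values[:8]))
        np.testing.assert_allclose(out, oracle.values, rtol=1e-10)
        # prediction rows corrected against the *training* reference
        assert tr.transform(M.values[8:]).shape == (4, 30)

    def test_sg_transformer_matches_function(self, rng):
        M = _matrix(rng, 4, 40)
        out = SavitzkyGolaySmoother(11, 3).fit_transform(M.values)
        exp = apply_method(M, "sg_smoothing", SGFilterSpec(5, 3)).values
        np.testing.assert_array_equal(out, exp)

    def test_row_scaler_and_centerer(self, rng):
        X = rng.uniform(size=(6, 20))
        out = RowMinMaxScaler().fit_transform(X)
        assert np.allclose(out.min(axis=1), 0) and np.allclose(out.max(axis=1), 1)
        cc = MeanCenterer().fit(X[:4])
        np.testing.assert_allclose(cc.transform(X[:4]).mean(axis=0), 0,
                                   atol=1e-12)

    def test_finite_difference(self):
        X = np.array([[1.0, 2.0, 4.0, 7.0]])
        out = FiniteDifferenceDerivative().fit_transform(X)
        np.testing.assert_allclose(out, [[1, 1, 2, 3]])
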