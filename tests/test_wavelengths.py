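"""Wavelength selection: absorbance transform, correlation curve, PCA
loadings, and band screening."""

import numpy as np
import pytest

from leafspec.datasets import SpectraSimConfig, generate_spectra
from leafspec.spectra import SpectraMatrix
from leafspec.wavelengths import (CharacteristicBandSelector, correlation_curve,
                                  log_inverse_transform, pca_loadings,
                                  screen_bands)


def _mat(values, wavelengths=None):
    values = np.asarray(values, dtype=float)
    w = (np.arange(values.shape[1], dtype=float) + 400.0
         if wavelengths is None else np.asarray(wavelengths, float))
    return SpectraMatrix(w, values)


class TestLogInverse:
    def test_point_values(self):
        M = _mat([[1.0, 0.1, 0.01]])
        np.testing.assert_allclose(log_inverse_transform(M).values,
                                   [[0.0, 1.0, 2.0]], atol=1e-12)

    def test_round_trip(self, rng):
        M = _mat(rng.uniform(0.05, 1.0, size=(6, 30)))
        T = log_inverse_transform(M)
        np.testing.assert_allclose(10.0 ** (-T.values), M.values, rtol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_inverse_transform(_mat([[0.5, 0.0, 0.2]]))


class TestCorrelationCurve:
    def test_perfectly_linear_columns(self):
        col = np.array([1.0, 2, 3, 4, 5])
        M = _mat(np.c_[col, -col, np.full(5, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            c = correlation_curve(M, 2 * col)
        np.testing.assert_allclose(c.r, [1.0, -1.0, 0.0], atol=1e-12)
        c2 = correlation_curve(_mat(col[:, None]), np.array([10., 8, 6, 4, 2]))
        assert c2.r[0] == pytest.approx(-1.0)

    def test_matches_bruteforce_pearson(self, rng):
        X = rng.normal(size=(30, 20))
        y = rng.normal(size=30)
        c = correlation_curve(_mat(X), y)
        for j in range(20):
            xm, ym = X[:, j] - X[:, j].mean(), y - y.mean()
            expected = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
            assert c.r[j] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(c.r_squared, c.r ** 2)

    def test_affine_invariance_and_sign_flip(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        base = correlation_curve(_mat(X), y).r
        np.testing.assert_allclose(correlation_curve(_mat(X), 3 * y + 2).r,
                                   base, atol=1e-12)
        np.testing.assert_allclose(correlation_curve(_mat(X), -y).r,
                                   -base, atol=1e-12)

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="constant"):
            correlation_curve(_mat(X), np.ones(10))
        with pytest.raises(ValueError):
            correlation_curve(_mat(X[:2]), np.arange(2.0))


class TestPCALoadings:
    def test_perfectly_correlated_two_columns(self, rng):
        x = rng.normal(size=30)
        loads = pca_loadings(_mat(np.c_[x, 2 * x + 1]), q=1)
        assert loads.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_orthonormal_loadings_and_evr_shape(self, rng):
        M = _mat(rng.normal(size=(20, 10)))
        loads = pca_loadings(M, q=4)
        np.testing.assert_allclose(loads.loadings @ loads.loadings.T,
                                   np.eye(4), atol=1e-9)
        evr = loads.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9
        assert np.all(evr >= 0)

    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        sv = np.linalg.svd(Z, compute_uv=False)
        expected = sv ** 2 / np.sum(sv ** 2)
        loads = pca_loadings(_mat(X), q=3)
        np.testing.assert_allclose(loads.explained_variance_ratio,
                                   expected[:3], rtol=1e-9)

    def test_rank_bound_enforced(self, rng):
        with pytest.raises(ValueError):
            pca_loadings(_mat(rng.normal(size=(4, 10))), q=5)


class TestScreenBands:
    def test_planted_band_selected_and_primary(self):
        cfg = SpectraSimConfig(n_samples=200, seed=11)
        s = generate_spectra(cfg)
        sel = CharacteristicBandSelector(wavelengths=s.spectra.wavelengths)
        sel.fit(s.spectra.values, s.concentrations)
        assert abs(sel.primary_band_ - cfg.planted_band) <= cfg.band_width_sigma
        assert any(abs(b - cfg.planted_band) <= cfg.band_width_sigma
                   for b in sel.selection_.wavelengths)

    def test_min_separation_respected(self):
        s = generate_spectra(SpectraSimConfig(n_samples=150, seed=4))
        sel = CharacteristicBandSelector(wavelengths=s.spectra.wavelengths,
                                         n_bands=7, min_separation=30.0)
        sel.fit(s.spectra.values, s.concentrations)
        bands = sel.selection_.wavelengths
        gaps = [abs(a - b) for i, a in enumerate(bands) for b in bands[i + 1:]]
        assert all(g >= 30.0 for g in gaps)

    def test_null_data_still_returns_with_low_evidence(self):
        s = generate_spectra(SpectraSimConfig(n_samples=150, effect_size=0.0,
                                              seed=8))
        sel = CharacteristicBandSelector(wavelengths=s.spectra.wavelengths)
        sel.fit(s.spectra.values, s.concentrations)
        assert sel.selection_.max_r_squared < 0.3
        assert sel.selection_.primary in sel.selection_.wavelengths

    def test_fewer_peaks_than_requested_warns(self, rng):
        # two clean peaks only
        from leafspec.wavelengths import CorrelationCurve, PCALoadings
        w = np.arange(400.0, 500.0)
        r = 0.5 * np.exp(-0.5 * ((w - 430) / 4) ** 2) \
            + 0.4 * np.exp(-0.5 * ((w - 470) / 4) ** 2)
        curve = CorrelationCurve(w, r)
        loads = PCALoadings(w, np.ones((1, w.size)) / np.sqrt(w.size),
                            np.array([0.9]))
        with pytest.warns(UserWarning, match="separated peaks"):
            sel = screen_bands(curve, loads, n_bands=5, min_separation=20.0)
        assert len(sel.wavelengths) == 2
        assert sel.primary == pytest.approx(430.0)

    def test_primary_transform_keeps_selected_columns(self):
        s = generate_spectra(SpectraSimConfig(n_samples=100, seed=2))
        sel = CharacteristicBandSelector(wavelengths=s.spectra.wavelengths,
                                         n_bands=5)
        Xt = sel.fit(s.spectra.values, s.concentrations).transform(s.spectra.values)
        assert Xt.shape == (100, len(sel.selection_.wavelengths))
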