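"""Tests of the causal core: MVAR fitting, AIC order selection, GPDC, band
averaging, and surrogate edge detection.

Includes two independent oracles: a brute-force polynomial-summation GPDC
evaluator, and a statsmodels VAR cross-check of the OLS coefficients.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from effconn.containers import TimeSeriesMatrix
from effconn.gca import (
    MVAR,
    VARModel,
    band_average,
    detect_edges_surrogate,
    fit_mvar,
    gpdc_from_coeffs,
    select_order_aic,
    transfer_matrix,
)
from effconn.graphs import CausalGraph, random_stable_graph
from effconn.simulate import simulate_var


def brute_force_gpdc(coeffs, noise_vars, f_norm):
    """Literal evaluation of the GPDC definition, term by term."""
    p, n, _ = coeffs.shape
    abar = np.zeros((n, n), dtype=complex)
    for i in range(n):
        for j in range(n):
            abar[i, j] = (1.0 if i == j else 0.0)
            for k in range(1, p + 1):
                abar[i, j] -= coeffs[k - 1][i][j] * np.exp(-1j * 2 * np.pi * f_norm * k)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = abs(abar[i, j]) / np.sqrt(noise_vars[i])
            den = 0.0
            for k in range(n):
                den += abs(abar[k, j]) ** 2 / noise_vars[k]
            out[i, j] = num / np.sqrt(den)
    return out


class TestFitMvar:
    def test_recovers_known_var1_coefficients(self, bivariate_chain):
        ts = simulate_var(bivariate_chain, 2000, seed=0)
        model = fit_mvar(ts, order=1, standardize=False)
        np.testing.assert_allclose(
            model.coeffs[0], bivariate_chain.coeffs[0], atol=0.05
        )

    def test_matches_statsmodels_var(self):
        # independent implementation of the same OLS problem
        from statsmodels.tsa.api import VAR as SmVAR

        g = random_stable_graph(3, 2, seed=11)
        ts = simulate_var(g, 800, seed=1)
        mine = fit_mvar(ts, order=2, standardize=False)
        sm = SmVAR(ts.values).fit(maxlags=2, trend="c")
        np.testing.assert_allclose(mine.coeffs[0], sm.coefs[0], atol=1e-8)
        np.testing.assert_allclose(mine.coeffs[1], sm.coefs[1], atol=1e-8)

    def test_white_noise_coefficients_near_zero(self):
        g = CausalGraph(np.zeros((1, 3, 3)), np.ones(3))
        inside = 0
        for s in range(20):
            ts = simulate_var(g, 1000, seed=s)
            model = fit_mvar(ts, order=1)
            se = 1 / np.sqrt(model.n_samples_used)
            inside += np.all(np.abs(model.coeffs[0]) < 3 * se)
        assert inside >= 17  # ~95% of seeds within 3 SEs

    def test_order_zero_rejected(self, bivariate_chain):
        ts = simulate_var(bivariate_chain, 200, seed=0)
        with pytest.raises(ValueError, match="order"):
            fit_mvar(ts, order=0)

    def test_identifiability_guard(self):
        ts = TimeSeriesMatrix(np.random.default_rng(0).standard_normal((20, 6)), 2.0)
        with pytest.raises(ValueError, match="identifiable"):
            fit_mvar(ts, order=3)

    def test_censor_mask_restricts_to_longest_run(self, bivariate_chain):
        from effconn.containers import CensorMask

        ts = simulate_var(bivariate_chain, 300, seed=2)
        keep = np.ones(300, dtype=bool)
        keep[200:205] = False  # longest run = frames 0..199
        est = MVAR(order=1).fit(ts, censor=CensorMask(keep=keep))
        assert est.n_samples_used_ == 200 - 1

    def test_roundtrip_preserves_lag1_autocovariance(self, bivariate_chain):
        ts = simulate_var(bivariate_chain, 5000, seed=3)
        model = fit_mvar(ts, order=1, standardize=False)
        refit_graph = CausalGraph(model.coeffs, np.maximum(model.noise_vars, 1e-6))
        ts2 = simulate_var(refit_graph, 5000, seed=4)

        def lag1(x):
            return (x[:-1].T @ x[1:]) / (len(x) - 1)

        np.testing.assert_allclose(
            lag1(ts2.values - ts2.values.mean(0)),
            lag1(ts.values - ts.values.mean(0)),
            rtol=0.10, atol=0.05,
        )


class TestSelectOrderAic:
    def test_recovers_true_order_two(self):
        a = np.zeros((2, 2, 2))
        a[0] = [[0.4, 0.0], [0.4, 0.4]]
        a[1] = [[0.4, 0.1], [0.0, 0.3]]
        g = CausalGraph(a, np.ones(2))
        hits = sum(
            select_order_aic(simulate_var(g, 1000, seed=s), p_max=6) == 2
            for s in range(25)
        )
        assert hits >= 20  # >= 80%

    def test_white_noise_selects_minimum_order(self):
        g = CausalGraph(np.zeros((1, 2, 2)), np.ones(2))
        picks = [select_order_aic(simulate_var(g, 500, seed=s), p_max=5)
                 for s in range(15)]
        assert sum(p == 1 for p in picks) > len(picks) / 2

    def test_increasing_aic_returns_one(self):
        # white noise at short T: penalty dominates, argmin at p = 1
        g = CausalGraph(np.zeros((1, 2, 2)), np.ones(2))
        ts = simulate_var(g, 120, seed=0)
        assert select_order_aic(ts, p_max=4) == 1


class TestTransferMatrix:
    def test_zero_coefficients_give_identity(self):
        m = VARModel(np.zeros((1, 3, 3)), np.eye(3), 100)
        for f in (0.0, 0.25, 0.5):
            np.testing.assert_allclose(transfer_matrix(m, f), np.eye(3))

    def test_univariate_dc_value(self):
        m = VARModel(np.array([[[0.9]]]), np.array([[1.0]]), 100)
        assert transfer_matrix(m, 0.0)[0, 0] == pytest.approx(0.1)

    def test_nyquist_alternating_sign_identity(self):
        coeffs = np.random.default_rng(5).normal(0, 0.2, (3, 2, 2))
        m = VARModel(coeffs, np.eye(2), 100)
        expected = np.eye(2) - sum(
            (-1) ** (k + 1) * coeffs[k] for k in range(3)
        )
        np.testing.assert_allclose(transfer_matrix(m, 0.5), expected, atol=1e-12)


class TestGPDC:
    def test_bivariate_closed_form(self, bivariate_chain):
        spec = gpdc_from_coeffs(bivariate_chain.coeffs, bivariate_chain.noise_vars, 2.0)
        expected = 0.5 / np.sqrt(1.25)
        np.testing.assert_allclose(spec.values[1, 0], expected, atol=1e-12)
        np.testing.assert_allclose(spec.values[0, 1], 0.0, atol=1e-12)

    def test_column_normalization_closed_form(self, bivariate_chain):
        spec = gpdc_from_coeffs(bivariate_chain.coeffs, bivariate_chain.noise_vars, 2.0)
        col = (spec.values[:, 0, :] ** 2).sum(axis=0)
        np.testing.assert_allclose(col, 1.0, atol=1e-12)

    def test_diagonal_coefficients_give_zero_offdiagonal(self):
        coeffs = np.zeros((2, 3, 3))
        np.fill_diagonal(coeffs[0], [0.5, 0.3, 0.2])
        np.fill_diagonal(coeffs[1], 0.1)
        spec = gpdc_from_coeffs(coeffs, np.ones(3), 2.0)
        off = spec.values * (1 - np.eye(3))[:, :, None]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 6), st.integers(1, 3), st.integers(0, 10**6))
    def test_normalization_invariant_random_models(self, n, p, seed):
        g = random_stable_graph(n, p, seed=seed)
        spec = gpdc_from_coeffs(g.coeffs, g.noise_vars, 2.0, n_freqs=17)
        norms = (spec.values**2).sum(axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-8)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(1, 3), st.integers(1, 2), st.integers(0, 10**6))
    def test_matches_brute_force_oracle(self, n, p, seed):
        g = random_stable_graph(n, p, seed=seed)
        freqs = np.array([0.0, 0.03, 0.1, 0.2, 0.25])
        spec = gpdc_from_coeffs(g.coeffs, g.noise_vars, 2.0, freqs_hz=freqs)
        for fi, f in enumerate(freqs):
            oracle = brute_force_gpdc(g.coeffs, g.noise_vars, f * 2.0)
            np.testing.assert_allclose(spec.values[:, :, fi], oracle, atol=1e-10)

    def test_permutation_equivariance(self):
        g = random_stable_graph(4, 2, seed=77)
        perm = np.array([2, 0, 3, 1])
        g_perm = CausalGraph(
            g.coeffs[:, perm][:, :, perm], g.noise_vars[perm]
        )
        a = gpdc_from_coeffs(g.coeffs, g.noise_vars, 2.0, n_freqs=9).values
        b = gpdc_from_coeffs(g_perm.coeffs, g_perm.noise_vars, 2.0, n_freqs=9).values
        np.testing.assert_allclose(b, a[perm][:, perm], atol=1e-12)

    def test_zero_noise_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gpdc_from_coeffs(np.zeros((1, 2, 2)), np.array([1.0, 0.0]), 2.0)


class TestBandAverage:
    def test_constant_spectrum_average_equals_constant(self, bivariate_chain):
        spec = gpdc_from_coeffs(bivariate_chain.coeffs, bivariate_chain.noise_vars, 2.0)
        edges = band_average(spec, 0.01, 0.1)
        assert edges.values[1, 0] == pytest.approx(0.5 / np.sqrt(1.25), abs=1e-12)

    def test_single_grid_point_band_rejected(self, bivariate_chain):
        spec = gpdc_from_coeffs(bivariate_chain.coeffs, bivariate_chain.noise_vars,
                                2.0, n_freqs=5)  # grid spacing 0.0625 Hz
        with pytest.raises(ValueError, match="2"):
            band_average(spec, 0.06, 0.07)

    def test_widening_band_over_constant_spectrum_unchanged(self, bivariate_chain):
        spec = gpdc_from_coeffs(bivariate_chain.coeffs, bivariate_chain.noise_vars, 2.0)
        narrow = band_average(spec, 0.01, 0.1).values
        wide = band_average(spec, 0.0, 0.25).values
        np.testing.assert_allclose(narrow, wide, atol=1e-12)


class TestDetectEdgesSurrogate:
    def test_strong_edge_detected(self, bivariate_chain):
        g = CausalGraph(bivariate_chain.coeffs.copy(), np.ones(2))
        g.coeffs[0, 1, 0] = 0.6
        hits = sum(
            detect_edges_surrogate(
                simulate_var(g, 400, seed=s), 99, 0.05, seed=1000 + s, order=1
            )[1, 0]
            for s in range(10)
        )
        assert hits >= 9

    def test_too_few_surrogates_rejected(self, bivariate_chain):
        ts = simulate_var(bivariate_chain, 200, seed=0)
        with pytest.raises(ValueError, match="surrogates"):
            detect_edges_surrogate(ts, n_surrogates=10, alpha=0.05)

    def test_phase_randomization_preserves_amplitude_spectrum(self):
        from effconn.gca import phase_randomize

        rng = np.random.default_rng(3)
        x = rng.standard_normal((256, 2))
        surr = phase_randomize(x, rng)
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(surr, axis=0)),
            np.abs(np.fft.rfft(x, axis=0)),
            atol=1e-8,
        )
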