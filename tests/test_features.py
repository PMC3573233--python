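"""PCA eigenvariate, shrinkage VAR estimation and the spectral transform."""

import numpy as np
import pytest
from scipy import signal

from bgdcm.features import (
    DEFAULT_VAR_ORDER,
    SegmentRecording,
    VarModel,
    debias,
    extract_features,
    feature_noise,
    first_principal_component,
    fit_var,
    simulate_var,
    var_csd,
    var_from_spectrum,
)
from bgdcm.synth import make_ground_truth, simulate_pair


@pytest.fixture(scope="module")
def off_on_pair(config):
    cohort = make_ground_truth(1, 1, seed=4, config=config)
    return simulate_pair(cohort.pairs[0], config=config)


class TestFirstPrincipalComponent:
    def test_identical_channels_explain_everything(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5000)
        series, frac = first_principal_component(np.vstack([x, x, x]))
        assert frac == pytest.approx(1.0)

    def test_independent_channels_share_evenly(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((3, 200_000))
        _, frac = first_principal_component(X)
        assert frac == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_known_mixture_matches_eigenvalue_share(self):
        """Rank-2 loading mixture: the variance fraction must equal the
        leading-eigenvalue share of the analytic covariance."""
        rng = np.random.default_rng(2)
        L = np.array([[1.0, 0.2], [0.7, -0.5], [0.4, 0.9]])
        T = 50_000
        X = L @ rng.standard_normal((2, T))
        cov = L @ L.T
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eig[0] / eig.sum()
        _, frac = first_principal_component(X)
        assert frac == pytest.approx(expected, rel=0.02)

    def test_sign_convention_and_determinism(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(3000)
        X = np.vstack([-2 * x, x, 0.5 * x])
        s1, _ = first_principal_component(X)
        s2, _ = first_principal_component(X)
        assert np.array_equal(s1, s2)
        # dominant loading positive: series aligned with the -2x channel
        assert np.corrcoef(s1, -x)[0, 1] > 0.99

    def test_constant_channel_rejected(self):
        X = np.vstack([np.zeros(1000), np.ones(1000) * 2.0,
                       np.linspace(0, 1, 1000)])
        with pytest.raises(ValueError, match="constant"):
            first_principal_component(X)


class TestFitVar:
    def _sample_var(self, A, E, T, seed):
        model = VarModel(A, E, fs=200.0)
        return simulate_var(model, T, seed=seed)

    def test_recovers_known_var8_coefficients(self):
        rng = np.random.default_rng(5)
        k, p = 3, DEFAULT_VAR_ORDER
        A = np.zeros((p, k, k))
        A[0] = 0.4 * np.eye(k) + 0.05 * rng.standard_normal((k, k))
        A[1] = -0.2 * np.eye(k)
        A[7] = 0.05 * np.eye(k)
        E = np.eye(k)
        Y = self._sample_var(A, E, 100_000, seed=6)
        fit = fit_var(Y, order=p)
        assert np.max(np.abs(fit.A - A)) < 0.02
        assert np.allclose(fit.E, E, atol=0.05)

    def test_white_noise_gives_null_coefficients(self):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((3, 50_000))
        fit = fit_var(Y, order=4)
        se = 3.0 / np.sqrt(Y.shape[1])
        assert np.max(np.abs(fit.A)) < 3 * se
        assert np.allclose(fit.E, np.cov(Y), atol=0.05)

    def test_infinite_shrinkage_zeroes_coefficients(self):
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((2, 5_000))
        fit = fit_var(Y, order=3, ridge=1e18)
        assert np.max(np.abs(fit.A)) < 1e-8

    def test_estimation_error_shrinks_with_length(self):
        A = np.zeros((2, 2, 2)); A[0] = 0.5 * np.eye(2); A[1] = -0.3 * np.eye(2)
        E = np.eye(2)
        errs = []
        for T in (2_000, 50_000):
            Y = self._sample_var(A, E, T, seed=9)
            fit = fit_var(Y, order=2)
            errs.append(np.max(np.abs(fit.A - A)))
        assert errs[1] < errs[0]

    def test_agrees_with_statsmodels_ols_var(self):
        """Independent cross-check: with negligible shrinkage the estimate
        must match an ordinary least-squares VAR fit."""
        from statsmodels.tsa.api import VAR as SmVAR

        A = np.zeros((2, 2, 2)); A[0] = 0.5 * np.eye(2)
        A[1] = np.array([[-0.2, 0.1], [0.0, -0.3]])
        Y = self._sample_var(A, np.eye(2), 20_000, seed=17)
        ours = fit_var(Y, order=2, ridge=1e-8)
        sm_fit = SmVAR(Y.T).fit(maxlags=2, trend="c")
        # statsmodels stacks lag-1 then lag-2 coefficient matrices
        assert np.allclose(ours.A[0], sm_fit.coefs[0], atol=1e-3)
        assert np.allclose(ours.A[1], sm_fit.coefs[1], atol=1e-3)
        assert np.allclose(ours.E, sm_fit.sigma_u, atol=1e-2)

    def test_rank_deficient_regressors_rejected(self):
        Y = np.zeros((2, 1000))
        Y[0] = np.sin(np.arange(1000))
        Y[1] = Y[0]  # duplicated channel
        with pytest.raises(ValueError):
            fit_var(Y, order=2, ridge=0.0)


class TestVarCsd:
    def test_white_noise_identity(self):
        E = np.array([[2.0, 0.5], [0.5, 1.0]])
        model = VarModel(np.zeros((1, 2, 2)), E, fs=200.0)
        csd = var_csd(model, np.array([5.0, 20.0, 60.0]), 200.0)
        for k in range(3):
            assert np.allclose(csd.S[k].real, E, atol=1e-12)

    def test_scalar_ar1_closed_form(self):
        a, fs = 0.9, 1000.0
        model = VarModel(np.array([[[a]]]), np.array([[1.0]]), fs=fs)
        freqs = np.array([1.0, 10.0, 40.0])
        csd = var_csd(model, freqs, fs)
        expected = 1.0 / np.abs(1 - a * np.exp(-1j * 2 * np.pi * freqs / fs)) ** 2
        assert np.allclose(csd.S[:, 0, 0].real, expected, rtol=1e-12)

    def test_hermitian_psd_for_fitted_models(self, off_on_pair):
        rec, _ = off_on_pair
        feats = extract_features(rec)
        assert feats.is_hermitian(tol=0.0)
        assert np.min(np.linalg.eigvalsh(feats.S)) >= -1e-12

    def test_matches_welch_of_long_simulation(self):
        """Simulation oracle: band spectra of a long sample from the model
        vs the analytic transform (up to the documented E-convention
        scale, fs/2 relative to one-sided density)."""
        A = np.zeros((2, 2, 2))
        A[0] = np.array([[0.6, 0.2], [0.0, 0.4]])
        A[1] = np.array([[-0.3, 0.0], [0.1, -0.2]])
        E = np.array([[1.0, 0.3], [0.3, 1.5]])
        fs = 200.0
        model = VarModel(A, E, fs=fs)
        Y = simulate_var(model, 400_000, seed=10)
        f, P = signal.welch(Y, fs=fs, nperseg=1024)
        m = (f >= 13) & (f <= 35)
        pred = var_csd(model, f[m], fs)
        for i in range(2):
            band_sim = np.trapezoid(P[i][m], f[m]) * fs / 2.0
            band_ana = np.trapezoid(pred.S[:, i, i].real, f[m])
            assert abs(band_sim / band_ana - 1) < 0.10


class TestVarFromSpectrum:
    def test_projection_recovers_generating_var(self):
        A = np.zeros((2, 2, 2)); A[0] = [[0.5, 0.1], [0.0, 0.3]]
        A[1] = [[-0.2, 0.0], [0.05, -0.1]]
        E = np.array([[1.0, 0.3], [0.3, 2.0]])
        vm = VarModel(A, E, fs=200.0)
        f = np.linspace(0.05, 100.0, 2001)
        S = var_csd(vm, f, 200.0).S
        back = var_from_spectrum(f, S, 200.0, order=2)
        assert np.allclose(back.A, A, atol=2e-3)
        assert np.allclose(back.E, E, atol=5e-3)


class TestExtractFeatures:
    def test_deterministic(self, off_on_pair):
        rec, _ = off_on_pair
        f1 = extract_features(rec)
        f2 = extract_features(rec)
        assert np.array_equal(f1.S, f2.S)

    def test_off_segment_peaks_in_beta_band(self, off_on_pair):
        rec_off, _ = off_on_pair
        feats = extract_features(rec_off)
        auto = feats.auto_spectra()
        for i in range(3):
            peak = feats.freqs[np.argmax(auto[:, i])]
            assert 13.0 <= peak <= 35.0

    def test_off_beta_exceeds_on(self, off_on_pair):
        rec_off, rec_on = off_on_pair
        p_off = extract_features(rec_off).band_power()
        p_on = extract_features(rec_on).band_power()
        stn = 1  # (ctx, stn, gpi) ordering
        assert p_off[stn] > p_on[stn]

    def test_common_scaling_invariance_up_to_power(self, off_on_pair):
        rec, _ = off_on_pair
        scaled = SegmentRecording(rec.channels * 3.0, rec.labels, rec.fs,
                                  rec.condition, rec.subject, rec.segment)
        f1 = extract_features(rec)
        f2 = extract_features(scaled)
        assert np.allclose(f2.S, 9.0 * f1.S, rtol=1e-8)

    def test_order14_can_split_a_single_peak(self, off_on_pair):
        """Diagnostic (not an assertion of failure): a higher model order
        may represent one spectral peak as several; record the in-band
        local-maximum counts for both orders."""
        rec_off, _ = off_on_pair
        def n_peaks(order):
            feats = extract_features(rec_off, order=order, freq_step=0.25)
            a = feats.auto_spectra()[:, 1]
            return int(np.sum((a[1:-1] > a[:-2]) & (a[1:-1] > a[2:])))
        peaks8, peaks14 = n_peaks(8), n_peaks(14)
        assert peaks8 >= 1 and peaks14 >= 1  # both remain usable spectra


class TestFeatureNoise:
    def test_bootstrap_variance_is_positive_and_finite(self, off_on_pair):
        rec, _ = off_on_pair
        var, bias = feature_noise(rec, n_boot=4)
        assert np.all(var.S.real > 0)
        assert np.all(np.isfinite(var.S.real))
        assert np.all(np.isfinite(bias.S.real))

    def test_debias_subtracts(self, off_on_pair):
        rec, _ = off_on_pair
        feats = extract_features(rec)
        var, bias = feature_noise(rec, n_boot=4)
        corrected = debias(feats, bias)
        assert np.allclose(corrected.S, feats.S - bias.S)


class TestRecordingIO:
    def test_csv_round_trip(self, off_on_pair, tmp_path):
        rec, _ = off_on_pair
        short = SegmentRecording(rec.channels[:, :12_000], rec.labels,
                                 rec.fs, rec.condition, rec.subject,
                                 rec.segment)
        path = tmp_path / "seg.csv"
        short.to_csv(path)
        back = SegmentRecording.from_csv(path)
        assert back.labels == short.labels
        assert np.allclose(back.channels, short.channels)
        assert back.condition == short.condition

    def test_hdf5_round_trip(self, off_on_pair, tmp_path):
        rec, _ = off_on_pair
        path = tmp_path / "seg.h5"
        rec.to_hdf5(path)
        back = SegmentRecording.from_hdf5(path)
        assert np.array_equal(back.channels, rec.channels)
        assert back.subject == rec.subject

    def test_layout_validation(self):
        with pytest.raises(ValueError, match="stn"):
            SegmentRecording(np.zeros((2, 20_000)), ("ctx", "stn_01"))
        with pytest.raises(ValueError, match="short"):
            SegmentRecording(np.zeros((7, 100)), (
                "ctx", "stn_01", "stn_12", "stn_23",
                "gpi_01", "gpi_12", "gpi_23"))
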