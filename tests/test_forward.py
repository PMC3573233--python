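"""Spectral forward model: linearization, transfer functions, predicted CSDs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from bgdcm import circuit as circ
from bgdcm.circuit import ThetaVector, state_derivative
from bgdcm.forward import (
    CrossSpectralData,
    NoiseSpectrumParams,
    default_band_grid,
    linearize,
    predict_csd,
    source_potential_csd,
    state_transfer,
    transfer_matrix,
)
from bgdcm.synth import simulate_channels_timedomain


def _full_jacobian(ss):
    return ss.aggregate


class TestLinearize:
    def test_jacobian_matches_finite_differences(self, standard, theta0,
                                                 config):
        """The analytic zero-delay aggregate must equal a numerical
        differentiation of the state equations."""
        ss = linearize(standard, theta0, config=config)
        gains = circ.effective_gains(standard, theta0, "on")
        n = standard.n_states
        x0 = np.zeros(n)
        h = 1e-7
        J = np.zeros((n, n))
        for k in range(n):
            xp = x0.copy(); xp[k] += h
            xm = x0.copy(); xm[k] -= h
            J[:, k] = (state_derivative(standard, xp, 0.0, gains=gains)
                       - state_derivative(standard, xm, 0.0, gains=gains)) \
                / (2 * h)
        J_kept = J[np.ix_(ss.keep, ss.keep)]
        assert np.allclose(_full_jacobian(ss), J_kept, atol=1e-6)

    def test_zero_extrinsic_gains_block_diagonal_by_source(self, standard,
                                                           config):
        th = ThetaVector.zeros(standard)
        th.log_gain[:] = -40.0  # effectively zero coupling between sources
        ss = linearize(standard, th, config=config)
        A = _full_jacobian(ss)
        # map kept states back to their source
        src_of_state = np.repeat(
            [p.source for p in standard.populations], 4)[ss.keep]
        for i in range(A.shape[0]):
            for j in range(A.shape[1]):
                if src_of_state[i] != src_of_state[j]:
                    assert abs(A[i, j]) < 1e-10

    def test_stable_at_prior_mean_both_conditions(self, standard, theta_off,
                                                  config):
        for cond in ("on", "off"):
            ss = linearize(standard, theta_off, condition=cond, config=config)
            assert ss.is_stable()


class TestTransferMatrix:
    def test_high_frequency_rolloff(self, standard, theta0, config):
        ss = linearize(standard, theta0, config=config)
        t_mid = transfer_matrix(ss, 2 * np.pi * 30.0)
        t_high = transfer_matrix(ss, 2 * np.pi * 3000.0)
        assert np.linalg.norm(t_high) < 1e-2 * np.linalg.norm(t_mid)

    def test_uncoupled_source_matches_alpha_kernel_closed_form(self, config):
        """With all couplings silenced, the STN channel transfer from its own
        innovation is the analytic second-order kernel response."""
        cm = circ.build_standard_circuit(config)
        th = ThetaVector.zeros(cm)
        th.log_gain[:] = -40.0
        ss = linearize(cm, th, config=config)
        p = cm.params
        stn_ch = cm.channel_labels.index("stn")
        stn_innov = [i for i, pop in enumerate(cm.innovation_sites)
                     if pop.source == circ.STN][0]
        for f in (5.0, 19.0, 60.0):
            w = 2 * np.pi * f
            T = transfer_matrix(ss, w)
            # drive (kappa*He) through the alpha kernel 1/(iw+kappa)^2
            expected = p.kappa_e * p.He / (1j * w + p.kappa_e) ** 2
            assert T[stn_ch, stn_innov] == pytest.approx(expected, rel=1e-9)

    def test_matches_fft_of_simulated_impulse_response(self, standard,
                                                       theta0, config):
        """Simulation oracle: discretize the delay system, push an impulse
        through one innovation channel, FFT the response."""
        ss = linearize(standard, theta0, config=config)
        fs = 32000.0
        dt = 1.0 / fs
        n = 2 ** 16
        delays = [int(round(d / dt)) for d, _ in ss.delay_blocks]
        nst = ss.A0.shape[0]
        hist = np.zeros((max(delays) + 1, nst))
        x = np.zeros(nst)
        out = np.zeros((n, ss.C.shape[0]))
        head = 0
        for t in range(n):
            u = 1.0 / dt if t == 0 else 0.0
            lag_sum = np.zeros(nst)
            for lag, (_, Ad) in zip(delays, ss.delay_blocks):
                lag_sum += Ad @ hist[(head - lag) % (max(delays) + 1)]
            f1 = ss.A0 @ x + lag_sum + ss.B[:, 0] * u
            xp = x + dt * f1
            f2 = ss.A0 @ xp + lag_sum + ss.B[:, 0] * u
            x = x + 0.5 * dt * (f1 + f2)
            head = (head + 1) % (max(delays) + 1)
            hist[head] = x
            out[t] = ss.C @ x
        H_num = np.fft.rfft(out, axis=0) * dt
        freqs = np.fft.rfftfreq(n, dt)
        for f in (10.0, 20.0, 35.0):
            k = np.argmin(np.abs(freqs - f))
            T = transfer_matrix(ss, 2 * np.pi * freqs[k])[:, 0]
            assert np.allclose(H_num[k], T, rtol=0.01, atol=1e-9)

    def test_continuity_in_frequency(self, standard, theta0, config):
        ss = linearize(standard, theta0, config=config)
        w = 2 * np.pi * np.array([19.0, 19.0001])
        T = transfer_matrix(ss, w)
        assert np.max(np.abs(T[0] - T[1])) < 1e-4 * np.max(np.abs(T[0]))


class TestPredictCsd:
    def test_hermitian_exactly(self, standard, theta_off, config):
        csd = predict_csd(standard, theta_off, default_band_grid(config),
                          "off", config=config)
        assert csd.is_hermitian(tol=0.0)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_admissible_theta_gives_hermitian_psd(self, seed):
        cfg = circ.load_config()
        cm = circ.build_standard_circuit(cfg)
        rng = np.random.default_rng(seed)
        th = ThetaVector.zeros(cm)
        th.log_gain[:] = rng.normal(0, 0.1, th.log_gain.size)
        th.log_mod[:] = rng.normal(0, 0.1, th.log_mod.size)
        th.log_obs[:] = rng.normal(0, 0.3, th.log_obs.size)
        th.log_innov_white = rng.normal(0, 0.3)
        try:
            csd = predict_csd(cm, th, np.arange(13.0, 36.0), "off",
                              config=cfg)
        except circ.UnstableModelError:
            return  # inadmissible draw
        assert csd.is_hermitian(tol=0.0)
        eig = np.linalg.eigvalsh(csd.S)
        assert np.min(eig) >= -1e-18

    def test_channel_noise_only_gives_flat_diagonal(self, standard, config):
        th = ThetaVector.zeros(standard)
        th.log_obs[:] = -40.0  # silence the neuronal signal at the sensors
        noise = NoiseSpectrumParams(1e-2, 1e-12, 1.0, 1e-12)
        freqs = np.array([15.0, 25.0, 35.0])
        csd = predict_csd(standard, th, freqs, "on", noise=noise,
                          config=config)
        auto = csd.auto_spectra()
        assert np.allclose(auto, 1.0, rtol=1e-6)
        off_diag = csd.S[:, 0, 1]
        assert np.max(np.abs(off_diag)) < 1e-12

    def test_zero_delay_limit_equals_dense_linearization(self, config):
        import copy
        cfg = copy.deepcopy(config)
        cfg["delays"]["extrinsic_ms"] = 0.0
        cfg["delays"]["intrinsic_ms"] = 0.0
        cm = circ.build_standard_circuit(cfg)
        th = ThetaVector.zeros(cm)
        ss = linearize(cm, th, config=cfg)
        assert len(ss.delay_blocks) == 0  # all couplings folded into A0
        csd = predict_csd(cm, th, np.arange(13.0, 36.0), config=cfg)
        assert np.all(np.isfinite(csd.S))

    def test_source_permutation_leaves_channel_spectra_invariant(self,
                                                                 config):
        cm = circ.build_standard_circuit(config)
        perm = CrossSpectralData  # noqa: F841 (clarity)
        # permute population order while keeping all wiring identical
        order = np.r_[3:8, 0:3]
        pops = tuple(cm.populations[i] for i in order)
        cm2 = circ.CircuitModel(pops, cm.connections, cm.observation_map,
                                cm.innovation_sites, cm.params, cm.name)
        th = ThetaVector.zeros(cm)
        f = default_band_grid(config)
        s1 = predict_csd(cm, th, f, "off", config=config).S
        s2 = predict_csd(cm2, th, f, "off", config=config).S
        assert np.allclose(s1, s2, rtol=1e-10)

    def test_montecarlo_periodogram_matches_prediction(self, standard,
                                                       theta0, config):
        """Simulation oracle: Welch spectra of time-domain integration of
        the linearized stochastic system, 200 s, against the analytic CSD."""
        y, fs = simulate_channels_timedomain(theta0, "on", duration=200.0,
                                             seed=11, config=config,
                                             oversample=8)
        f, P = signal.csd(y[:, None, :], y[None, :, :], fs=fs, nperseg=4000,
                          axis=-1)
        m = (f >= 13) & (f <= 35)
        pred = predict_csd(standard, theta0, f[m], "on", config=config)
        for i in range(3):
            ratio = np.trapezoid(P[i, i, m].real, f[m]) \
                / np.trapezoid(pred.S[:, i, i].real, f[m])
            assert abs(ratio - 1) < 0.10
        for i, j in ((0, 1), (0, 2), (1, 2)):
            # scipy's csd convention is conj(X)*Y, the conjugate of ours
            num = np.conj(np.trapezoid(P[i, j, m], f[m]))
            den = np.trapezoid(pred.S[:, i, j], f[m])
            assert abs(num / den - 1) < 0.10


class TestSourceSpectra:
    def test_covers_all_sources_including_hidden(self, standard, theta0,
                                                 config):
        csd = source_potential_csd(standard, theta0,
                                   default_band_grid(config), config=config)
        assert tuple(csd.labels) == standard.sources
        assert np.all(csd.band_power() >= 0)

    def test_beta_attenuated_on_condition(self, standard, theta_off, config):
        f = default_band_grid(config)
        off = source_potential_csd(standard, theta_off, f, "off",
                                   config=config)
        on = source_potential_csd(standard, theta_off, f, "on",
                                  config=config)
        assert off.band_power().sum() > on.band_power().sum()


class TestCsdContainer:
    def test_hdf5_round_trip(self, standard, theta0, config, tmp_path):
        csd = predict_csd(standard, theta0, default_band_grid(config),
                          config=config)
        path = tmp_path / "csd.h5"
        csd.to_hdf5(path)
        back = CrossSpectralData.from_hdf5(path)
        assert np.allclose(back.S, csd.S)
        assert back.labels == csd.labels
        assert np.allclose(back.freqs, csd.freqs)
        assert tuple(back.band) == tuple(csd.band)

    def test_csv_long_format(self, standard, theta0, config, tmp_path):
        csd = predict_csd(standard, theta0, np.array([20.0, 21.0]),
                          config=config)
        path = tmp_path / "csd.csv"
        csd.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["f", "chan_i", "chan_j", "re", "im"]
        assert len(df) == 2 * 9

    def test_band_mask(self, standard, theta0, config):
        csd = predict_csd(standard, theta0, np.arange(5.0, 50.0),
                          config=config)
        assert np.all(csd.freqs[csd.band_mask] >= 13)
        assert np.all(csd.freqs[csd.band_mask] <= 35)
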