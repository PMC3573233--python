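"""Architecture wiring, activation function and state-equation checks."""

import json

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from bgdcm import circuit as circ
from bgdcm.circuit import (
    EXCITATORY_KINDS,
    CircuitModel,
    SubpopulationParams,
    ThetaVector,
    build_standard_circuit,
    build_variant,
    effective_gains,
    find_fixed_point,
    has_directed_walk,
    sigmoid_firing,
    state_derivative,
)


class TestArchitectures:
    def test_standard_has_nine_extrinsic_connections(self, standard):
        assert len(standard.extrinsic) == 9

    def test_cortex_has_three_layered_subpopulations(self, standard):
        cortex = [p for p in standard.populations if p.source == circ.CORTEX]
        assert sorted(p.kind for p in cortex) == sorted(
            [circ.SPINY_STELLATE, circ.PYRAMIDAL, circ.INTERNEURON])

    def test_subcortical_sources_are_single_masses(self, standard):
        for src in (circ.STRIATUM, circ.GPE, circ.STN, circ.GPI,
                    circ.THALAMUS):
            pops = [p for p in standard.populations if p.source == src]
            assert len(pops) == 1
            assert pops[0].kind in (circ.EXC_MASS, circ.INH_MASS)

    def test_key_connection_signs(self, standard):
        conn = {c.name: c for c in standard.extrinsic}
        assert conn["gpe_stn"].sign == -1
        assert conn["ctx_stn"].sign == +1
        assert conn["gpi_tha"].sign == -1
        assert conn["tha_ctx"].sign == +1

    def test_observed_and_hidden_sources(self, standard):
        assert set(standard.observed_sources) == {circ.CORTEX, circ.STN,
                                                  circ.GPI}
        assert set(standard.hidden_sources) == {circ.STRIATUM, circ.GPE,
                                                circ.THALAMUS}

    def test_deleting_stn_leaves_five_extrinsic(self, standard):
        sub = standard.without_source(circ.STN)
        assert len(sub.extrinsic) == 5

    @pytest.mark.parametrize("which,extra", [
        ("gpe_gpi", "gpe_gpi"), ("gpe_striatum", "gpe_str")])
    def test_extra_connection_variants(self, which, extra, config):
        cm = build_variant(which, config)
        assert len(cm.extrinsic) == 10
        c = cm.connections[cm.connection_index(extra)]
        assert c.sign == -1 and c.scope == "extrinsic"

    def test_pallidal_channel_variant_maps_to_gpe(self, config):
        cm = build_variant("pallidal_channel_to_gpe", config)
        assert len(cm.extrinsic) == 9
        assert set(cm.observed_sources) == {circ.CORTEX, circ.STN, circ.GPE}
        assert circ.GPI in cm.hidden_sources

    def test_unknown_variant_rejected(self, config):
        with pytest.raises(ValueError):
            build_variant("no_such_variant", config)

    def test_signs_follow_transmitter_in_all_architectures(self, config):
        for cm in circ.all_architectures(config).values():
            for c in cm.connections:
                expected = 1 if c.kind_from in EXCITATORY_KINDS else -1
                assert c.sign == expected

    def test_canonical_pathways_exist_as_directed_walks(self, standard):
        direct = (circ.CORTEX, circ.STRIATUM, circ.GPI)
        indirect = (circ.CORTEX, circ.STRIATUM, circ.GPE, circ.STN, circ.GPI)
        hyperdirect = (circ.CORTEX, circ.STN)
        loop_return = (circ.GPI, circ.THALAMUS, circ.CORTEX)
        for path in (direct, indirect, hyperdirect, loop_return):
            assert has_directed_walk(standard, path)

    def test_json_round_trip_is_lossless(self, standard, tmp_path):
        path = tmp_path / "circuit.json"
        standard.to_json(path)
        loaded = CircuitModel.from_json(path)
        assert loaded == standard

    def test_json_version_mismatch_rejected(self, standard, tmp_path):
        d = standard.to_dict()
        d["version"] = 99
        with pytest.raises(ValueError, match="version"):
            CircuitModel.from_dict(d)


class TestSigmoid:
    def test_zero_at_baseline(self, standard):
        assert sigmoid_firing(0.0, standard.params) == pytest.approx(0.0)

    def test_saturates_at_finite_maximum(self, standard):
        p = standard.params
        top = sigmoid_firing(1e6, p)
        assert np.isfinite(top)
        assert sigmoid_firing(1e7, p) == pytest.approx(top)

    def test_monotone_nondecreasing(self, standard):
        v = np.linspace(-50, 50, 1001)
        s = sigmoid_firing(v, standard.params)
        assert np.all(np.diff(s) >= 0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SubpopulationParams(He=-1.0)
        with pytest.raises(ValueError):
            SubpopulationParams(kappa_e=0.0)


class TestStateEquations:
    def test_origin_is_fixed_point_at_zero_input(self, standard):
        x0 = np.zeros(standard.n_states)
        dx = state_derivative(standard, x0, 0.0)
        assert np.linalg.norm(dx) == 0.0

    def test_dimension_mismatch_rejected(self, standard):
        with pytest.raises(ValueError):
            state_derivative(standard, np.zeros(5), 0.0)

    def test_isolated_population_impulse_follows_alpha_kernel(self, config):
        """An isolated mass driven by an impulse must trace H*k*t*exp(-k*t),
        peaking at t = 1/kappa_e."""
        cm = build_standard_circuit(config)
        gains = np.zeros(len(cm.connections))
        p = cm.params
        x = np.zeros(cm.n_states)
        # impulse: set z_e of the cortical input layer to kappa_e*He
        # (the state reached after an instantaneous unit rate impulse)
        i = cm.population_index(circ.CORTEX, circ.SPINY_STELLATE)
        x[4 * i + 1] = p.kappa_e * p.He

        sol = solve_ivp(
            lambda t, xx: state_derivative(cm, xx, 0.0, gains=gains),
            (0, 0.05), x, t_eval=np.linspace(0, 0.05, 201), rtol=1e-9,
            atol=1e-12)
        v = sol.y[4 * i]
        expected = p.He * p.kappa_e * sol.t * np.exp(-p.kappa_e * sol.t)
        assert np.allclose(v, expected, rtol=1e-5, atol=1e-9)
        assert sol.t[np.argmax(v)] == pytest.approx(1.0 / p.kappa_e,
                                                    rel=0.02)

    def test_zero_amplitudes_decay_to_rest(self, config):
        cm = build_standard_circuit(config)
        params = SubpopulationParams(He=1e-12, Hi=1e-12)
        cm = circ.replace_params(cm, params) if hasattr(circ, "replace_params") \
            else CircuitModel(cm.populations, cm.connections,
                              cm.observation_map, cm.innovation_sites,
                              params, cm.name)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(cm.n_states)
        sol = solve_ivp(lambda t, xx: state_derivative(cm, xx, 0.0),
                        (0, 0.5), x, rtol=1e-8, atol=1e-12)
        assert np.linalg.norm(sol.y[:, -1]) < 1e-3 * np.linalg.norm(x)

    def test_amplitude_homogeneity_of_accelerations(self, standard, config):
        """z-dot terms scale linearly in (He, Hi) at fixed firing input."""
        x = np.zeros(standard.n_states)
        x[::4] = 0.05  # small depolarisations
        dx1 = state_derivative(standard, x, 0.3)
        p2 = SubpopulationParams(He=2 * standard.params.He,
                                 Hi=2 * standard.params.Hi,
                                 kappa_e=standard.params.kappa_e,
                                 kappa_i=standard.params.kappa_i)
        cm2 = CircuitModel(standard.populations, standard.connections,
                           standard.observation_map,
                           standard.innovation_sites, p2, standard.name)
        dx2 = state_derivative(cm2, x, 0.3)
        # drive enters only the z-equations; subtract the kernel leak terms
        for i in range(len(standard.populations)):
            for off, kap in ((1, standard.params.kappa_e),
                             (3, standard.params.kappa_i)):
                row = 4 * i + off
                leak = -2 * kap * x[row] - kap ** 2 * x[row - 1]
                assert dx2[row] - leak == pytest.approx(
                    2 * (dx1[row] - leak), rel=1e-9, abs=1e-12)


class TestFixedPoint:
    def test_zero_input_returns_origin(self, standard):
        x0 = find_fixed_point(standard, 0.0)
        assert np.all(x0 == 0.0)

    def test_constant_input_root_has_small_residual(self, standard):
        x0 = find_fixed_point(standard, 0.05)
        res = np.linalg.norm(state_derivative(standard, x0, 0.05))
        assert res < 1e-8

    def test_fixed_point_matches_long_integration(self, standard):
        """Independent oracle: the ODE endpoint after a long horizon."""
        u0 = 0.05
        x0 = find_fixed_point(standard, u0)
        sol = solve_ivp(lambda t, xx: state_derivative(standard, xx, u0),
                        (0, 3.0), np.zeros(standard.n_states),
                        rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[:, -1], x0, atol=1e-4)


class TestEffectiveGains:
    def test_modulators_scale_off_only(self, standard, theta_off):
        g_on = effective_gains(standard, theta_off, "on")
        g_off = effective_gains(standard, theta_off, "off")
        names = [c.name for c in standard.connections]
        for j, name in enumerate(names):
            if name in ("ctx_stn", "gpe_stn", "stn_gpi"):
                assert g_off[j] == pytest.approx(1.5 * g_on[j])
            else:
                assert g_off[j] == pytest.approx(g_on[j])

    def test_unknown_condition_rejected(self, standard, theta0):
        with pytest.raises(ValueError):
            effective_gains(standard, theta0, "half_on")


class TestThetaVector:
    def test_pack_unpack_round_trip(self, standard):
        rng = np.random.default_rng(3)
        th = ThetaVector.zeros(standard)
        vec = rng.standard_normal(th.pack().size)
        th2 = ThetaVector.unpack(vec, standard)
        assert np.allclose(th2.pack(), vec)

    def test_names_align_with_vector(self, standard, theta0):
        names = theta0.names(standard)
        assert len(names) == theta0.pack().size
        sl = theta0.modulator_slice(standard)
        assert all(n.startswith("mod:") for n in names[sl])
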