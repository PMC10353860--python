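"""Spiking circuit: drives, rates, plasticity, gain homeostasis, decoding."""

import numpy as np
import pytest

import rdwm.circuit as circuit
from rdwm.channel import DistortionMatrix, Source, StimulusGrid, blahut_arimoto, \
    mutual_information
from rdwm.circuit import (
    CircuitParams,
    CircuitState,
    decode_ml,
    excitatory_input,
    firing_rates,
    information_rate,
    run_session,
    run_trial,
    sample_spikes,
    update_excitability,
    update_gain,
)
from rdwm.paradigms import gen_serialdep_session


@pytest.fixture
def params():
    return CircuitParams()


@pytest.fixture
def state(params):
    return CircuitState.init(params, n_subpops=1)


class TestDefaults:
    def test_plasticity_gain_default_matches_marginal_fixed_point(self, params):
        # exp(w*) = c * E[z] = c * r_bar * dt * marginal; c = 1/(r_bar*dt)
        # makes w converge to the log marginal winner probability
        assert params.c == pytest.approx(1.0 / (params.r_bar * params.dt))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CircuitParams(dt=0.0)
        with pytest.raises(ValueError):
            CircuitParams(c=-1.0)


class TestExcitatoryInput:
    def test_zero_gain_returns_excitability(self, params, state):
        state.beta = 0.0
        u = excitatory_input(state, [0.3], params)
        assert np.allclose(u, state.w)

    def test_cosine_drive_sign(self, params):
        st = CircuitState.init(params, 1, w0=0.0)
        st.w[:] = 0.0
        st.beta = 1.0
        u = excitatory_input(st, [0.0], params, probe_probs=[1.0])
        assert np.allclose(u[0], np.cos(0.0 - st.phi))

    def test_probe_probability_scales_drive(self, params):
        st = CircuitState.init(params, 4, w0=0.0)
        st.w[:] = 0.0
        st.beta = 2.0
        u4 = excitatory_input(st, [0.5] * 4, params)  # pi_m = 1/4
        st1 = CircuitState.init(params, 1, w0=0.0)
        st1.w[:] = 0.0
        st1.beta = 2.0
        u1 = excitatory_input(st1, [0.5], params, probe_probs=[1.0])
        assert np.allclose(u4[0], u1[0] / 4.0)

    def test_set_size_mismatch_raises(self, params, state):
        with pytest.raises(ValueError):
            excitatory_input(state, [0.1, 0.2], params)


class TestFiringRates:
    def test_equal_drive_uniform(self):
        r = firing_rates(np.zeros(7))
        assert np.allclose(r, 1 / 7)

    def test_two_neuron_logit(self):
        r = firing_rates(np.array([0.0, np.log(3.0)]))
        assert np.allclose(r, [0.25, 0.75])

    def test_shift_invariance_and_normalization(self):
        rng = np.random.default_rng(0)
        u = rng.normal(0, 5, (3, 40))
        r = firing_rates(u)
        assert np.allclose(r.sum(axis=-1), 1.0, atol=1e-12)
        assert np.allclose(firing_rates(u + 17.3), r, atol=1e-12)


class TestSampleSpikes:
    def test_zero_rate_scale(self, params):
        p0 = CircuitParams(r_bar=0.0)
        z = sample_spikes(np.full(10, 0.1), p0, np.random.default_rng(0))
        assert np.all(z == 0)

    def test_concentrated_rate_only_one_neuron(self, params):
        r = np.zeros(10)
        r[0] = 1.0
        z = sample_spikes(r, params, np.random.default_rng(1))
        assert np.all(z[1:] == 0)

    def test_poisson_moments(self, params):
        """Empirical spike counts match the Poisson mean r_bar*r*dt."""
        rng = np.random.default_rng(2)
        r = np.full(100, 0.01)
        draws = np.array([sample_spikes(r, params, rng) for _ in range(2000)])
        expected = params.r_bar * 0.01 * params.dt  # 0.025
        se = np.sqrt(expected / (2000 * 100))
        assert draws.mean() == pytest.approx(expected, abs=3 * se)


class TestUpdateExcitability:
    def test_spike_branch_fixed_point(self, params):
        w = np.array([np.log(params.c)])
        z = np.ones(1)
        assert update_excitability(w, z, params) == pytest.approx(w)

    def test_no_spike_decrement(self, params):
        w = np.array([-3.0])
        w2 = update_excitability(w, np.zeros(1), params)
        assert w2[0] == pytest.approx(-3.0 - params.eta * params.dt)

    def test_clipping(self, params):
        w = np.array([params.w_clip[0] + 1e-9])
        assert update_excitability(w, np.zeros(1), params)[0] == params.w_clip[0]

    def test_stationary_point_is_log_of_c_times_mean_rate(self, params):
        """Under Bernoulli(p) spiking, E[dw] = 0 at exp(w) = c*p."""
        rng = np.random.default_rng(3)
        p_spike = 0.3
        # use an unclipped parameter set so the fixed point is interior
        pr = CircuitParams(w_clip=(-12.0, 5.0), eta=0.5)
        w = np.array([-1.0])
        for _ in range(4000):
            z = rng.binomial(1, p_spike, size=1)
            w = update_excitability(w, z, pr)
        assert np.exp(w[0]) == pytest.approx(pr.c * p_spike, rel=0.25)


class TestInformationRate:
    def test_zero_gain_zero_rate(self, params, state):
        state.beta = 0.0
        assert information_rate(state, params) == pytest.approx(0.0, abs=1e-12)

    def test_high_gain_approaches_log_K(self, params):
        st = CircuitState.init(CircuitParams(N=16), 1, grid_K=16)
        st.w[:] = 0.0
        st.beta = 500.0
        p16 = CircuitParams(N=16)
        assert information_rate(st, p16) == pytest.approx(np.log(16), abs=0.05)

    def test_matches_rd_core_channel_mutual_information(self):
        """Cross-module consistency: the circuit's information rate equals
        the mutual information of the BA channel at the same gain when w
        holds the log marginal."""
        K = 16
        p16 = CircuitParams(N=K)
        st = CircuitState.init(p16, 1, grid_K=K)
        grid = StimulusGrid(K)
        src = Source(grid)
        ch = blahut_arimoto(src, DistortionMatrix(grid), 2.0, tol=1e-13)
        st.w[0] = np.log(ch.marginal)
        st.beta = 2.0
        assert information_rate(st, p16, probe_probs=[1.0]) == pytest.approx(
            mutual_information(ch), abs=1e-8)

    def test_numba_and_numpy_kernels_agree(self, params):
        if circuit._winner_mi_nb is None:
            pytest.skip("numba unavailable")
        st = CircuitState.init(params, 2)
        st.w += np.random.default_rng(4).normal(0, 0.5, st.w.shape)
        bop = np.array([3.1, 1.7])
        prior = np.full(st.grid.K, 1.0 / st.grid.K)
        a = circuit._winner_mi_nb(bop, st.cosmat, st.w, prior)
        b = circuit._winner_mi_numpy(bop, st.cosmat, st.w, prior)
        assert a == pytest.approx(b, abs=1e-12)
        cosg = np.cos(2 * np.pi * np.arange(st.grid.K) / st.grid.K)
        c = circuit._winner_mi_circ_nb(bop, st.w, cosg, prior)
        assert c == pytest.approx(b, abs=1e-12)


class TestUpdateGain:
    def test_at_setpoint_no_change(self, params):
        C_eff = params.C * 2.0
        assert update_gain(5.0, C_eff, params, 1.0, 1.0) == pytest.approx(5.0)

    def test_below_capacity_increases(self, params):
        assert update_gain(5.0, 0.5, params, 1.0, 1.0) > 5.0

    def test_clipped_at_bounds(self, params):
        assert update_gain(params.beta_clip[1], -10.0, params, 1.0, 0.0) == \
            params.beta_clip[1]


class TestDecodeML:
    def test_all_spikes_at_preferred_zero(self, params, state):
        counts = np.zeros(params.N, dtype=int)
        i0 = int(np.argmin(np.abs(state.phi - 0.0)))
        counts[i0] = 20
        theta, flag = decode_ml(counts, state, params, 0, 1.0, np.random.default_rng(0))
        assert not flag
        assert theta == pytest.approx(state.phi[i0])

    def test_symmetric_counts_decode_to_axis(self, params, state):
        i0 = int(np.argmin(np.abs(state.phi - np.pi / 2)))
        counts = np.zeros(params.N, dtype=int)
        counts[i0 - 3] = 5
        counts[i0 + 3] = 5
        counts[i0] = 1
        theta, _ = decode_ml(counts, state, params, 0, 1.0, np.random.default_rng(0))
        assert theta == pytest.approx(state.phi[i0])

    def test_zero_spikes_flagged_random(self, params, state):
        theta, flag = decode_ml(np.zeros(params.N, dtype=int), state, params, 0, 1.0,
                                np.random.default_rng(5))
        assert flag
        assert theta in state.grid.centers

    def test_higher_gain_reduces_decode_variance(self, params):
        """Decoding noise shrinks as the gain sharpens the code."""
        rng = np.random.default_rng(6)
        out = {}
        for beta in (2.0, 20.0):
            st = CircuitState.init(params, 1)
            st.beta = beta
            errs = []
            for _ in range(500):
                u = beta * np.cos(0.0 - st.phi) + st.w[0]
                r = np.exp(u - u.max())
                r /= r.sum()
                counts = rng.poisson(200 * r)
                th, _ = decode_ml(counts, st, params, 0, 1.0, rng)
                errs.append(th)
            out[beta] = np.var(errs)
        assert out[20.0] < out[2.0]


class TestRunTrial:
    def test_fixed_gain_keeps_beta(self, params):
        st = CircuitState.init(params, 1)
        b0 = st.beta
        run_trial([0.2], 0, 1.0, 1.0, st, params, np.random.default_rng(0),
                  variant="fixed_gain")
        assert st.beta == b0

    def test_no_plasticity_keeps_w(self, params):
        st = CircuitState.init(params, 1)
        w0 = st.w.copy()
        run_trial([0.2], 0, 1.0, 1.0, st, params, np.random.default_rng(0),
                  variant="no_plasticity")
        assert np.array_equal(st.w, w0)

    def test_full_model_updates_both(self, params):
        st = CircuitState.init(params, 1)
        b0, w0 = st.beta, st.w.copy()
        rec = run_trial([0.2], 0, 1.0, 1.0, st, params, np.random.default_rng(0))
        assert st.beta != b0
        assert not np.array_equal(st.w, w0)
        assert abs(rec["error"]) <= np.pi

    def test_zero_ri_decodes_immediately(self, params):
        st = CircuitState.init(params, 1)
        rec = run_trial([0.2], 0, 0.0, 1.0, st, params, np.random.default_rng(0))
        assert rec["ri_s"] == 0.0

    def test_negative_ri_rejected(self, params):
        st = CircuitState.init(params, 1)
        with pytest.raises(ValueError):
            run_trial([0.2], 0, -1.0, 1.0, st, params, np.random.default_rng(0))

    def test_invalid_variant_rejected(self, params):
        st = CircuitState.init(params, 1)
        with pytest.raises(ValueError):
            run_trial([0.2], 0, 1.0, 1.0, st, params, np.random.default_rng(0),
                      variant="nope")


class TestRunSession:
    def test_empty_session(self, params):
        spec = gen_serialdep_session(0, seed=0)
        spec.n_trials = 0
        table = run_session(spec, params, seed=0)
        assert len(table) == 0

    def test_seed_determinism(self, params):
        spec = gen_serialdep_session(30, ri_levels=(1.0,), seed=3)
        t1 = run_session(spec, params, seed=7)
        t2 = run_session(spec, params, seed=7)
        assert t1.equals(t2)

    def test_different_seed_differs(self, params):
        spec = gen_serialdep_session(30, ri_levels=(1.0,), seed=3)
        t1 = run_session(spec, params, seed=7)
        t2 = run_session(spec, params, seed=8)
        assert not t1["response"].equals(t2["response"])

    def test_errors_wrapped_and_beta_within_clip(self, params):
        spec = gen_serialdep_session(50, ri_levels=(1.0,), seed=4)
        t = run_session(spec, params, seed=9)
        assert np.all(np.abs(t["error"]) <= np.pi)
        assert np.all((t["beta"] >= params.beta_clip[0])
                      & (t["beta"] <= params.beta_clip[1]))

    def test_set_size_effect_on_error_variance(self, params):
        """More simultaneously stored items -> lower precision."""
        from rdwm.behavior import circ_variance
        from rdwm.paradigms import SessionSpec

        out = {}
        for M in (1, 4):
            rng = np.random.default_rng(10 + M)
            spec = SessionSpec(300, np.full(300, M),
                               rng.uniform(-np.pi, np.pi, (300, M)),
                               rng.integers(M, size=300), np.full(300, -1),
                               np.full(300, 1.0), np.full(300, 1.0))
            t = run_session(spec, params, seed=11)
            out[M] = circ_variance(t["error"])
        assert out[4] > out[1]

    def test_trace_records_beta_and_rate(self, params):
        spec = gen_serialdep_session(5, ri_levels=(1.0,), seed=5)
        trace = []
        run_session(spec, params, seed=12, trace=trace, trace_every=5)
        assert len(trace) > 0
        steps, betas, rates = zip(*trace)
        assert all(np.isfinite(betas))
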