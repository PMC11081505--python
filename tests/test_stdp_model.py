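"""Unit and property tests for the coincidence-detector STDP model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msodev.stdp_model import (
    ModelParams,
    ModelNeuron,
    STDPKernel,
    SynapticInput,
    apply_update,
    epsp_trace,
    firing_rate,
    init_neuron,
    itd_rate_curve,
    kernel_extrema,
    kernel_t_off,
    membrane_potential,
    run_population_experiment,
    stdp_kernel,
    train_neuron,
)

ZC = (5.0 / 9.0) * math.log(2.5)  # kernel zero-crossing lag after t_off


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


class TestInitNeuron:
    def test_default_input_count_and_weights(self, params):
        n = init_neuron(1.8, params, seed=0)
        assert len(n.inputs) == 60
        sides = [i.side for i in n.inputs]
        assert sides.count("ipsi") == 30 and sides.count("contra") == 30
        np.testing.assert_allclose(n.weights, 1.0 / 60.0)

    def test_zero_gamma_gives_exact_best_freq(self):
        p = ModelParams(gamma=0.0)
        n = init_neuron(1.2, p, seed=1)
        assert all(inp.freq == 1.2 for inp in n.inputs)

    def test_deterministic_latencies_equal_offsets(self, quiet_params):
        n = init_neuron(1.8, quiet_params, seed=2)
        for inp in n.inputs:
            expected = 5.0 if inp.side == "ipsi" else 5.3
            assert inp.latency == pytest.approx(expected)

    @pytest.mark.parametrize("bad_freq", [0.0, -1.0])
    def test_rejects_nonpositive_best_freq(self, params, bad_freq):
        with pytest.raises(ValueError):
            init_neuron(bad_freq, params, seed=0)

    def test_rejects_gamma_that_could_flip_frequency_sign(self):
        with pytest.raises(ValueError, match="gamma"):
            ModelParams(gamma=2.0)


# ---------------------------------------------------------------------------
# EPSP and membrane potential
# ---------------------------------------------------------------------------


class TestEpsp:
    def test_causality_peak_and_decay(self):
        tau = 0.35
        inp = SynapticInput(side="ipsi", freq=1.0, latency=5.0, weight=0.25)
        t = np.arange(0.0, 12.0, 0.001)
        v = epsp_trace(inp, 0.0, t, tau)
        assert np.all(v[t < 5.0] == 0.0)
        peak_idx = np.argmin(np.abs(t - (5.0 + tau)))
        assert v[peak_idx] == pytest.approx(0.25, rel=1e-5)
        at_2tau = v[np.argmin(np.abs(t - (5.0 + 2 * tau)))]
        assert at_2tau == pytest.approx(0.25 * 2 * math.exp(-1), rel=1e-4)

    def test_onset_shift_moves_the_trace(self):
        inp = SynapticInput(side="ipsi", freq=1.0, latency=5.0, weight=1.0)
        t = np.arange(0.0, 12.0, 0.01)
        v0 = epsp_trace(inp, 0.0, t, 0.35)
        v1 = epsp_trace(inp, 0.5, t, 0.35)
        shift = int(round(0.5 / 0.01))
        np.testing.assert_allclose(v1[shift:], v0[:-shift], atol=1e-12)


class TestMembranePotential:
    def test_zero_weights_zero_potential(self, quiet_params):
        n = init_neuron(1.8, quiet_params, seed=0)
        n.weights = np.zeros(60)
        assert np.all(membrane_potential(n, 0.0) == 0.0)

    def test_single_input_matches_its_epsp(self, quiet_params):
        n = init_neuron(1.8, quiet_params, seed=0)
        w = np.zeros(60)
        w[3] = 1.0
        n.weights = w
        t = quiet_params.t_grid
        vm = membrane_potential(n, 0.0)
        single = epsp_trace(n.inputs[3], 0.0, t, quiet_params.tau_EPSP)
        np.testing.assert_allclose(vm, single, atol=1e-12)

    def test_linearity_two_identical_inputs(self, quiet_params):
        n = init_neuron(1.8, quiet_params, seed=0)
        w = np.zeros(60)
        w[0] = 0.3
        n.weights = w
        v1 = membrane_potential(n, 0.0).copy()
        w2 = np.zeros(60)
        w2[0], w2[1] = 0.3, 0.3  # both ipsi at the same 5.0-ms latency
        n.weights = w2
        v2 = membrane_potential(n, 0.0)
        np.testing.assert_allclose(v2, 2 * v1, atol=1e-12)

    def test_positive_itd_delays_ipsilateral_onsets(self, quiet_params):
        n = init_neuron(1.8, quiet_params, seed=0)
        w = np.zeros(60)
        w[0] = 1.0  # an ipsilateral input
        n.weights = w
        v0 = membrane_potential(n, 0.0)
        v_shift = membrane_potential(n, 0.2)
        k = int(round(0.2 / quiet_params.dt))
        np.testing.assert_allclose(v_shift[k:], v0[:-k], atol=1e-12)


class TestFiringRate:
    def test_normalization_endpoints(self, params):
        r = firing_rate(np.array([0.0, params.total_weight]), params)
        assert r[0] == pytest.approx(0.0, abs=1e-12)
        assert r[1] == pytest.approx(params.R_max, rel=1e-12)

    def test_strictly_increasing(self, params):
        v = np.linspace(0, 1, 101)
        r = firing_rate(v, params)
        assert np.all(np.diff(r) > 0)

    def test_degenerate_normalization_rejected(self):
        with pytest.raises(ValueError):
            firing_rate(np.array([0.5]), ModelParams(k_E=1e6, v_c=-50.0))


# ---------------------------------------------------------------------------
# ITD tuning of the untrained neuron
# ---------------------------------------------------------------------------


def _brute_force_bitd(neuron, itds, dt=0.005):
    """Independent oracle: expected firing per ITD from per-input EPSP
    traces summed explicitly on a fine grid."""
    p = neuron.params
    t = np.arange(0.0, 15.0, dt)
    rates = []
    for itd in itds:
        vm = np.zeros_like(t)
        for inp in neuron.inputs:
            shift = itd if inp.side == "ipsi" else 0.0
            vm += epsp_trace(inp, shift, t, p.tau_EPSP)
        r = firing_rate(vm, p)
        rates.append(r.sum() * dt / p.integration_window)
    rates = np.array(rates)
    return itds[np.argmax(rates)]


class TestItdRateCurve:
    def test_symmetric_neuron_peaks_at_zero(self):
        p = ModelParams(l_offset_contra=5.0, l_SD=0.0, phi_low=0, phi_high=0, t_SD=0)
        n = init_neuron(1.8, p, seed=0)
        assert itd_rate_curve(n).bitd == pytest.approx(0.0, abs=1e-12)

    def test_default_offsets_give_plus_300_us(self, quiet_params):
        n = init_neuron(1.8, quiet_params, seed=0)
        assert itd_rate_curve(n).bitd == pytest.approx(0.3, abs=1e-9)

    def test_agrees_with_brute_force_oracle(self, params):
        n = init_neuron(1.2, params, seed=7)
        curve = itd_rate_curve(n)
        oracle = _brute_force_bitd(n, np.arange(-1.5, 1.5001, 0.05))
        assert abs(curve.bitd - oracle) <= 0.05 + 1e-9  # oracle grid is coarser

    def test_untrained_population_mean_near_offset_difference(self, params):
        bitds = [itd_rate_curve(init_neuron(1.8, params, seed=s)).bitd
                 for s in range(20)]
        assert 0.2 < np.mean(bitds) < 0.5


# ---------------------------------------------------------------------------
# STDP kernel
# ---------------------------------------------------------------------------


class TestKernel:
    def test_continuity_at_t_off(self, kernel, params):
        t_off = kernel_t_off(kernel, params.tau_EPSP)
        below = stdp_kernel(t_off - 1e-9, kernel, params.tau_EPSP)
        at = stdp_kernel(t_off, kernel, params.tau_EPSP)
        assert at == pytest.approx(0.3, abs=1e-6)
        assert below == pytest.approx(at, abs=1e-6)

    @pytest.mark.parametrize("ts", [1.0, 2.0, 3.0, 6.0, 10.0])
    def test_zero_crossing_location(self, ts, params):
        k = STDPKernel(t_scaling=ts)
        t_off = kernel_t_off(k, params.tau_EPSP)
        zc = t_off + ZC * ts
        eps = 1e-7
        assert stdp_kernel(zc - eps, k, params.tau_EPSP) > 0
        assert stdp_kernel(zc + eps, k, params.tau_EPSP) < 0

    def test_single_sign_change_after_t_off(self, kernel, params):
        t_off = kernel_t_off(kernel, params.tau_EPSP)
        t = t_off + np.arange(0.0, 60.0, 0.001)
        vals = stdp_kernel(t, kernel, params.tau_EPSP)
        assert np.sum(np.diff(np.sign(vals)) != 0) == 1

    def test_extrema_separation_approx_1_8_ms(self, kernel, params):
        ex = kernel_extrema(kernel, params.tau_EPSP)
        assert ex["separation"] == pytest.approx((5 / 9) * math.log(25), abs=1e-4)
        assert ex["max_potentiation"] == pytest.approx(0.3, abs=1e-9)
        assert ex["max_depression"] == pytest.approx(-0.1259, abs=1e-3)

    def test_extrema_scale_linearly_with_t_scaling(self, params):
        e1 = kernel_extrema(STDPKernel(t_scaling=1.0), params.tau_EPSP)
        e2 = kernel_extrema(STDPKernel(t_scaling=2.0), params.tau_EPSP)
        off1 = e1["t_max_depression"] - e1["t_max_potentiation"]
        off2 = e2["t_max_depression"] - e2["t_max_potentiation"]
        assert off2 == pytest.approx(2 * off1, rel=1e-4)

    def test_alignment_shift(self, params):
        tau = params.tau_EPSP
        assert kernel_t_off(STDPKernel(alignment="peak"), tau) == pytest.approx(-0.05 - tau)
        k6 = STDPKernel(alignment="zero_crossing", t_scaling=6.0)
        assert kernel_t_off(k6, tau) == pytest.approx(-0.05 - tau - 5 * ZC)

    def test_ablated_variants_have_one_lobe(self, params):
        t = np.arange(-10, 40, 0.01)
        pot = stdp_kernel(t, STDPKernel(variant="potentiation_only"), params.tau_EPSP)
        dep = stdp_kernel(t, STDPKernel(variant="depression_only"), params.tau_EPSP)
        assert np.all(pot >= 0) and pot.max() > 0
        assert np.all(dep <= 0) and dep.min() < 0

    def test_ablated_extrema_reported_absent(self, params):
        ex = kernel_extrema(STDPKernel(variant="potentiation_only"), params.tau_EPSP)
        assert ex["t_max_depression"] is None and ex["separation"] is None

    def test_nonpositive_scaling_rejected(self):
        with pytest.raises(ValueError):
            STDPKernel(t_scaling=0.0)


# ---------------------------------------------------------------------------
# plasticity updates
# ---------------------------------------------------------------------------


class TestApplyUpdate:
    def test_weight_conservation(self, params, kernel, default_neuron):
        rng = np.random.default_rng(0)
        for _ in range(20):
            apply_update(default_neuron, 0.0, kernel, params, rng)
            assert default_neuron.weights.sum() == pytest.approx(
                params.total_weight, abs=1e-9
            )
            assert np.all(default_neuron.weights >= 0)

    def test_zero_kernel_leaves_weights_unchanged(self, params, default_neuron):
        dead = STDPKernel(a_pre=0.0, a_fast=0.0, a_slow=0.0)
        w0 = default_neuron.weights
        diag = apply_update(default_neuron, 0.0, dead, params, np.random.default_rng(0))
        assert not diag["applied"]
        np.testing.assert_array_equal(default_neuron.weights, w0)

    def test_out_of_reach_input_gets_zero_raw_change(self, quiet_params):
        # one ipsi input far earlier than everything else: beyond the kernel
        # support relative to all supra-threshold firing
        n = init_neuron(1.8, quiet_params, seed=0)
        n.inputs[0].latency = 0.5
        w = np.full(60, 1.0 / 60.0)
        n.weights = w
        k = STDPKernel()
        diag = apply_update(n, 0.0, k, quiet_params, np.random.default_rng(0))
        assert diag["applied"]
        dw = diag["dw"]
        # oracle: explicit correlation of the thresholded rate with the kernel
        t = quiet_params.t_grid
        vm = np.zeros_like(t)
        for inp, wi in zip(n.inputs, w):
            inp_w = SynapticInput(inp.side, inp.freq, inp.latency, wi)
            vm += epsp_trace(inp_w, 0.0, t, quiet_params.tau_EPSP)
        r = firing_rate(vm, quiet_params)
        r_thr = np.where(r >= quiet_params.r_min, r, 0.0)
        for i in (0, 5, 40):
            onset = n.inputs[i].latency
            expect = np.sum(
                r_thr * stdp_kernel(onset - t, k, quiet_params.tau_EPSP)
            ) * quiet_params.dt
            assert dw[i] == pytest.approx(expect, rel=1e-9, abs=1e-15)
        # ~5 ms ahead of all firing: raw change negligible next to the rest
        assert abs(dw[0]) < 1e-3 * np.abs(dw).max()

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000), itd=st.floats(-0.5, 0.5))
    def test_conservation_property(self, seed, itd):
        p = ModelParams()
        n = init_neuron(1.0, p, seed=seed)
        apply_update(n, itd, STDPKernel(), p, np.random.default_rng(seed))
        assert n.weights.sum() == pytest.approx(p.total_weight, abs=1e-9)
        assert np.all(n.weights >= 0)


class TestTrainNeuron:
    def test_zero_updates_leaves_initial_weights(self, params, kernel):
        n = init_neuron(1.8, params, seed=3)
        w0 = n.weights
        res = train_neuron(n, (-0.13, 0.13), 0, kernel, params, seed=3)
        np.testing.assert_array_equal(n.weights, w0)
        assert res.bitd_trajectory == []

    def test_checkpoint_schedule(self, params, kernel):
        n = init_neuron(1.8, params, seed=3)
        res = train_neuron(n, (-0.13, 0.13), 200, kernel, params, seed=3,
                           checkpoints=(1, 100, 200, 999))
        assert res.checkpoints == [1, 100, 200]
        assert len(res.bitd_trajectory) == 3

    def test_fixed_seed_bit_identical(self, params, kernel):
        results = []
        for _ in range(2):
            n = init_neuron(1.8, params, seed=11)
            res = train_neuron(n, (-0.13, 0.13), 50, kernel, params, seed=12,
                               checkpoints=(25, 50))
            results.append((n.weights, res.bitd_trajectory))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        assert results[0][1] == results[1][1]

    def test_bitd_stays_on_itd_grid(self, params, kernel):
        n = init_neuron(1.8, params, seed=5)
        res = train_neuron(n, (-0.13, 0.13), 100, kernel, params, seed=5,
                           checkpoints=(50, 100))
        for b in res.bitd_trajectory:
            assert params.itd_grid.min() <= b <= params.itd_grid.max()


class TestPopulationExperiment:
    def test_row_counts_and_reproducibility(self):
        config = dict(
            groups=[{"best_freq": 1.8, "n_neurons": 2},
                    {"best_freq": 0.9, "n_neurons": 2}],
            teacher_range=[-0.13, 0.13],
            n_updates=20,
            checkpoints=[10, 20],
            seed=9,
        )
        res1 = run_population_experiment(config)
        res2 = run_population_experiment(config)
        # one row per neuron at update 0 plus one per checkpoint
        assert len(res1["neurons"]) == 4 * 3
        assert len(res1["weights"]) == 4 * 60
        assert res1["neurons"].equals(res2["neurons"])
        assert res1["weights"].equals(res2["weights"])

    def test_invalid_group_rejected_before_simulation(self):
        with pytest.raises(ValueError):
            run_population_experiment(
                dict(groups=[{"best_freq": -1.0, "n_neurons": 5}],
                     teacher_range=[-0.13, 0.13])
            )
        with pytest.raises(ValueError):
            run_population_experiment(dict(groups=[], teacher_range=[0, 0.1]))
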