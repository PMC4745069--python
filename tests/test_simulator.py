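import numpy as np
import pytest

from microsacc import (
    ModelParams,
    connection_weights,
    generate_poisson_spikes,
    integrate_v1,
    layer_geometry,
    load_spike_trains,
    run_simulation,
    save_spike_trains,
    steady_state_strength,
)
from microsacc.simulator import SpikeTrainSet


def _spike_set(times, ids, n_neurons, duration):
    order = np.lexsort((ids, times))
    return SpikeTrainSet(
        neuron_ids=np.asarray(ids, dtype=np.int64)[order],
        times=np.asarray(times, dtype=float)[order],
        n_neurons=n_neurons,
        layer="LGN",
        duration=duration,
    )


class TestPoissonGeneration:
    def test_zero_rate_is_silent(self):
        rng = np.random.default_rng(0)
        s = generate_poisson_spikes(np.array([0.0, 50.0]), 0.0, 1000.0, 0.1, rng)
        assert len(s.spike_times(0)) == 0
        assert len(s.spike_times(1)) > 0

    def test_count_statistics(self):
        # 100 Hz over 10 s: count within 3 sd of 1000
        rng = np.random.default_rng(42)
        s = generate_poisson_spikes(np.array([100.0]), 0.0, 10_000.0, 0.1, rng)
        assert abs(len(s) - 1000) < 3 * np.sqrt(1000)

    def test_determinism_same_seedsequence(self):
        rates = np.full(20, 80.0)
        a = generate_poisson_spikes(rates, 0.0, 500.0, 0.1, np.random.SeedSequence(9))
        b = generate_poisson_spikes(rates, 0.0, 500.0, 0.1, np.random.SeedSequence(9))
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.neuron_ids, b.neuron_ids)

    def test_per_neuron_streams_stable_under_N(self):
        """Adding neurons must not reshuffle existing neurons' spikes."""
        r20 = generate_poisson_spikes(
            np.full(20, 60.0), 0.0, 500.0, 0.1, np.random.SeedSequence(3)
        )
        r30 = generate_poisson_spikes(
            np.full(30, 60.0), 0.0, 500.0, 0.1, np.random.SeedSequence(3)
        )
        for j in range(20):
            np.testing.assert_array_equal(r20.spike_times(j), r30.spike_times(j))

    def test_refuses_coarse_dt(self):
        with pytest.raises(ValueError, match="smaller dt"):
            generate_poisson_spikes(
                np.array([5000.0]), 0.0, 100.0, 1.0, np.random.default_rng(0)
            )

    def test_spike_times_sorted_in_window(self):
        s = generate_poisson_spikes(
            np.full(5, 90.0), 100.0, 400.0, 0.1, np.random.SeedSequence(5)
        )
        assert np.all(np.diff(s.times) >= 0)
        assert s.times.min() >= 100.0 and s.times.max() < 400.0
        for j in range(5):
            assert np.all(np.diff(s.spike_times(j)) > 0)


class TestIntegration:
    def test_no_input_no_output(self, params_small):
        geom = layer_geometry(params_small.N, params_small.L)
        W = connection_weights(geom, params_small.sigma2)
        empty = _spike_set([], [], params_small.N, 100.0)
        v1, V, S, _ = integrate_v1(empty, W, params_small, return_state=True)
        assert len(v1) == 0
        np.testing.assert_allclose(V, params_small.V0)
        np.testing.assert_allclose(S, 1.0)

    def test_single_kick_amplitude(self):
        """One spike through a unit weight: V jumps by g*(VE - V0) = 10.5 mV."""
        p = ModelParams(N=4, g=0.15)
        W = np.ones((4, 4))
        # recording ends at the spike step, so no leak follows the kick
        s = _spike_set([99.9], [2], 4, 99.9)
        _, V, S, _ = integrate_v1(s, W, p, return_state=True)
        np.testing.assert_allclose(V, -70.0 + 0.15 * (0.0 - (-70.0)))  # -59.5 mV
        assert S[2] == pytest.approx(0.75)
        assert np.all(S[[0, 1, 3]] == 1.0)

    def test_kick_uses_prespike_strength_then_depresses(self):
        """Two immediate spikes from one afferent: kicks at S=1 then S=f."""
        p = ModelParams(N=1, g=0.1, f=0.75)
        W = np.ones((1, 1))
        s = _spike_set([99.8, 99.9], [0, 0], 1, 99.9)
        _, V, S, _ = integrate_v1(s, W, p, return_state=True)
        v1 = -70.0 + 0.1 * 1.0 * 70.0         # after first kick (S=1)
        v1 = v1 * np.exp(-0.1 / 20.0) - 70.0 * (1 - np.exp(-0.1 / 20.0))
        s_rec = 1.0 - 0.25 * np.exp(-0.1 / 300.0)  # S recovers between spikes
        expected = v1 + 0.1 * s_rec * (0.0 - v1)   # second kick at recovered S
        assert V[0] == pytest.approx(expected, abs=1e-9)
        assert S[0] == pytest.approx(0.75 * s_rec, rel=1e-9)

    def test_zero_conductance_never_fires(self, params_small):
        p = params_small.replace(g=0.0)
        geom = layer_geometry(p.N, p.L)
        W = connection_weights(geom, p.sigma2)
        spikes = generate_poisson_spikes(
            np.full(p.N, 100.0), 0.0, 500.0, p.dt, np.random.SeedSequence(1)
        )
        v1 = integrate_v1(spikes, W, p)
        assert len(v1) == 0

    def test_unsorted_input_rejected(self, params_small):
        geom = layer_geometry(params_small.N, params_small.L)
        W = connection_weights(geom, params_small.sigma2)
        bad = SpikeTrainSet(
            neuron_ids=np.array([0, 1]),
            times=np.array([50.0, 10.0]),
            n_neurons=params_small.N,
            layer="LGN",
            duration=100.0,
        )
        with pytest.raises(ValueError, match="sorted"):
            integrate_v1(bad, W, params_small)

    def test_jit_and_python_kernels_agree(self):
        from microsacc._kernel import integrate_kernel, integrate_kernel_py

        p = ModelParams(N=30)
        geom = layer_geometry(p.N, p.L)
        W = connection_weights(geom, p.sigma2)
        rates = np.full(p.N, 90.0)
        spikes = generate_poisson_spikes(rates, 0.0, 300.0, p.dt, np.random.SeedSequence(8))
        steps = np.floor(spikes.times / p.dt + 0.5).astype(np.int64)
        args = (
            steps, spikes.neuron_ids.astype(np.int64), 3000, W,
        )
        tail = (p.tau_m, p.V0, p.VE, p.Vth, p.Vreset, p.g, p.f, p.tau_d, p.dt, 0.0, 300.0)
        t1, n1, s1 = integrate_kernel(
            *args, np.full(p.N, p.V0), np.ones(p.N), *tail
        )
        t2, n2, s2 = integrate_kernel_py(
            *args, np.full(p.N, p.V0), np.ones(p.N), *tail
        )
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(n1, n2)
        np.testing.assert_allclose(s1, s2, rtol=1e-12)


class TestRunSimulation:
    def test_schedule_validation(self, params_small):
        with pytest.raises(ValueError):
            run_simulation(params_small, [], seed=0)
        with pytest.raises(ValueError, match="contiguous"):
            run_simulation(
                params_small, [(0.0, 100.0, 0.0), (150.0, 200.0, 1.0)], seed=0
            )

    def test_zero_brightness_silent(self, params_small):
        p = params_small.replace(A=0.0)
        res = run_simulation(p, [(0.0, 200.0, 0.0)], seed=0)
        assert len(res.lgn_spikes) == 0
        assert len(res.v1_spikes) == 0

    def test_bit_identical_reproducibility(self, params_small):
        sched = [(0.0, 300.0, 0.0), (300.0, 500.0, 0.8)]
        a = run_simulation(params_small, sched, seed=77)
        b = run_simulation(params_small, sched, seed=77)
        np.testing.assert_array_equal(a.lgn_spikes.times, b.lgn_spikes.times)
        np.testing.assert_array_equal(a.lgn_spikes.neuron_ids, b.lgn_spikes.neuron_ids)
        np.testing.assert_array_equal(a.v1_spikes.times, b.v1_spikes.times)
        np.testing.assert_array_equal(a.v1_spikes.neuron_ids, b.v1_spikes.neuron_ids)

    def test_v1_count_monotone_in_A_and_g(self):
        """More brightness or stronger synapses -> more V1 spikes (seed-averaged)."""
        base = ModelParams(N=200)
        counts = {}
        for label, p in {
            "lowA": base.replace(A=60.0),
            "highA": base.replace(A=120.0),
            "lowg": base.replace(g=0.08),
            "highg": base.replace(g=0.25),
        }.items():
            n = [
                len(run_simulation(p, [(0.0, 400.0, 0.0)], seed=s).v1_spikes)
                for s in (1, 2, 3)
            ]
            counts[label] = np.mean(n)
        assert counts["highA"] > counts["lowA"]
        assert counts["highg"] > counts["lowg"]

    def test_synapse_average_matches_steady_state(self):
        """Time-averaged S_j during fixation ~ closed-form steady state (5 %)."""
        p = ModelParams(N=100)
        res = run_simulation(
            p, [(0.0, 20_000.0, 0.0)], seed=11, s_average_window=(2000.0, 20_000.0)
        )
        from microsacc import gaussian_rate_profile

        geom = layer_geometry(p.N, p.L)
        rates = gaussian_rate_profile(geom, 0.0, p.A, p.sigma1).rates
        expected = steady_state_strength(rates, p.f, p.tau_d)
        # low-rate synapses fire too rarely for an 18 s average to settle
        active = rates > 50.0
        np.testing.assert_allclose(res.s_average[active], expected[active], rtol=0.05)

    def test_spike_train_text_roundtrip(self, tmp_path, params_small):
        res = run_simulation(params_small, [(0.0, 300.0, 0.0)], seed=5)
        path = tmp_path / "spikes.tsv"
        save_spike_trains(path, res.lgn_spikes, res.v1_spikes)
        loaded = load_spike_trains(path, duration=300.0)
        assert set(loaded) <= {"LGN", "V1"}
        np.testing.assert_allclose(
            loaded["LGN"].times, res.lgn_spikes.times, atol=1e-4
        )
        np.testing.assert_array_equal(
            loaded["LGN"].neuron_ids, res.lgn_spikes.neuron_ids
        )
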