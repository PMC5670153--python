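"""Network dynamics: sigmoid, kernels, delays, Euler integration."""

import numpy as np
import pytest

import msinet as M
from msinet.dynamics import (
    AREAS,
    NetworkState,
    delayed_activity,
    mexican_hat_matrix,
    sigmoid,
    simulate_trial,
    step,
)


class TestSigmoid:
    def test_midpoint(self):
        p = M.NeuronParams(sigmoid_slope=0.6, sigmoid_center=12.0)
        assert sigmoid(12.0, p) == pytest.approx(0.5)

    def test_saturates_at_one(self):
        p = M.NeuronParams()
        assert sigmoid(1e6, p) == pytest.approx(1.0)
        assert sigmoid(-1e2, p) == pytest.approx(0.0, abs=1e-10)

    def test_closed_form(self):
        p = M.NeuronParams(sigmoid_slope=1.0, sigmoid_center=10.0)
        assert sigmoid(12.0, p) == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-12)

    def test_monotone(self):
        p = M.NeuronParams()
        u = np.linspace(-50, 50, 201)
        assert np.all(np.diff(sigmoid(u, p)) > 0)


class TestMexicanHat:
    KERNEL = M.LateralKernel(a_ex=2.0, sigma_ex=1.0, a_in=1.0, sigma_in=4.0)

    def test_no_self_connection(self):
        m = mexican_hat_matrix(self.KERNEL, 30)
        assert np.all(np.diag(m) == 0.0)

    def test_closed_form_neighbor(self):
        m = mexican_hat_matrix(self.KERNEL, 30)
        expected = 2 * np.exp(-0.5) - np.exp(-1 / 32)  # d = 1
        assert m[10, 11] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.2438, abs=5e-4)

    def test_inhibitory_annulus(self):
        m = mexican_hat_matrix(self.KERNEL, 30)
        d6 = 2 * np.exp(-18.0) - np.exp(-36.0 / 32.0)
        assert m[10, 16] == pytest.approx(d6, abs=1e-12)
        assert m[10, 16] < 0  # net inhibitory at distance 6

    def test_symmetric(self):
        m = mexican_hat_matrix(self.KERNEL, 50)
        assert np.array_equal(m, m.T)

    def test_default_kernels_have_hat_shape(self, default_config):
        for kernel in (default_config.lateral_unisensory, default_config.lateral_multisensory):
            m = mexican_hat_matrix(kernel, 100)
            assert m[50, 51] > 0  # near-center excitation
            row = m[50]
            assert row.min() < 0  # surround inhibition exists

    def test_invalid_sigmas_rejected(self):
        with pytest.raises(ValueError):
            M.LateralKernel(a_ex=1.0, sigma_ex=-1.0, a_in=1.0, sigma_in=4.0)
        with pytest.raises(ValueError):
            M.LateralKernel(a_ex=1.0, sigma_ex=4.0, a_in=1.0, sigma_in=2.0)


class TestDelayedActivity:
    def _state(self, n=4, n_steps=20, dt=1.0):
        state = NetworkState.initial(n, n_steps, dt)
        for k in range(1, n_steps + 1):
            state.history["auditory"][k] = k  # activity = step index
        return state

    def test_zero_latency_returns_current(self):
        state = self._state()
        assert np.all(delayed_activity(state, "auditory", 0.0, 10.0) == 10.0)

    def test_before_start_returns_zeros(self):
        state = self._state()
        assert not delayed_activity(state, "auditory", 50.0, 10.0).any()

    def test_constant_past_returns_it(self):
        state = self._state()
        assert np.all(delayed_activity(state, "auditory", 5.0, 15.0) == 10.0)


class TestStep:
    def test_single_euler_step_by_hand(self, default_config):
        # u = 0, net input 1, tau 15, dt 1  ->  u' = 1/15
        net = M.build_network(default_config)
        for proj in net.projections.values():
            proj.weights[:] = 0.0
        for area in AREAS:
            net.lateral[area][:] = 0.0
        state = NetworkState.initial(net.n, 10, dt=1.0)
        drive = np.ones(net.n)
        step(net, state, drive, np.zeros(net.n))
        assert state.u["auditory"][0] == pytest.approx(1.0 / 15.0)
        assert state.u["multisensory"][0] == pytest.approx(0.0)

    def test_rest_state_is_fixed_point_below_floor(self, default_config):
        net = M.build_network(default_config)
        for proj in net.projections.values():
            proj.weights[:] = 0.0
        state = NetworkState.initial(net.n, 50, dt=1.0)
        for _ in range(50):
            step(net, state, np.zeros(net.n), np.zeros(net.n))
        # rest activity stays below the sigmoid floor contract (< 0.01)
        for area in AREAS:
            assert state.z[area].max() < 0.01

    def test_pure_latency_contract(self, noiseless_config):
        # multisensory drive from an input at t=0 is exactly zero while
        # t < feedforward latency
        net = M.build_network(noiseless_config)
        trial = M.make_trial("V", 50, 5, noiseless_config.space, noiseless_config.stimulus)
        rec = simulate_trial(net, trial, np.random.default_rng(0))
        latency = net.projections["sv"].latency
        k_lat = int(latency / noiseless_config.dt)
        baseline = rec.activity["multisensory"][0, :]
        pre = rec.activity["multisensory"][1 : k_lat + 1]
        # before the latency elapses the multisensory area only relaxes
        # toward its input-free floor: no stimulus-driven deviation
        assert np.all(np.abs(pre - pre[0:1]) < 1e-3)
        post = rec.activity["multisensory"][k_lat + 5 :]
        assert post.max() > pre.max() + 1e-3


class TestSimulateTrial:
    def test_identical_seeds_bit_identical(self, default_config, untrained_network):
        trial = M.make_trial("AV", 50, 7, default_config.space, default_config.stimulus)
        a = simulate_trial(untrained_network, trial, np.random.default_rng(11))
        b = simulate_trial(untrained_network, trial, np.random.default_rng(11))
        for area in AREAS:
            assert np.array_equal(a.activity[area], b.activity[area])

    def test_noiseless_trial_deterministic_across_generators(
        self, noiseless_config, untrained_network
    ):
        trial = M.make_trial("AV", 50, 7, noiseless_config.space, noiseless_config.stimulus)
        a = simulate_trial(untrained_network, trial, np.random.default_rng(1))
        b = simulate_trial(untrained_network, trial, np.random.default_rng(999))
        for area in AREAS:
            assert np.array_equal(a.activity[area], b.activity[area])

    def test_activity_bounded(self, default_config, rng):
        # arbitrary admissible weights cannot push activity outside [0, 1]
        net = M.build_network(default_config)
        for key, proj in net.projections.items():
            proj.weights = rng.uniform(0, 3.0, size=proj.weights.shape)
        trial = M.make_trial("AV", 50, 7, default_config.space, default_config.stimulus)
        rec = simulate_trial(net, trial, rng)
        for area in AREAS:
            z = rec.activity[area]
            assert z.min() >= 0.0 and z.max() <= 1.0

    def test_disconnected_network_stays_subthreshold(self, noiseless_config):
        net = M.build_network(noiseless_config)
        for proj in net.projections.values():
            proj.weights[:] = 0.0
        trial = M.make_trial("AV", 50, 7, noiseless_config.space, noiseless_config.stimulus)
        rec = simulate_trial(net, trial, np.random.default_rng(0))
        assert rec.max_activity("multisensory").max() < noiseless_config.readout.threshold

    def test_fast_core_matches_step_reference(self, default_config, untrained_network):
        """The float32 integration core agrees with the float64 step() path."""
        from msinet.dynamics import _trial_drives

        cfg = default_config
        trial = M.make_trial("AV", 50, 7, cfg.space, cfg.stimulus)
        n_steps = int(trial.trial_duration / cfg.dt)
        net = untrained_network
        drives_a, drives_v = _trial_drives(trial, net.n, n_steps, cfg.dt, np.random.default_rng(5))
        rec = simulate_trial(net, trial, np.random.default_rng(5))
        state = NetworkState.initial(net.n, n_steps, cfg.dt)
        for k in range(n_steps):
            step(net, state, drives_a[k], drives_v[k])
        for area in AREAS:
            assert np.allclose(
                state.history[area], rec.activity[area], atol=5e-5
            ), f"core/step mismatch in {area}"

    def test_numba_core_matches_numpy_reference(self, default_config, untrained_network):
        """The jitted integration core equals the pure-numpy implementation."""
        from msinet.dynamics import _integrate, _integrate_numpy, _trial_drives

        cfg = default_config
        trial = M.make_trial("McGurk", 50, 6, cfg.space, cfg.stimulus)
        n_steps = int(trial.trial_duration / cfg.dt)
        net = untrained_network
        rng = np.random.default_rng(2)
        drives = _trial_drives(trial, net.n, n_steps, cfg.dt, rng)
        p = net.projections
        args = (
            n_steps,
            np.float64(cfg.dt / net.neuron.tau),
            np.float64(net.neuron.sigmoid_slope),
            np.float64(net.neuron.sigmoid_center),
            *[
                np.ascontiguousarray(m)
                for m in (
                    net.lateral["auditory"],
                    net.lateral["visual"],
                    net.lateral["multisensory"],
                    p["av"].weights,
                    p["va"].weights,
                    p["sa"].weights,
                    p["sv"].weights,
                )
            ],
            10,
            10,
            50,
            50,
            np.ascontiguousarray(drives[0]),
            np.ascontiguousarray(drives[1]),
        )
        fast = _integrate(*args)
        slow = _integrate_numpy(*args)
        for f, s in zip(fast, slow):
            assert np.allclose(f, s, atol=1e-12)

    def test_euler_dt_refinement(self, noiseless_config, untrained_network):
        """First-order Euler convergence: halving dt halves the error, and in
        the convergent regime (dt <= 0.5 ms) the change stays below 1%."""
        trial = M.make_trial("AV", 50, 7, noiseless_config.space, noiseless_config.stimulus)
        recs = {
            dt: simulate_trial(
                untrained_network, trial, np.random.default_rng(0), dt=dt, dtype=np.float64
            )
            for dt in (0.5, 0.25, 0.125)
        }
        for area in AREAS:
            err_coarse = np.abs(recs[0.5].activity[area] - recs[0.25].activity[area][::2]).max()
            err_fine = np.abs(recs[0.25].activity[area][::2] - recs[0.125].activity[area][::4]).max()
            assert err_fine < 0.01, f"{area}: refinement drift {err_fine:.4f}"
            if err_coarse > 1e-4:  # transient large enough to measure the order
                assert err_fine < 0.75 * err_coarse

    def test_too_coarse_dt_rejected(self, default_config, untrained_network, rng):
        trial = M.make_trial("A", 50, 5, default_config.space, default_config.stimulus)
        with pytest.raises(ValueError, match="dt"):
            simulate_trial(untrained_network, trial, rng, dt=5.0)


class TestActivationBubble:
    def test_suprathreshold_set_contiguous(self, noiseless_config):
        """A single suprathreshold stimulus produces one contiguous bubble."""
        net = M.build_network(noiseless_config)
        trial = M.make_trial("A", 50, 7, noiseless_config.space, noiseless_config.stimulus)
        rec = simulate_trial(net, trial, np.random.default_rng(0))
        z = rec.max_activity("auditory")
        idx = np.flatnonzero(z >= 0.5)
        assert idx.size >= 1
        assert np.all(np.diff(idx) == 1), "activation bubble must be contiguous"
        assert 50 in idx


class TestSerialization:
    def test_save_load_round_trip(self, untrained_network, default_config, tmp_path):
        untrained_network.save(tmp_path / "bundle", metadata={"epoch": 0})
        loaded = M.Network.load(
            tmp_path / "bundle", default_config.space, default_config.neuron
        )
        for key in untrained_network.projections:
            orig = untrained_network.projections[key]
            new = loaded.projections[key]
            assert np.allclose(orig.weights, new.weights)
            assert orig.latency == new.latency
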