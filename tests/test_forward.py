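"""Bilinear dynamics, balloon hemodynamics and BOLD sampling."""

import numpy as np
import pytest

from durnet import forward as fw


class TestNeuralDerivative:
    def test_fixed_point_at_rest(self, three_node_params):
        d = fw.neural_derivative(np.zeros(3), np.zeros(1), three_node_params)
        assert np.allclose(d, 0)

    def test_pure_drive(self):
        p = fw.BilinearParams(A=np.array([[-1.0]]), B=np.zeros((1, 1, 1)),
                              C=np.array([[1.0]]))
        assert np.allclose(fw.neural_derivative(np.zeros(1), np.ones(1), p), [1.0])

    def test_bilinear_expression(self):
        A = np.array([[-1.0, 0.0], [0.5, -1.0]])
        B = np.zeros((1, 2, 2))
        B[0, 1, 0] = 0.3
        p = fw.BilinearParams(A=A, B=B, C=np.zeros((2, 1)))
        d = fw.neural_derivative(np.array([1.0, 0.0]), np.array([1.0]), p)
        assert np.allclose(d, [-1.0, 0.8])

    def test_dimension_mismatch(self, three_node_params):
        with pytest.raises(ValueError):
            fw.neural_derivative(np.zeros(2), np.zeros(1), three_node_params)
        with pytest.raises(ValueError):
            fw.neural_derivative(np.zeros(3), np.zeros(2), three_node_params)


class TestIntegrateStates:
    def test_zero_input_stays_at_rest(self, three_node_params):
        U = np.zeros((100, 1))
        traj = fw.integrate_states(three_node_params, U, 0.1)
        assert np.allclose(traj, 0)

    def test_matches_analytic_exponential_decay(self):
        """1-node linear system: impulse response is a pure exponential."""
        a = -0.5
        p = fw.BilinearParams(A=np.array([[a]]), B=np.zeros((1, 1, 1)),
                              C=np.array([[1.0]]))
        dt = 0.01
        n = 1000
        U = np.zeros((n, 1))
        U[0, 0] = 1.0 / dt  # unit-area impulse held over one step
        traj = fw.integrate_states(p, U, dt)
        t = np.arange(1, n + 1) * dt
        # after the impulse step the state decays from x(dt)
        expected = traj[1, 0] * np.exp(a * (t - dt))
        assert np.max(np.abs(traj[1:, 0] - expected)) < 1e-4

    def test_step_halving_convergence(self, three_node_params):
        dt = 1.368 / 16
        U = np.zeros((160, 1))
        U[5, 0] = 1.0 / dt
        x1 = fw.integrate_states(three_node_params, U, dt)[-1]
        U2 = np.repeat(U, 2, axis=0)
        x2 = fw.integrate_states(three_node_params, U2, dt / 2)[-1]
        assert np.max(np.abs(x1 - x2)) < 1e-5

    def test_unstable_params_warn(self):
        p = fw.BilinearParams(A=np.array([[-0.1, 1.0], [1.0, -0.1]]),
                              B=np.zeros((1, 2, 2)), C=np.zeros((2, 1)))
        with pytest.warns(RuntimeWarning):
            fw.integrate_states(p, np.zeros((10, 1)), 0.1)


class TestHemodynamics:
    def test_defaults_are_7t_constants(self):
        h = fw.HemodynamicConfig()
        assert h.echo_time == 0.026
        assert h.frequency_offset == 197.9
        assert h.intravascular_relaxation == 340.0
        assert h.intra_extra_ratio == 0.026
        assert h.resting_o2_extraction == 0.34

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValueError):
            fw.HemodynamicConfig(transit_time=0.0)

    def test_rest_gives_zero_bold(self):
        x = np.zeros((200, 2))
        y = fw.hemodynamic_bold(x, fw.HemodynamicConfig(), 0.1)
        assert np.allclose(y, 0)

    def test_boxcar_response_shape_and_fine_step_agreement(self):
        """1 s of activity: positive transient peaking seconds later, then
        an undershoot; agrees with the same equations at 10x finer step."""
        dt = 1.368 / 16
        n = int(30 / dt)
        x = np.zeros((n + 1, 1))
        x[: int(1 / dt) + 1, 0] = 1.0
        h = fw.HemodynamicConfig()
        y = fw.hemodynamic_bold(x, h, dt)[:, 0]
        t = np.arange(n + 1) * dt
        peak = np.argmax(y)
        assert 2.0 < t[peak] < 8.0
        assert y[peak] > 0
        assert y[(t > 8) & (t < 25)].min() < -1e-3  # post-stimulus undershoot
        xf = np.repeat(x[:-1], 10, axis=0)
        xf = np.vstack([xf, x[-1:]])
        yf = fw.hemodynamic_bold(xf, h, dt / 10, sample_every=10)[:, 0]
        assert np.max(np.abs(y - yf)) < 1e-4

    def test_finite_input_required(self):
        with pytest.raises(ValueError):
            fw.hemodynamic_bold(np.array([[np.nan]]), fw.HemodynamicConfig(), 0.1)


class TestFullForwardPass:
    def test_matches_fine_step_reference(self, three_node_params, impulse_inputs):
        U, dt = impulse_inputs
        y = fw.simulate_bold(three_node_params, U, dt)
        yf = fw.simulate_bold(three_node_params, np.repeat(U, 10, axis=0),
                              dt / 10, sample_every=160)
        assert np.max(np.abs(y - yf)) < 1e-4

    def test_linearity_in_c_at_rest(self, three_node_params, impulse_inputs):
        """Doubling C doubles the initial response regime."""
        U, dt = impulse_inputs
        p2 = fw.BilinearParams(A=three_node_params.A, B=three_node_params.B,
                               C=2 * three_node_params.C)
        x1 = fw.integrate_states(three_node_params, U[:32], dt)
        x2 = fw.integrate_states(p2, U[:32], dt)
        assert np.allclose(x2, 2 * x1, atol=1e-12)

    def test_energy_decay_after_inputs_stop(self, three_node_params):
        dt = 1.368 / 16
        U = np.zeros((400, 1))
        U[0, 0] = 1.0 / dt
        traj = fw.integrate_states(three_node_params, U, dt)
        norms = np.linalg.norm(traj, axis=1)
        tail = norms[100:]
        assert np.all(np.diff(tail) <= 1e-12)
        assert tail[-1] < 1e-3 * norms[1:].max()

    def test_batch_consistency(self, three_node_params, impulse_inputs):
        U, dt = impulse_inputs
        single = fw.simulate_bold(three_node_params, U, dt)
        batch = fw.simulate_bold_batch(
            np.stack([three_node_params.A] * 3),
            np.stack([three_node_params.B] * 3),
            np.stack([three_node_params.C] * 3), U,
            three_node_params.hemo, dt)
        for b in range(3):
            assert np.array_equal(batch[b], single)


class TestSampling:
    def test_noise_free_sampling_is_identity(self):
        y = np.random.default_rng(0).standard_normal((50, 2))
        assert np.array_equal(fw.sample_bold(y), y)

    def test_seeded_reproducibility(self):
        y = np.zeros((100, 2))
        a = fw.sample_bold(y, noise_sd=0.5, rng=np.random.default_rng(42))
        b = fw.sample_bold(y, noise_sd=0.5, rng=np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_empirical_noise_sd(self):
        y = np.zeros((10_000, 1))
        out = fw.sample_bold(y, noise_sd=0.7, rng=np.random.default_rng(1))
        assert abs(out.std() - 0.7) / 0.7 < 0.05

    def test_drift_added(self):
        y = np.zeros((64, 1))
        drift = fw.cosine_drift(64, 3, np.array([1.0, 0.5, 0.2]))[:, None]
        out = fw.sample_bold(y, drift=drift)
        assert np.array_equal(out, drift)

    def test_event_outside_run_rejected(self):
        with pytest.raises(ValueError):
            fw.build_inputs([np.array([100.0])], 100, 0.1)

    def test_mean_centering(self):
        U = fw.build_inputs([np.array([1.0, 3.0])], 100, 0.1, mean_center=True)
        assert abs(U[:, 0].mean()) < 1e-12


class TestParamsValidation:
    def test_positive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            fw.BilinearParams(A=np.array([[0.1]]), B=np.zeros((1, 1, 1)),
                              C=np.zeros((1, 1)))

    def test_roundtrip(self, three_node_params, tmp_path):
        path = tmp_path / "p.json"
        three_node_params.save(str(path))
        back = fw.BilinearParams.load(str(path))
        assert np.array_equal(back.A, three_node_params.A)
        assert np.array_equal(back.B, three_node_params.B)
        assert back.hemo == three_node_params.hemo
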