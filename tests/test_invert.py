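"""Variational-Laplace inversion: recovery, monotonicity, shrinkage, limits."""

import numpy as np
import pytest

from durnet import forward as fw
from durnet.invert import (ParamLayout, PriorSpec, default_confounds,
                           default_priors, predict_bold, variational_laplace)


@pytest.fixture(scope="module")
def three_node_problem():
    """A 3-node system with one driving input, 150 volumes."""
    n, m, T, micro = 3, 1, 150, 8
    tvol = 1.368
    dt = tvol / micro
    a_mask = np.ones((n, n), bool)
    b_masks = np.zeros((m, n, n), bool)
    c_mask = np.zeros((n, m), bool)
    c_mask[0, 0] = True
    layout = ParamLayout(a_mask, b_masks, c_mask)
    A = np.array([[-0.5, 0.0, 0.0], [0.4, -0.5, 0.0], [0.0, 0.3, -0.5]])
    truth = fw.BilinearParams(A=A, B=np.zeros((m, n, n)), C=np.array([[0.4], [0.0], [0.0]]))
    U = fw.build_inputs([np.arange(6.0, T * tvol - 10, 9.0)], T * micro, dt)
    y_clean = fw.simulate_bold(truth, U, dt, sample_every=micro)[:T]
    return layout, truth, U, y_clean, dt, micro


class TestLayout:
    def test_roundtrip(self, three_node_problem):
        layout, truth, *_ = three_node_problem
        theta = layout.from_params(truth)
        back = layout.to_params(theta)
        assert np.allclose(back.A, truth.A)
        assert np.allclose(back.C, truth.C)

    def test_masked_entries_not_in_vector(self):
        a_mask = np.eye(2, dtype=bool)
        a_mask[1, 0] = True
        layout = ParamLayout(a_mask, np.zeros((1, 2, 2), bool), np.zeros((2, 1), bool))
        assert layout.size == 3  # one off-diagonal + two self

    def test_default_priors_deterministic_and_masked(self):
        a_mask = np.ones((2, 2), bool)
        b = np.zeros((1, 2, 2), bool)
        c = np.ones((2, 1), bool)
        p1 = default_priors(ParamLayout(a_mask, b, c))
        p2 = default_priors(ParamLayout(a_mask, b, c))
        assert np.array_equal(p1.var, p2.var)
        assert np.all(p1.mean == 0)

    def test_self_connection_prior_mean_maps_to_half_hz(self):
        layout = ParamLayout(np.eye(1, dtype=bool), np.zeros((1, 1, 1), bool),
                             np.zeros((1, 1), bool))
        params = layout.to_params(np.zeros(layout.size))
        assert params.A[0, 0] == pytest.approx(-0.5)


class TestVariationalLaplace:
    def test_empty_data_rejected(self, three_node_problem):
        layout, truth, U, y, dt, micro = three_node_problem
        with pytest.raises(ValueError):
            variational_laplace(layout, np.empty((0, 3)), U, dt, micro=micro)

    def test_parameter_recovery_at_snr_one(self, three_node_problem):
        """Posterior-mean A correlates with truth across seeds at SNR 1."""
        layout, truth, U, y_clean, dt, micro = three_node_problem
        off = ~np.eye(3, dtype=bool)
        corrs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            y = y_clean + y_clean.std(axis=0) * rng.standard_normal(y_clean.shape)
            res = variational_laplace(layout, y, U, dt, micro=micro)
            est = res.to_params()
            corrs.append(np.corrcoef(truth.A[off], est.A[off])[0, 1])
        assert np.mean(corrs) >= 0.8

    def test_f_monotone_over_accepted_steps(self, three_node_problem):
        layout, truth, U, y_clean, dt, micro = three_node_problem
        rng = np.random.default_rng(0)
        y = y_clean + 0.5 * y_clean.std(axis=0) * rng.standard_normal(y_clean.shape)
        res = variational_laplace(layout, y, U, dt, micro=micro)
        diffs = np.diff(res.f_trajectory)
        assert np.all(diffs > -1e-6)

    def test_posterior_variance_below_prior(self, three_node_problem):
        layout, truth, U, y_clean, dt, micro = three_node_problem
        rng = np.random.default_rng(1)
        y = y_clean + 0.5 * y_clean.std(axis=0) * rng.standard_normal(y_clean.shape)
        priors = default_priors(layout)
        res = variational_laplace(layout, y, U, dt, priors=priors, micro=micro)
        post_var = np.diag(res.dcm_cov())
        assert np.all(post_var <= priors.var + 1e-10)

    def test_zero_prior_variance_recovers_prior(self, three_node_problem):
        """With all coupling priors pinned, posterior = prior mean and the
        fit reduces to the confound-only model."""
        layout, truth, U, y_clean, dt, micro = three_node_problem
        rng = np.random.default_rng(2)
        y = y_clean + 0.3 * rng.standard_normal(y_clean.shape)
        priors = default_priors(layout)
        pinned = PriorSpec(mean=priors.mean, var=np.full(layout.size, 1e-12))
        res = variational_laplace(layout, y, U, dt, priors=pinned, micro=micro)
        assert np.allclose(res.dcm_mean(), 0.0)
        assert np.all(np.diag(res.dcm_cov()) == 0.0)

    def test_true_mask_beats_shuffled_mask(self, three_node_problem):
        """Evidence prefers the generating sparsity over a permuted one."""
        layout, truth, U, y_clean, dt, micro = three_node_problem
        wins = 0
        n_rep = 3
        # true mask: only the generating edges free
        a_true = np.eye(3, dtype=bool)
        a_true[1, 0] = a_true[2, 1] = True
        a_shuf = np.eye(3, dtype=bool)
        a_shuf[0, 1] = a_shuf[1, 2] = True  # reversed edges
        c_mask = np.zeros((3, 1), bool)
        c_mask[0, 0] = True
        lt = ParamLayout(a_true, np.zeros((1, 3, 3), bool), c_mask)
        ls = ParamLayout(a_shuf, np.zeros((1, 3, 3), bool), c_mask)
        for seed in range(n_rep):
            rng = np.random.default_rng(seed + 10)
            y = y_clean + 0.2 * y_clean.std(axis=0) * rng.standard_normal(y_clean.shape)
            ft = variational_laplace(lt, y, U, dt, micro=micro).free_energy
            fs = variational_laplace(ls, y, U, dt, micro=micro).free_energy
            wins += ft > fs
        assert wins == n_rep

    def test_multi_run_joint_inversion(self, three_node_problem):
        layout, truth, U, y_clean, dt, micro = three_node_problem
        rng = np.random.default_rng(3)
        y1 = y_clean + 0.3 * rng.standard_normal(y_clean.shape)
        y2 = y_clean + 0.3 * rng.standard_normal(y_clean.shape)
        res = variational_laplace(layout, [y1, y2], [U, U], dt, micro=micro)
        assert res.mean.size >= layout.size
        assert np.isfinite(res.free_energy)

    def test_projected_confounds_match_explicit_betas(self, three_node_problem):
        """Profiling the confounds out gives the same coupling estimates as
        estimating their coefficients explicitly."""
        layout, truth, U, y_clean, dt, micro = three_node_problem
        rng = np.random.default_rng(4)
        y = y_clean + 0.3 * rng.standard_normal(y_clean.shape)
        r1 = variational_laplace(layout, y, U, dt, micro=micro)
        r2 = variational_laplace(layout, y, U, dt, micro=micro,
                                 project_confounds=True)
        assert np.allclose(r1.dcm_mean(), r2.dcm_mean(), atol=0.06)


class TestPredictBold:
    def test_low_noise_explained_variance(self, three_node_problem):
        layout, truth, U, y_clean, dt, micro = three_node_problem
        rng = np.random.default_rng(5)
        y = y_clean + 0.05 * y_clean.std(axis=0) * rng.standard_normal(y_clean.shape)
        res = variational_laplace(layout, y, U, dt, micro=micro)
        assert res.explained_variance >= 0.9
        pred = predict_bold(res, U, dt, micro=micro, n_volumes=y.shape[0])
        assert pred.shape == y.shape
        assert 1 - np.var(y - pred) / np.var(y) >= 0.9

    def test_zero_coupling_prediction_is_confounds_only(self, three_node_problem):
        layout, truth, U, y_clean, dt, micro = three_node_problem
        T = y_clean.shape[0]
        res_mean = np.zeros(layout.size)
        # C pinned at zero -> forward sim is identically zero
        from durnet.invert import InversionResult
        K = default_confounds(T, dt * micro).shape[1]
        mean = np.concatenate([res_mean, np.zeros(3 * K)])
        mean[layout.size] = 1.23  # first confound coefficient of node 1
        res = InversionResult(mean=mean, cov=np.eye(mean.size), free_energy=0.0,
                              lambdas=np.zeros(3), layout=layout, n_confounds=K,
                              explained_variance=1.0, iterations=1, converged=True)
        # zero C because to_params of zero theta has C=0 on the masked entry
        res.mean[layout.size - 1] = 0.0  # the single C parameter
        pred = predict_bold(res, U, dt, micro=micro, n_volumes=T)
        X = default_confounds(T, dt * micro)
        expected = np.zeros((T, 3))
        expected[:, 0] = X @ np.concatenate([[1.23], np.zeros(K - 1)])
        assert np.allclose(pred, expected, atol=1e-10)
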