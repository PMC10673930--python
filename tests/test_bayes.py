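"""Bayesian model reduction, random-effects selection, averaging."""

import numpy as np
import pytest

from durnet import bayes
from durnet.invert import PriorSpec


def _gauss_posterior(prior_mean, prior_cov, J, y, noise_var):
    """Conjugate linear-Gaussian posterior + log evidence (oracle)."""
    P0 = np.linalg.inv(prior_cov)
    P = P0 + J.T @ J / noise_var
    S = np.linalg.inv(P)
    m = S @ (P0 @ prior_mean + J.T @ y / noise_var)
    # evidence: y ~ N(J mu0, J S0 J' + noise I)
    C = J @ prior_cov @ J.T + noise_var * np.eye(len(y))
    r = y - J @ prior_mean
    lev = -0.5 * (r @ np.linalg.solve(C, r) + np.linalg.slogdet(C)[1]
                  + len(y) * np.log(2 * np.pi))
    return m, S, lev


class TestLogEvidenceChange:
    def test_identity_reduction(self):
        rng = np.random.default_rng(0)
        S = np.eye(3) * 0.2
        m = rng.standard_normal(3)
        dF, mr, Sr = bayes.log_evidence_change(m, S, np.zeros(3), np.eye(3),
                                               np.zeros(3), np.eye(3))
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(mr, m) and np.allclose(Sr, S)

    def test_matches_conjugate_linear_model_oracle(self):
        """BMR evidence difference equals exact evidences of two linear models."""
        rng = np.random.default_rng(1)
        p, n = 4, 40
        J = rng.standard_normal((n, p))
        theta_true = np.array([1.0, 0.0, -0.5, 0.0])
        y = J @ theta_true + 0.3 * rng.standard_normal(n)
        prior_cov = np.eye(p)
        m, S, lev_full = _gauss_posterior(np.zeros(p), prior_cov, J, y, 0.09)
        # reduced model pins parameters 1 and 3 (true zeros)
        rvar = np.array([1.0, 1e-8, 1.0, 1e-8])
        mr_, Sr_, lev_red = _gauss_posterior(np.zeros(p), np.diag(rvar), J, y, 0.09)
        dF, mr, Sr = bayes.log_evidence_change(m, S, np.zeros(p), prior_cov,
                                               np.zeros(p), np.diag(rvar))
        assert dF == pytest.approx(lev_red - lev_full, abs=1e-6)
        assert np.allclose(mr, mr_, atol=1e-6)

    def test_compositionality_of_nested_reductions(self):
        rng = np.random.default_rng(2)
        p, n = 5, 60
        J = rng.standard_normal((n, p))
        y = J @ rng.standard_normal(p) + 0.5 * rng.standard_normal(n)
        m, S, _ = _gauss_posterior(np.zeros(p), np.eye(p), J, y, 0.25)
        var1 = np.array([1, 1, 1, 1e-8, 1.0])
        var2 = np.array([1, 1e-8, 1, 1e-8, 1.0])
        dF1, m1, S1 = bayes.log_evidence_change(m, S, np.zeros(p), np.eye(p),
                                                np.zeros(p), np.diag(var1))
        dF2, m2, S2 = bayes.log_evidence_change(m1, S1, np.zeros(p), np.diag(var1),
                                                np.zeros(p), np.diag(var2))
        dF_direct, md, Sd = bayes.log_evidence_change(m, S, np.zeros(p), np.eye(p),
                                                      np.zeros(p), np.diag(var2))
        assert dF1 + dF2 == pytest.approx(dF_direct, abs=1e-6)
        assert np.allclose(md, m2, atol=1e-6)

    def test_widened_priors_rejected_by_bmr_wrapper(self):
        from durnet.invert import InversionResult
        pri = PriorSpec(np.zeros(2), np.ones(2))
        wider = PriorSpec(np.zeros(2), np.array([1.0, 2.0]))
        res = InversionResult(mean=np.zeros(2), cov=np.eye(2), free_energy=0.0,
                              lambdas=np.zeros(1), layout=None, n_confounds=0,
                              explained_variance=1.0, iterations=1, converged=True)
        res.__class__ = type("R", (InversionResult,),
                             {"n_dcm": property(lambda self: 2)})
        with pytest.raises(ValueError):
            bayes.bayesian_model_reduction(res, pri, wider)


class TestRfxBms:
    def test_symmetric_evidence_uniform(self):
        lme = np.full((8, 4), 2.5)
        r = bayes.rfx_bms(lme, seed=0)
        assert np.allclose(r.expected_prob, 0.25, atol=1e-6)
        assert np.allclose(r.protected_exceedance_prob, 0.25, atol=0.01)
        assert r.bayesian_omnibus_risk > 0.5

    def test_dominant_model_wins(self):
        lme = np.zeros((12, 3))
        lme[:, 1] += 10.0
        r = bayes.rfx_bms(lme, seed=0)
        assert r.protected_exceedance_prob[1] > 0.9
        assert np.argmax(r.expected_prob) == 1

    def test_offset_invariance(self):
        rng = np.random.default_rng(4)
        lme = rng.standard_normal((10, 4)) * 3
        r1 = bayes.rfx_bms(lme, seed=1)
        r2 = bayes.rfx_bms(lme + rng.standard_normal((10, 1)) * 50, seed=1)
        assert np.allclose(r1.expected_prob, r2.expected_prob, atol=1e-8)
        assert np.allclose(r1.protected_exceedance_prob,
                           r2.protected_exceedance_prob, atol=1e-8)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        r = bayes.rfx_bms(rng.standard_normal((6, 5)), seed=2)
        assert r.expected_prob.sum() == pytest.approx(1.0, abs=1e-8)
        assert r.exceedance_prob.sum() == pytest.approx(1.0, abs=1e-8)
        assert r.protected_exceedance_prob.sum() == pytest.approx(1.0, abs=1e-8)

    def test_pep_mixing_identity(self):
        rng = np.random.default_rng(6)
        lme = rng.standard_normal((9, 3)) * 2
        r = bayes.rfx_bms(lme, seed=3)
        K = 3
        expected = (1 - r.bayesian_omnibus_risk) * r.exceedance_prob \
            + r.bayesian_omnibus_risk / K
        assert np.allclose(r.protected_exceedance_prob, expected, atol=1e-12)

    def test_ep_matches_long_monte_carlo_oracle(self):
        lme = np.zeros((6, 3))
        lme[:, 0] += 1.0
        r = bayes.rfx_bms(lme, seed=0, n_samples=100_000)
        rng = np.random.default_rng(123)
        draws = rng.dirichlet(r.alpha, size=400_000)
        oracle = np.bincount(np.argmax(draws, axis=1), minlength=3) / 400_000
        assert np.allclose(r.exceedance_prob, oracle, atol=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bayes.rfx_bms(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            bayes.rfx_bms(np.array([[np.inf, 0.0]]))


class TestFamilyInference:
    def test_equal_size_symmetric_families(self):
        lme = np.full((7, 6), 1.0)
        r = bayes.family_inference(lme, ["a", "a", "a", "b", "b", "b"], seed=0)
        assert np.allclose(r.expected_prob, 0.5, atol=1e-6)

    def test_unequal_sizes_corrected(self):
        """A family is not favored merely for holding more models."""
        lme = np.full((10, 5), 2.0)
        r = bayes.family_inference(lme, ["a", "a", "a", "a", "b"], seed=0)
        assert np.allclose(r.expected_prob, 0.5, atol=0.02)

    def test_dominant_family_wins(self):
        lme = np.zeros((10, 6))
        lme[:, 3:] += 6.0
        r = bayes.family_inference(lme, ["x", "x", "x", "y", "y", "y"], seed=0)
        assert r.model_names[np.argmax(r.protected_exceedance_prob)] == "y"
        assert r.protected_exceedance_prob[1] > 0.9

    def test_partition_must_cover(self):
        with pytest.raises(ValueError):
            bayes.family_inference(np.zeros((3, 4)), ["a", "b"])


class TestAveraging:
    def test_bma_one_hot(self):
        means = [np.array([1.0, 2.0]), np.array([5.0, 6.0])]
        covs = [np.eye(2), 2 * np.eye(2)]
        m, S = bayes.bma(means, covs, np.array([0.0, 1.0]))
        assert np.allclose(m, means[1]) and np.allclose(S, covs[1])

    def test_bma_mixture_moments(self):
        m, S = bayes.bma([np.array([1.0]), np.array([3.0])],
                         [np.array([[0.1]]), np.array([[0.1]])],
                         np.array([0.5, 0.5]))
        assert m[0] == pytest.approx(2.0)
        assert S[0, 0] == pytest.approx(1.1)

    def test_bma_weight_mismatch(self):
        with pytest.raises(ValueError):
            bayes.bma([np.zeros(1)], [np.eye(1)], np.array([0.5, 0.5]))

    def test_bpa_precision_combination(self):
        m, S = bayes.bpa([np.array([0.0]), np.array([2.0])],
                         [np.eye(1), np.eye(1)])
        assert m[0] == pytest.approx(1.0)
        assert S[0, 0] == pytest.approx(0.5)

    def test_bpa_single_subject_unchanged(self):
        m0 = np.array([0.3, -0.7])
        S0 = np.array([[0.5, 0.1], [0.1, 0.4]])
        m, S = bayes.bpa([m0], [S0])
        assert np.allclose(m, m0) and np.allclose(S, S0)

    def test_bpa_layout_mismatch(self):
        with pytest.raises(ValueError):
            bayes.bpa([np.zeros(2), np.zeros(3)], [np.eye(2), np.eye(3)])
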