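"""Group-level Bayesian model comparison and averaging.

Implements analytic Bayesian model reduction (nested-prior re-evaluation of a
fitted Gaussian posterior), random-effects Bayesian model selection with
exceedance and protected exceedance probabilities (the protection weighs the
comparison against the null possibility that evidence differences arose by
chance, quantified by the Bayesian omnibus risk), inference over model
families, Bayesian model averaging across models, and Bayesian parameter
averaging across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .invert import InversionResult, PriorSpec

PINNED_VAR = 1e-8


def robust_precision(cov: np.ndarray, rel_floor: float = 1e-9) -> np.ndarray:
    """Symmetric positive-definite inverse of a (near-singular) covariance.

    Eigenvalues are floored at ``rel_floor`` times the largest, so strongly
    correlated posteriors cannot produce spuriously indefinite precisions.
    """
    S = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, rel_floor * w.max())
    return (V / w) @ V.T


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------

def log_evidence_change(post_mean, post_cov, prior_mean, prior_cov,
                        rprior_mean, rprior_cov):
    """Evidence change and posterior of a reduced model, analytically.

    Given a Gaussian prior/posterior pair of a full model and a reduced prior
    (same dimension, variances only shrunk), returns
    (dF = ln p_reduced(y) - ln p_full(y), reduced mean, reduced covariance).
    """
    post_mean = np.asarray(post_mean, float)
    P = np.linalg.inv(post_cov)
    P0 = np.linalg.inv(prior_cov)
    Pr0 = np.linalg.inv(rprior_cov)
    Pr = P + Pr0 - P0
    br = P @ post_mean + Pr0 @ np.asarray(rprior_mean, float) - P0 @ np.asarray(prior_mean, float)
    Sr = np.linalg.inv(Pr)
    mr = Sr @ br
    terms = (np.linalg.slogdet(P)[1] + np.linalg.slogdet(Pr0)[1]
             - np.linalg.slogdet(P0)[1] - np.linalg.slogdet(Pr)[1])
    quad = (post_mean @ P @ post_mean
            + np.asarray(rprior_mean, float) @ Pr0 @ np.asarray(rprior_mean, float)
            - np.asarray(prior_mean, float) @ P0 @ np.asarray(prior_mean, float)
            - br @ Sr @ br)
    dF = 0.5 * terms - 0.5 * quad
    return float(dF), mr, Sr


def reduce_priors(priors: PriorSpec, keep: np.ndarray,
                  pinned_var: float = PINNED_VAR) -> PriorSpec:
    """Reduced prior: variances of dropped parameters pinned near zero."""
    keep = np.asarray(keep, dtype=bool)
    var = np.where(keep, priors.var, pinned_var)
    return PriorSpec(mean=priors.mean.copy(), var=var, names=list(priors.names))


def bayesian_model_reduction(full: InversionResult, priors: PriorSpec,
                             reduced_priors: PriorSpec,
                             beta_var: float = 16.0):
    """Reduced-model free energy and posterior from a fitted full model.

    ``priors``/``reduced_priors`` cover the coupling parameters; confound
    coefficients keep their own (unchanged) prior.  The reduced prior may
    only shrink variances.
    """
    if np.any(reduced_priors.var > priors.var + 1e-12):
        raise ValueError("reduced prior variances may not exceed the full ones")
    p = full.n_dcm
    n_beta = full.mean.size - p
    mean0 = np.concatenate([priors.mean, np.zeros(n_beta)])
    var0 = np.concatenate([priors.var, np.full(n_beta, beta_var)])
    rmean0 = np.concatenate([reduced_priors.mean, np.zeros(n_beta)])
    rvar0 = np.concatenate([reduced_priors.var, np.full(n_beta, beta_var)])
    # operate on the currently-free dims of the full model only
    free = var0 > PINNED_VAR
    idx = np.flatnonzero(free)
    dF, mr, Sr = log_evidence_change(
        full.mean[idx], full.cov[np.ix_(idx, idx)],
        mean0[idx], np.diag(var0[idx]),
        rmean0[idx], np.diag(np.maximum(rvar0[idx], PINNED_VAR)))
    mean_r = full.mean.copy()
    mean_r[idx] = mr
    cov_r = np.zeros_like(full.cov)
    cov_r[np.ix_(idx, idx)] = Sr
    return dF, mean_r, cov_r


def score_model_space(full: InversionResult, priors: PriorSpec,
                      reduced_prior_list: list[PriorSpec]) -> np.ndarray:
    """Relative log evidences (vs the full model) of many reduced models."""
    return np.array([bayesian_model_reduction(full, priors, rp)[0]
                     for rp in reduced_prior_list])


# ---------------------------------------------------------------------------
# random-effects Bayesian model selection
# ---------------------------------------------------------------------------

@dataclass
class BMSResult:
    """Group model-frequency inference (random-effects)."""

    expected_prob: np.ndarray  # E[r_k]
    exceedance_prob: np.ndarray  # P(r_k > r_j for all j)
    protected_exceedance_prob: np.ndarray
    bayesian_omnibus_risk: float
    alpha: np.ndarray  # Dirichlet posterior
    model_names: list[str] = field(default_factory=list)


def _dirichlet_vb(log_ev: np.ndarray, alpha0: np.ndarray,
                  max_iter: int = 200, tol: float = 1e-8):
    """Variational posterior over model frequencies; returns (alpha, u, F1).

    u is (subjects, models) responsibility matrix; F1 the variational free
    energy of the random-effects model at convergence.
    """
    N, K = log_ev.shape
    alpha = alpha0.copy().astype(float)
    u = np.full((N, K), 1.0 / K)
    for _ in range(max_iter):
        w = log_ev + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    w = log_ev + (digamma(alpha) - digamma(alpha.sum()))[None, :]
    u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
    F1 = (gammaln(alpha0.sum()) - gammaln(alpha.sum())
          + float(np.sum(gammaln(alpha) - gammaln(alpha0)))
          + float(np.sum(u * (log_ev - np.log(np.maximum(u, 1e-300))))))
    return alpha, u, F1


def _null_evidence(log_ev: np.ndarray, prior_weights: np.ndarray) -> float:
    """Log evidence of the null: fixed equal-frequency model mixture."""
    w = np.log(prior_weights / prior_weights.sum())
    return float(np.sum(logsumexp(log_ev + w[None, :], axis=1)))


def rfx_bms(log_ev: np.ndarray, alpha0: float | np.ndarray = 1.0,
            n_samples: int = 100_000, seed: int = 0,
            model_names: list[str] | None = None) -> BMSResult:
    """Random-effects model selection over a subjects x models evidence matrix.

    Expected frequencies come from the variational Dirichlet posterior;
    exceedance probabilities from Monte-Carlo draws of that posterior; the
    Bayesian omnibus risk compares the random-effects model against the null
    of indistinguishable models, and protects the exceedance probabilities:
    PEP = (1 - BOR) * EP + BOR / K.
    """
    log_ev = np.asarray(log_ev, dtype=float)
    if log_ev.ndim != 2 or log_ev.shape[1] < 2:
        raise ValueError("need a (subjects, >=2 models) evidence matrix")
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("log evidences must be finite")
    N, K = log_ev.shape
    alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,)).copy()
    alpha, u, F1 = _dirichlet_vb(log_ev, alpha0)
    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    wins = np.bincount(np.argmax(draws, axis=1), minlength=K)
    ep = wins / n_samples
    F0 = _null_evidence(log_ev, alpha0)
    bor = 1.0 / (1.0 + np.exp(np.clip(F1 - F0, -700, 700)))
    pep = (1.0 - bor) * ep + bor / K
    return BMSResult(expected_prob=expected, exceedance_prob=ep,
                     protected_exceedance_prob=pep, bayesian_omnibus_risk=float(bor),
                     alpha=alpha, model_names=model_names or [f"m{k}" for k in range(K)])


def family_inference(log_ev: np.ndarray, partition: list[str] | np.ndarray,
                     n_samples: int = 100_000, seed: int = 0) -> BMSResult:
    """Family-level random-effects comparison with a uniform family prior.

    ``partition`` labels each model column with its family.  Each family's
    per-subject evidence marginalizes its member models under a uniform
    within-family prior (log-mean-exp), which corrects for unequal family
    sizes exactly; the random-effects comparison then runs over families
    with a unit Dirichlet prior.
    """
    log_ev = np.asarray(log_ev, dtype=float)
    labels = np.asarray(partition)
    if labels.shape[0] != log_ev.shape[1]:
        raise ValueError("partition must label every model column")
    families = list(dict.fromkeys(labels.tolist()))
    fam_lme = np.stack(
        [logsumexp(log_ev[:, labels == f], axis=1) - np.log(np.sum(labels == f))
         for f in families], axis=1)
    result = rfx_bms(fam_lme, alpha0=1.0, n_samples=n_samples, seed=seed,
                     model_names=[str(f) for f in families])
    return result


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------

def bma(means: list[np.ndarray], covs: list[np.ndarray],
        weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bayesian model average: mixture mean and law-of-total-variance cov."""
    weights = np.asarray(weights, dtype=float)
    if len(means) != weights.size or len(covs) != weights.size:
        raise ValueError("one weight per model required")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    means = [np.asarray(m, float) for m in means]
    mean = sum(w * m for w, m in zip(weights, means))
    cov = sum(w * (np.asarray(S, float) + np.outer(m - mean, m - mean))
              for w, m, S in zip(weights, means, covs))
    return mean, cov


def bpa(means: list[np.ndarray], covs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Bayesian parameter average across subjects: precision-weighted fusion."""
    if not means:
        raise ValueError("need at least one posterior")
    shapes = {np.asarray(m).shape for m in means}
    if len(shapes) != 1:
        raise ValueError("parameter layouts differ across subjects")
    precisions = [np.linalg.inv(S) for S in covs]
    Ptot = sum(precisions)
    Stot = np.linalg.inv(Ptot)
    mean = Stot @ sum(P @ np.asarray(m, float) for P, m in zip(precisions, means))
    return mean, Stot
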