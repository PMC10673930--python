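"""Parametric empirical Bayes over first-level posteriors.

The second level models each first-level unit's coupling parameters as a
group mean plus Gaussian between-subject variation,

    theta_i = X beta + eps_i,   eps_i ~ N(0, exp(-gamma) * Sigma0),

where Sigma0 is the first-level prior covariance of the selected parameters
and gamma a single log precision-scaling estimated from the data.  Only the
first-level Gaussian posteriors are consumed (never the raw time-series):
swapping each unit's prior for the hierarchical prior N(X beta, Sigma_b) is
an analytic change-of-priors evaluation, so the total free energy is
quadratic in beta and the group posterior is available in closed form at
each candidate gamma.

Group-level structure search prunes parameters greedily by Bayesian model
reduction on the group posterior; a parameter's posterior probability Pp of
being nonzero is the sigmoid of the evidence difference between keeping and
pinning it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import log_evidence_change, robust_precision, PINNED_VAR
from .invert import InversionResult, PriorSpec

DEFAULT_PP_THRESHOLD = 0.99


@dataclass
class PEBResult:
    """Group posterior, per-parameter posterior probabilities, diagnostics."""

    mean: np.ndarray  # group-level beta
    cov: np.ndarray
    prior: PriorSpec  # group-level prior over beta
    gamma: float  # between-subject log precision scale
    free_energy: float
    pp: np.ndarray  # P(parameter nonzero), via reduced-model evidence
    surviving: np.ndarray  # bool mask {Pp > threshold}
    pp_threshold: float
    names: list[str] = field(default_factory=list)
    n_units: int = 0
    design: np.ndarray | None = None


def _collect(first_level: list[InversionResult], priors: PriorSpec,
             param_idx: np.ndarray):
    """Sub-block posteriors/prior over the selected coupling parameters."""
    mus, Ps = [], []
    for res in first_level:
        mu = res.dcm_mean()[param_idx]
        S = res.dcm_cov()[np.ix_(param_idx, param_idx)]
        mus.append(mu)
        Ps.append(robust_precision(S))
    mu0 = priors.mean[param_idx]
    P0 = np.diag(1.0 / priors.var[param_idx])
    return mus, Ps, mu0, P0


def _data_summaries(mus, Ps, mu0, P0, rel_floor: float = 1e-8):
    """Prior-free likelihood summaries per unit.

    Each first-level posterior N(mu_i, P_i^-1) under the shared prior
    N(mu0, P0^-1) carries the data message N(m_i, D_i^-1) with
    D_i = P_i - P0 and D_i m_i = c_i = P_i mu_i - P0 mu0.  D_i is
    PSD-floored in its eigenbasis (directions the data do not inform get a
    tiny precision, i.e. an essentially flat message).
    """
    out = []
    for mu_i, P_i in zip(mus, Ps):
        D = 0.5 * ((P_i - P0) + (P_i - P0).T)
        w, V = np.linalg.eigh(D)
        w = np.maximum(w, rel_floor * max(w.max(), 1.0))
        c = P_i @ mu_i - P0 @ mu0
        m = (V / w) @ (V.T @ c)
        out.append(((V * w) @ V.T, m))
    return out


def _peb_at_gamma(summaries, Sigma0, gamma, beta_prior_prec):
    """Closed-form (beta_hat, Sigma_beta, F up to unit constants) at fixed gamma.

    The second level is the Gaussian random-effects model
    m_i ~ N(beta, D_i^-1 + Sigma_b) with Sigma_b = exp(-gamma) Sigma0; all
    algebra runs through M_i = I + D_i Sigma_b, which stays well-conditioned
    even when a unit's data message is flat in some directions.
    """
    p = Sigma0.shape[0]
    Sb = np.exp(-gamma) * Sigma0
    H = beta_prior_prec.copy()
    rhs = np.zeros(p)
    logdet = 0.0
    quad0 = 0.0
    Ws = []
    for D, m in summaries:
        M = np.eye(p) + D @ Sb
        Minv = np.linalg.inv(M)
        W = Minv @ D  # (D^-1 + Sigma_b)^-1, symmetric up to roundoff
        W = 0.5 * (W + W.T)
        H += W
        Wm = W @ m
        rhs += Wm
        logdet += np.linalg.slogdet(M)[1]
        quad0 += m @ Wm
        Ws.append((W, Wm))
    Sbeta = np.linalg.inv(H)
    beta = Sbeta @ rhs
    quad = quad0 - 2.0 * beta @ rhs + sum(beta @ W @ beta for W, _ in Ws)
    F = -0.5 * (logdet + quad)
    F -= 0.5 * beta @ beta_prior_prec @ beta
    F += 0.5 * (np.linalg.slogdet(Sbeta)[1] + np.linalg.slogdet(beta_prior_prec)[1])
    return beta, Sbeta, float(F)


def _moment_second_level(summaries, prior_var, rel_floor: float = 1e-8):
    """Per-parameter random-effects combination with moment-matched
    between-unit variance (DerSimonian-Laird).

    Works on the diagonal of each unit's data message: v_ik = (D_i^-1)_kk.
    The between-unit variance tau_k^2 is estimated from the excess dispersion
    of the unit estimates over their claimed variances, which keeps the group
    weighting honest when individual curvature estimates are off.
    """
    n_units = len(summaries)
    p = summaries[0][1].size
    M = np.stack([m for _, m in summaries])  # (units, p)
    V = np.stack([np.diag(np.linalg.inv(D + np.eye(p) * rel_floor))
                  for D, _ in summaries])
    beta = np.zeros(p)
    var = np.zeros(p)
    tau2 = np.zeros(p)
    for k in range(p):
        # a unit contributes to this parameter only where its data actually
        # constrain it; in flat directions the prior-free estimate is noise
        inf = V[:, k] < 4.0 * prior_var[k]
        if inf.sum() < 2:
            beta[k] = 0.0
            var[k] = prior_var[k]
            continue
        m = M[inf, k]
        v = V[inf, k]
        w = 1.0 / v
        mbar = np.sum(w * m) / np.sum(w)
        q = float(np.sum(w * (m - mbar) ** 2))
        denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        tau2[k] = max(0.0, (q - (inf.sum() - 1)) / max(denom, 1e-300))
        wstar = 1.0 / (v + tau2[k])
        prec = np.sum(wstar) + 1.0 / prior_var[k]
        beta[k] = np.sum(wstar * m) / prec
        var[k] = 1.0 / prec
    return beta, np.diag(var), tau2


def fit_peb(first_level: list[InversionResult], priors: PriorSpec,
            param_idx: np.ndarray | None = None,
            design: np.ndarray | None = None,
            gamma_grid: np.ndarray | None = None,
            gamma_prior: tuple[float, float] = (2.0, 4.0),
            pp_threshold: float = DEFAULT_PP_THRESHOLD,
            between_variance: str = "moment") -> PEBResult:
    """Hierarchical group estimate from first-level posteriors.

    ``param_idx`` selects which coupling parameters go to the second level
    (default: all).  ``design`` currently supports the single group-mean
    column (rows must match the number of first-level units); covariate
    designs are out of scope.  ``between_variance`` selects how the
    between-unit covariance is set: ``"moment"`` (default) matches it per
    parameter to the observed excess dispersion of the prior-free unit
    estimates; ``"evidence"`` maximizes the group free energy over a single
    precision scaling of the first-level prior.
    """
    if not first_level:
        raise ValueError("need at least one first-level result")
    p_all = first_level[0].n_dcm
    if any(r.n_dcm != p_all for r in first_level):
        raise ValueError("first-level parameter layouts differ")
    if design is not None:
        design = np.asarray(design, float)
        if design.shape[0] != len(first_level):
            raise ValueError(f"design rows ({design.shape[0]}) must match "
                             f"first-level units ({len(first_level)})")
        if design.ndim != 2 or design.shape[1] != 1 or not np.allclose(design, 1.0):
            raise ValueError("only the single group-mean design column is supported")
    param_idx = np.arange(p_all) if param_idx is None else np.asarray(param_idx, int)
    mus, Ps, mu0, P0 = _collect(first_level, priors, param_idx)
    Sigma0 = np.diag(priors.var[param_idx])
    beta_prior_prec = np.diag(1.0 / priors.var[param_idx])
    summaries = _data_summaries(mus, Ps, mu0, P0)
    if between_variance == "moment":
        beta, Sb, tau2 = _moment_second_level(summaries, priors.var[param_idx])
        # report the dispersion as an equivalent log precision scaling
        rel = np.mean(tau2 / priors.var[param_idx])
        gamma = float(-np.log(max(rel, 1e-12)))
        _, _, F = _peb_at_gamma(summaries, Sigma0, gamma, beta_prior_prec)
    elif between_variance == "evidence":
        if gamma_grid is None:
            gamma_grid = np.arange(-1.0, 8.01, 0.25)
        g0, gv = gamma_prior
        best = None
        for g in gamma_grid:
            beta, Sb, F = _peb_at_gamma(summaries, Sigma0, g, beta_prior_prec)
            F -= 0.5 * (g - g0) ** 2 / gv
            if not np.isfinite(F):
                continue
            if best is None or F > best[3]:
                best = (g, beta, Sb, F)
        if best is None:
            raise RuntimeError("no admissible between-subject precision on the grid")
        gamma, beta, Sb, F = best
    else:
        raise ValueError("between_variance must be 'moment' or 'evidence'")
    prior = PriorSpec(mean=mu0.copy(), var=priors.var[param_idx].copy(),
                      names=[priors.names[i] for i in param_idx] if priors.names else [])
    result = PEBResult(mean=beta, cov=Sb, prior=prior, gamma=float(gamma),
                       free_energy=F, pp=np.ones(beta.size),
                       surviving=np.ones(beta.size, bool),
                       pp_threshold=pp_threshold, names=prior.names,
                       n_units=len(first_level), design=design)
    result.pp = _posterior_probabilities(result, np.ones(beta.size, bool))
    result.surviving = result.pp > pp_threshold
    return result


def _reduced_F(peb: PEBResult, keep: np.ndarray) -> float:
    """Group-level evidence change when pinning the dropped parameters at 0."""
    rvar = np.where(keep, peb.prior.var, PINNED_VAR)
    dF, _, _ = log_evidence_change(peb.mean, peb.cov, peb.prior.mean,
                                   np.diag(peb.prior.var),
                                   peb.prior.mean, np.diag(rvar))
    return dF


def _posterior_probabilities(peb: PEBResult, base: np.ndarray) -> np.ndarray:
    """Pp per parameter: sigmoid of F(with k) - F(without k) around ``base``."""
    p = peb.mean.size
    pp = np.empty(p)
    for k in range(p):
        with_k = base.copy(); with_k[k] = True
        without_k = base.copy(); without_k[k] = False
        d = _reduced_F(peb, with_k) - _reduced_F(peb, without_k)
        pp[k] = 1.0 / (1.0 + np.exp(-np.clip(d, -700, 700)))
    return pp


def prune_parameters(peb: PEBResult, threshold: float | None = None,
                     candidates: np.ndarray | None = None) -> PEBResult:
    """Greedy structure search over reduced group models.

    Repeatedly switches off the candidate parameter whose removal most
    increases the group evidence, until no removal helps; Pp is then
    recomputed around the surviving structure and the surviving mask is
    {Pp > threshold}.  Returns a new PEBResult with the reduced (BMA)
    posterior of the surviving model.
    """
    threshold = peb.pp_threshold if threshold is None else threshold
    p = peb.mean.size
    candidates = np.ones(p, bool) if candidates is None else np.asarray(candidates, bool)
    keep = np.ones(p, bool)
    F_cur = _reduced_F(peb, keep)
    while True:
        best_gain, best_k = 0.0, -1
        for k in np.flatnonzero(keep & candidates):
            trial = keep.copy(); trial[k] = False
            gain = _reduced_F(peb, trial) - F_cur
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k < 0:
            break
        keep[best_k] = False
        F_cur += best_gain
    pp = _posterior_probabilities(peb, keep)
    pp = np.where(candidates, pp, 1.0)  # non-candidates are not up for removal
    surviving = pp > threshold
    rvar = np.where(keep, peb.prior.var, PINNED_VAR)
    _, mr, Sr = log_evidence_change(peb.mean, peb.cov, peb.prior.mean,
                                    np.diag(peb.prior.var),
                                    peb.prior.mean, np.diag(rvar))
    return PEBResult(mean=mr, cov=Sr, prior=peb.prior, gamma=peb.gamma,
                     free_energy=peb.free_energy + F_cur, pp=pp,
                     surviving=surviving, pp_threshold=threshold,
                     names=peb.names, n_units=peb.n_units, design=peb.design)


def peb_bma(pruned: PEBResult, zero_tol: float = 1e-6) -> np.ndarray:
    """Group parameter strengths of the surviving structure (Hz, signed).

    Parameters outside the surviving mask are reported as exactly zero.
    """
    out = np.where(pruned.surviving, pruned.mean, 0.0)
    out[np.abs(out) < zero_tol] = 0.0
    return out
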